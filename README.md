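# lcstress

Prospective biomarkers of stress resilience from locus-coeruleus (LC)
conflict-upregulation responses, and out-of-sample prediction of
longitudinal symptom change.

## The problem

When people are about to face a prolonged real-life stressor, can a
physiological measurement taken *beforehand* predict who will develop
anxiety or depression symptoms? One candidate marker is the responsivity of
the locus coeruleus–noradrenaline (LC-NE) system. In an emotional Stroop
task, an incongruent trial preceded by a congruent trial (CI) demands an
upregulation of cognitive control that an incongruent trial preceded by
another incongruent trial (II) does not — the stimuli and responses are
identical, so the **CI > II contrast** isolates the upregulation response.
This package implements the full analysis chain around that contrast:

- **`synthetic_cohort`** (`lcstress.synthetic`) — seeded generator for
  complete cohorts: trial tables, 4D functional volumes on a voxel grid
  with probabilistic ROI masks (LC at two widths, raphe nuclei, VTA,
  substantia nigra, amygdala, a CSF compartment), 250 Hz pupil traces, and
  longitudinal STAI/PHQ panels whose mean change is rank-coupled to the true
  LC amplitude through a Gaussian copula at a configurable Spearman level.
- **`task_behavior`** (`lcstress.behavior`) — standardized linear (RT) and
  logistic (accuracy) conflict regressions; the congruency-sequence-effect
  score CSE = mean RT(CI) − mean RT(II).
- **`neuro_glm`** (`lcstress.glm`) — event-related GLM with double-gamma
  HRF, discrete-cosine high-pass, motion/blink/CSF-PC nuisance regressors,
  exact AR(1) prewhitening, CI > II contrast maps, and PPI coupling
  (seed × CI − seed × II) with an LC seed.
- **`roi_signals`** (`lcstress.roi`) — probability-weighted ROI averages
  `Σwᵢxᵢ/Σwᵢ`, tSNR maps (mean/sd per voxel), and leave-one-subject-out
  sphere extraction around group peaks.
- **`pupil`** (`lcstress.pupil`) — blink interpolation, 0.05–4 Hz
  zero-phase band-pass, run z-scoring, ±5 s epochs, cluster-mass sign-flip
  permutation tests, and the pupil dilation distance
  PDD = (CI−II)_current − (CI−II)_pre.
- **`resilience_prediction`** (`lcstress.prediction`) — symptom change
  scores Δt = t − t0, Spearman/robust-regression associations, median-split
  tests, and the headline **leave-two-subjects-out (LTSO)** procedure: for
  each of the N·(N−1) ordered pairs (2256 at N = 48), fit on the other
  N−2 subjects, predict both, score the predicted ordering against the
  observed one; significance from a permutation null with
  p = (1 + #{null ≥ observed}) / (1 + n_perm).
- **`model_selection`** (`lcstress.models`) — base (clinical-only) vs full
  (clinical + physiological) vs stepwise-selected models with R², adjusted
  R², AIC/BIC, and ROC/AUC summaries.

## Worked example

```python
import numpy as np
from lcstress import CohortConfig, simulate_symptoms, spearman_rho
from lcstress.prediction import permutation_null

cfg = CohortConfig()              # N = 48, LC–symptom Spearman target 0.35
rng = np.random.default_rng(0)
amps = cfg.lc_amplitude_mean + cfg.lc_amplitude_sd * rng.standard_normal(48)
panel = simulate_symptoms(amps, cfg, seed=1)
change = ((panel.STAI_t1 + panel.STAI_t2) / 2 - panel.STAI_t0).to_numpy(float)

rho, p = spearman_rho(amps, change)
res = permutation_null(amps, change, n_perm=1000, seed=2)
print(f"Spearman rho = {rho:.2f} (p = {p:.4f})")
print(f"LTSO accuracy = {res.accuracy:.1f}% over {res.n_pairs} pairs, "
      f"p = {res.p_value:.4f}, null 95th pct = {res.null_pct95:.1f}%")
```

prints

```
Spearman rho = 0.34 (p = 0.0197)
LTSO accuracy = 61.3% over 2256 pairs, p = 0.0110, null 95th pct = 59.3%
```

A true LC amplitude that rank-correlates with subsequent symptom change at
0.34 lets the leave-two-out procedure order unseen subject pairs correctly
61.3% of the time — above the 95th percentile of the label-shuffled null,
so the marker carries genuine prospective information in this cohort.

The shell pipeline runs the same stages over an on-disk cohort:

```bash
lcstress simulate --seed 7 --out cohort/
lcstress behavior --cohort cohort/
lcstress glm      --cohort cohort/
lcstress roi      --cohort cohort/
lcstress pupil    --cohort cohort/ --n-perm 1000 --seed 11
lcstress predict  --cohort cohort/ --outcome anxiety --predictors lc --n-perm 1000 --seed 13
lcstress models   --cohort cohort/ --outcome anxiety
```

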