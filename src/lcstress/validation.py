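"""Calibration and recovery experiments on synthetic cohorts.

Each experiment regenerates data from scratch under a stated configuration,
runs the corresponding analysis pathway, and returns summary numbers.  They
serve two purposes: the test suite asserts the statistical contracts
(type-I error control, power, recovery of planted effects), and the
reproduction script reports the same numbers for a given seed.

Problem sizes default to desk-scale settings (compact voxel grids, a few
hundred permutations) chosen so the whole battery runs in minutes on one
CPU; cohort-level statistical conditions (N, coupling, noise, tSNR) follow
the study configuration.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import CohortConfig
from .glm import (
    build_design,
    contrast_tmap,
    contrast_vector,
    csf_nuisance_pcs,
    fit_glm_ar1,
)
from .prediction import ltso_accuracy, permutation_null
from .pupil import cluster_permutation_test
from .roi import roi_tsnr, tsnr_map, weighted_roi_average
from .synthetic import (
    cohort_streams,
    generate_trial_sequence,
    simulate_bold,
    simulate_symptoms,
    _draw_truths,
)

__all__ = [
    "compact_config",
    "ltso_type1_experiment",
    "ltso_power_experiment",
    "glm_recovery_experiment",
    "roi_specificity_experiment",
    "pupil_fwer_experiment",
    "pupil_power_experiment",
    "tsnr_experiment",
]

#: control ROIs compared against the LC in the specificity harness
CONTROL_ROIS = ("dr", "mr", "vta", "sn", "amygdala")


def compact_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default study conditions on a compact voxel grid.

    The grid is trimmed to a box that still contains every ROI; this only
    removes background voxels, so ROI-level statistics are unchanged while
    per-subject cost drops.
    """
    kw = dict(grid_shape=(16, 20, 13), seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


# ---------------------------------------------------------------------------
# LTSO calibration

def ltso_type1_experiment(n_replicates: int = 200, n_subjects: int = 24,
                          n_perm: int = 200, alpha: float = 0.05,
                          seed: int = 0) -> dict:
    """Rejection rate of the LTSO permutation test when the symptom changes
    are independent of the predictor."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.standard_normal(n_subjects)
        y = rng.standard_normal(n_subjects)
        res = permutation_null(x, y, n_perm=n_perm,
                               seed=int(rng.integers(2 ** 31)))
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_replicates,
            "n_replicates": n_replicates, "n_subjects": n_subjects}


def ltso_power_experiment(n_cohorts: int = 100, n_perm: int = 1000,
                          seed: int = 0, config: CohortConfig | None = None) -> dict:
    """LTSO accuracy and power with the configured LC–symptom coupling.

    Cohorts are drawn at the study size (N = 48 by default); the predictor
    is the true LC amplitude and the outcome the anxiety (STAI) mean change
    produced by the copula-coupled symptom generator.
    """
    base = config or CohortConfig()
    accs, pvals = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_cohorts):
        cseed = int(rng.integers(2 ** 31))
        _, cohort_level = cohort_streams(cseed, base.n_subjects)
        truths = _draw_truths(base, cohort_level["amplitudes"])
        amps = np.array([t["lc_amplitude"] for t in truths])
        panel = simulate_symptoms(amps, base,
                                  np.random.default_rng(cohort_level["symptoms"]))
        y = ((panel["STAI_t1"] + panel["STAI_t2"]) / 2.0
             - panel["STAI_t0"]).to_numpy(float)
        res = permutation_null(amps, y, n_perm=n_perm,
                               seed=int(rng.integers(2 ** 31)))
        accs.append(res.accuracy)
        pvals.append(res.p_value)
    accs, pvals = np.array(accs), np.array(pvals)
    return {"mean_accuracy": float(accs.mean()),
            "frac_significant": float(np.mean(pvals < 0.05)),
            "n_cohorts": n_cohorts,
            "n_pairs": base.n_subjects * (base.n_subjects - 1)}


# ---------------------------------------------------------------------------
# GLM calibration

def glm_recovery_experiment(n_null_voxels: int = 2000, phi: float = 0.3,
                            amplitude: float = 0.7, n_effect_voxels: int = 4000,
                            seed: int = 0) -> dict:
    """Noiseless recovery, AR(1) estimation, effect bias and null t type-I.

    A shared event schedule drives: (a) one noiseless voxel whose CI−II
    contrast must reproduce the injected amplitude to numerical precision;
    (b) ``n_effect_voxels`` AR(1)-noise voxels carrying the amplitude, for
    the bias check; (c) ``n_null_voxels`` null AR(1) voxels, whose contrast
    t statistics are compared against the nominal 5% level.
    """
    rng = np.random.default_rng(seed)
    cfg = CohortConfig()
    trials = generate_trial_sequence(
        cfg.n_trials, rng, soa_seconds=cfg.soa_seconds,
        jitter_seconds=cfg.jitter_seconds,
        initial_offset_seconds=cfg.initial_offset_seconds)
    design = build_design(trials, cfg.tr_seconds, cfg.n_scans,
                          hp_cutoff_s=None)
    n_scans = cfg.n_scans
    ci = design.X[:, design.index("CI")]
    ii = design.X[:, design.index("II")]
    signal = amplitude * (ci - ii) / 2.0
    c = contrast_vector(design, {"CI": 1.0, "II": -1.0})

    # (a) noiseless
    clean = (100.0 + signal).reshape(1, 1, 1, n_scans)
    rel_err = abs(float(
        contrast_tmap(fit_glm_ar1(clean, design, ar1=0.0), c).effect.ravel()[0])
        - amplitude) / amplitude

    # (b)+(c) AR(1) noise voxels, one pooled fit
    def ar1(n_vox):
        e = rng.standard_normal((n_scans, n_vox)) * np.sqrt(1 - phi ** 2)
        e[0] = rng.standard_normal(n_vox)
        from scipy.signal import lfilter
        return lfilter([1.0], [1.0, -phi], e, axis=0)

    n_tot = n_effect_voxels + n_null_voxels
    Y = 100.0 + ar1(n_tot) * 2.0
    Y[:, :n_effect_voxels] += signal[:, None]
    res = fit_glm_ar1(Y.T.reshape(n_tot, 1, 1, n_scans), design)
    cmap = contrast_tmap(res, c)
    eff = cmap.effect.ravel()
    tmap = cmap.t.ravel()
    bias = float(abs(eff[:n_effect_voxels].mean() - amplitude) / amplitude)
    tcrit = stats.t.ppf(0.975, df=res.df)
    type1 = float(np.mean(np.abs(tmap[n_effect_voxels:]) > tcrit))
    return {"noiseless_rel_err": rel_err, "phi_est": res.phi,
            "beta_rel_bias": bias, "null_t_type1": type1,
            "n_null_voxels": n_null_voxels}


# ---------------------------------------------------------------------------
# ROI specificity

def _subject_lc_and_controls(config: CohortConfig, trials, truth, seed):
    """Run the first-level pipeline for one subject; return ROI contrasts.

    The massively univariate GLM is fit on the brainstem/limbic voxels that
    feed the extractions (union of all ROI supports); per-voxel estimates
    are identical to a whole-grid fit, with the AR(1) coefficient pooled
    over those voxels.
    """
    bold, masks, motion, blink = simulate_bold(trials, config, truth, seed)
    pcs, _ = csf_nuisance_pcs(bold, masks["csf"], k=5)
    nuis = {f"motion{i + 1}": motion[:, i] for i in range(6)}
    nuis["blink"] = blink
    for i in range(5):
        nuis[f"csf_pc{i + 1}"] = pcs[:, i]
    design = build_design(trials, config.tr_seconds, config.n_scans,
                          nuisance=nuis, oversampling=8)
    support = np.zeros(bold.shape[:-1], dtype=bool)
    for m in masks.values():
        support |= m > 0
    sub = bold[support][:, None, None, :]
    res = fit_glm_ar1(sub, design)
    effect = contrast_tmap(res, contrast_vector(
        design, {"CI": 1.0, "II": -1.0})).effect.ravel()
    out = {"lc_1sd": weighted_roi_average(effect, masks["lc_1sd"][support])}
    for name in CONTROL_ROIS:
        out[name] = weighted_roi_average(effect, masks[name][support])
    return out, masks, bold


def roi_specificity_experiment(n_cohorts: int = 100, n_subjects: int = 48,
                               seed: int = 0,
                               config: CohortConfig | None = None) -> dict:
    """Does the LC extraction out-correlate every control ROI?

    Only the LC carries the symptom-coupled amplitude; control ROIs respond
    to the task but carry no CI−II difference, so their extracted values are
    estimation noise.  For each cohort, |Spearman rho| with the anxiety mean
    change is compared between the LC-1SD extraction and each control ROI.
    Returns per-ROI win fractions and the mean measured LC rho.
    """
    base = config or compact_config()
    rng = np.random.default_rng(seed)
    wins = {name: 0 for name in CONTROL_ROIS}
    lc_rhos = []
    for _ in range(n_cohorts):
        cseed = int(rng.integers(2 ** 31))
        cfg = CohortConfig(**{**base.__dict__, "seed": cseed,
                              "n_subjects": n_subjects})
        sub_streams, cohort_level = cohort_streams(cfg.seed, n_subjects)
        truths = _draw_truths(cfg, cohort_level["amplitudes"])
        values = {name: [] for name in ("lc_1sd",) + CONTROL_ROIS}
        for i in range(n_subjects):
            trials = generate_trial_sequence(
                cfg.n_trials, np.random.default_rng(sub_streams[i]["trials"]),
                soa_seconds=cfg.soa_seconds, jitter_seconds=cfg.jitter_seconds,
                initial_offset_seconds=cfg.initial_offset_seconds)
            vals, _, _ = _subject_lc_and_controls(
                cfg, trials, truths[i],
                np.random.default_rng(sub_streams[i]["bold"]))
            for name, v in vals.items():
                values[name].append(v)
        amps = np.array([t["lc_amplitude"] for t in truths])
        panel = simulate_symptoms(amps, cfg,
                                  np.random.default_rng(cohort_level["symptoms"]))
        y = ((panel["STAI_t1"] + panel["STAI_t2"]) / 2.0
             - panel["STAI_t0"]).to_numpy(float)
        rho_lc = abs(stats.spearmanr(values["lc_1sd"], y).statistic)
        lc_rhos.append(rho_lc)
        for name in CONTROL_ROIS:
            if rho_lc > abs(stats.spearmanr(values[name], y).statistic):
                wins[name] += 1
    return {"win_fraction": {k: v / n_cohorts for k, v in wins.items()},
            "mean_lc_abs_rho": float(np.mean(lc_rhos)),
            "n_cohorts": n_cohorts}


# ---------------------------------------------------------------------------
# pupil cluster statistics

def pupil_fwer_experiment(n_replicates: int = 500, n_subjects: int = 48,
                          n_time: int = 2501, n_perm: int = 200,
                          seed: int = 0) -> dict:
    """Family-wise error of the cluster test on null Gaussian waveforms."""
    rng = np.random.default_rng(seed)
    false_pos = 0
    for _ in range(n_replicates):
        W = rng.standard_normal((n_subjects, n_time))
        res = cluster_permutation_test(W, n_perm=n_perm,
                                       seed=int(rng.integers(2 ** 31)))
        if any(c[3] < 0.05 for c in res.clusters):
            false_pos += 1
    return {"fwer": false_pos / n_replicates, "n_replicates": n_replicates}


def pupil_power_experiment(n_replicates: int = 200, n_subjects: int = 48,
                           n_time: int = 2501, n_perm: int = 200,
                           offset_sd: float = 0.8,
                           window: tuple[int, int] = (400, 700),
                           seed: int = 0) -> dict:
    """Detection rate of a planted offset (in units of the within-subject
    waveform sd) spanning a known sample window."""
    rng = np.random.default_rng(seed)
    hits = 0
    lo, hi = window
    dt_ms = 4.0
    for _ in range(n_replicates):
        W = rng.standard_normal((n_subjects, n_time))
        W[:, lo:hi + 1] += offset_sd
        res = cluster_permutation_test(W, n_perm=n_perm,
                                       seed=int(rng.integers(2 ** 31)))
        for start_ms, end_ms, _, p in res.clusters:
            if p < 0.05 and start_ms <= hi * dt_ms and end_ms >= lo * dt_ms:
                hits += 1
                break
    return {"detection_rate": hits / n_replicates,
            "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# tSNR

def tsnr_experiment(n_sims: int = 1000, mu: float = 100.0, sigma: float = 2.5,
                    n_scans: int = 200, seed: int = 0,
                    n_subjects_qc: int = 8) -> dict:
    """tSNR calibration on Gaussian series plus the cohort QC rule.

    (a) mean tSNR of white-Gaussian series with mu/sigma = 40;
    (b) LC tSNR for every subject of a default-condition cohort must clear
    the > 30 quality cut-off.
    """
    rng = np.random.default_rng(seed)
    series = mu + sigma * rng.standard_normal((n_sims, 1, n_scans))
    vals = tsnr_map(series)
    mean_tsnr = float(np.nanmean(vals))

    cfg = compact_config(seed=seed + 1, n_subjects=n_subjects_qc)
    sub_streams, cohort_level = cohort_streams(cfg.seed, cfg.n_subjects)
    truths = _draw_truths(cfg, cohort_level["amplitudes"])
    lc_tsnrs = []
    for i in range(cfg.n_subjects):
        trials = generate_trial_sequence(
            cfg.n_trials, np.random.default_rng(sub_streams[i]["trials"]),
            soa_seconds=cfg.soa_seconds, jitter_seconds=cfg.jitter_seconds,
            initial_offset_seconds=cfg.initial_offset_seconds)
        bold, masks, _, _ = simulate_bold(
            trials, cfg, truths[i], np.random.default_rng(sub_streams[i]["bold"]))
        lc_tsnrs.append(roi_tsnr(tsnr_map(bold), masks["lc_1sd"]))
    return {"mean_tsnr": mean_tsnr, "lc_tsnr_min": float(min(lc_tsnrs)),
            "lc_tsnr_mean": float(np.mean(lc_tsnrs)),
            "n_subjects_qc": n_subjects_qc}
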