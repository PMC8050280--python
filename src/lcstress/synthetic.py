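"""Seeded synthetic cohorts for the conflict-upregulation pipeline.

The generator emulates the statistical structure the analyses assume:

* an emotional-Stroop trial sequence with congruent/incongruent trials and
  the derived trial-sequence labels (CC, CI, IC, II — second letter is the
  current trial, first letter the previous one);
* reaction times carrying congruency, congruency-sequence and valence
  effects, and accuracies with a higher error rate on incongruent trials;
* 4D functional volumes on a common voxel grid, where the locus coeruleus
  (LC) carries a per-subject CI > II amplitude, all nuclei respond to every
  trial, AR(1) noise and three shared physiological components contaminate
  the data (full amplitude in a CSF compartment, attenuated leakage into
  the brainstem nuclei), plus motion-correlated drift;
* a 250 Hz pupil trace with conflict-modulated evoked dilations, a
  pre-trial elevation on II trials carried over from the preceding
  incongruent trial, and contiguous blink gaps;
* longitudinal symptom scores (STAI, PHQ) at t0/t1/t2 whose mean change
  rank-correlates with the true LC amplitude at a configurable Spearman
  level via a Gaussian copula.

All randomness flows from the root ``config.seed`` through
:func:`cohort_streams`: one ``numpy.random.SeedSequence`` child per subject,
further split into named streams (trials, behavior, bold, pupil), plus
cohort-level streams for the true amplitudes and the symptom panel.
Identical (config, seed) therefore reproduces identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import CubicSpline

from . import io as cio
from .config import CohortConfig, BehaviorConfig
from .errors import InvalidArgumentError
from .glm import build_design

__all__ = [
    "SubjectDataset",
    "cohort_streams",
    "generate_trial_sequence",
    "simulate_behavior",
    "make_masks",
    "simulate_bold",
    "simulate_pupil",
    "simulate_symptoms",
    "generate_subject",
    "generate_cohort_data",
    "generate_cohort",
]

NUCLEI = ("lc_1sd", "dr", "mr", "vta", "sn", "amygdala")


@dataclass
class SubjectDataset:
    """In-memory per-subject bundle mirroring the on-disk layout."""

    subject_id: int
    trials: pd.DataFrame
    bold: np.ndarray                      # (*grid, n_scans)
    masks: Mapping[str, np.ndarray]
    motion: np.ndarray                    # (n_scans, 6)
    blink_regressor: np.ndarray           # (n_scans,)
    pupil: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# seeding

def cohort_streams(seed: int, n_subjects: int):
    """Deterministic seed-spawning scheme for a whole cohort.

    Returns ``(subject_streams, cohort_level)`` where ``subject_streams`` is
    a list of dicts with SeedSequences for the streams ``trials``,
    ``behavior``, ``bold`` and ``pupil``, and ``cohort_level`` has streams
    ``amplitudes`` and ``symptoms``.
    """
    root = np.random.SeedSequence(seed)
    cohort_child, *subs = root.spawn(n_subjects + 1)
    amp_ss, symp_ss = cohort_child.spawn(2)
    names = ("trials", "behavior", "bold", "pupil")
    subject = [dict(zip(names, ss.spawn(4))) for ss in subs]
    return subject, {"amplitudes": amp_ss, "symptoms": symp_ss}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trials and behavior

def generate_trial_sequence(n_trials: int, seed, *, soa_seconds: float = 4.0,
                            jitter_seconds: float = 1.0,
                            initial_offset_seconds: float = 12.0,
                            trial_duration_seconds: float = 1.0,
                            imbalance_cap: int = 4) -> pd.DataFrame:
    """Randomised first-order-balanced congruent/incongruent sequence.

    Congruency labels are a shuffled half/half split (so the congruency
    imbalance is at most ``n_trials % 2``, always within ``imbalance_cap``);
    the shuffle is redrawn (bounded attempts) until all four trial-sequence
    types occur, which is essentially always the case beyond toy lengths.
    Onsets start at ``initial_offset_seconds`` and are spaced by the SOA
    plus a uniform jitter.
    """
    if n_trials < 2:
        raise InvalidArgumentError("need at least 2 trials")
    rng = _rng(seed)
    base = np.array(["C", "I"]).repeat([(n_trials + 1) // 2, n_trials // 2])
    congr = rng.permutation(base)
    if n_trials >= 8:
        for _ in range(100):
            pairs = set(zip(congr[:-1], congr[1:]))
            if len(pairs) == 4:
                break
            congr = rng.permutation(base)
    prev = np.concatenate([["none"], congr[:-1]])
    trial_type = np.where(prev == "none", "first",
                          np.char.add(prev.astype(str), congr.astype(str)))
    valence = rng.permutation(
        np.array(["happy", "fearful"]).repeat([(n_trials + 1) // 2, n_trials // 2]))
    gaps = soa_seconds + jitter_seconds * rng.random(n_trials)
    onsets = initial_offset_seconds + np.concatenate([[0.0], np.cumsum(gaps[1:])])
    return pd.DataFrame({
        "trial_index": np.arange(n_trials),
        "onset_seconds": onsets,
        "duration_seconds": trial_duration_seconds,
        "congruency": congr,
        "prev_congruency": prev,
        "trial_type": trial_type,
        "valence": valence,
        "rt_ms": np.nan,
        "accuracy": np.nan,
    })


def simulate_behavior(trials: pd.DataFrame, effects: BehaviorConfig,
                      seed) -> pd.DataFrame:
    """Fill in reaction times and accuracies.

    RT = baseline + congruency effect (on incongruent trials)
    + half the congruency-sequence effect (+ on CI, − on II)
    + valence effect (on fearful faces) + Gaussian noise, truncated > 50 ms.
    Errors are Bernoulli with a higher rate on incongruent trials.
    """
    effects.validate()
    rng = _rng(seed)
    out = trials.copy()
    n = len(out)
    is_i = (out["congruency"] == "I").to_numpy()
    tt = out["trial_type"].to_numpy()
    rt = np.full(n, effects.baseline_ms)
    rt += effects.congruency_ms * is_i
    rt += (effects.cse_ms / 2.0) * (tt == "CI")
    rt -= (effects.cse_ms / 2.0) * (tt == "II")
    rt += effects.valence_ms * (out["valence"] == "fearful").to_numpy()
    rt = rt + effects.noise_sd_ms * rng.standard_normal(n)
    rt = np.maximum(rt, 50.0)
    err_p = np.where(is_i, effects.error_rate_incongruent,
                     effects.error_rate_congruent)
    out["rt_ms"] = rt
    out["accuracy"] = (rng.random(n) >= err_p).astype(int)
    return out


# ---------------------------------------------------------------------------
# functional volumes

def make_masks(config: CohortConfig) -> dict[str, np.ndarray]:
    """Probabilistic masks from the ROI layout (Gaussian membership profile)."""
    grid = np.asarray(config.grid_shape)
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in grid], indexing="ij")
    masks = {}
    for name, roi in config.roi_layout.items():
        d2 = ((ii - roi.center[0]) ** 2 + (jj - roi.center[1]) ** 2
              + (kk - roi.center[2]) ** 2).astype(float)
        sd = roi.radius / 2.0
        prob = roi.peak * np.exp(-d2 / (2.0 * sd ** 2))
        prob[d2 > roi.radius ** 2] = 0.0
        masks[name] = prob
    return masks


def _ar1_noise(rng, n_scans: int, n_vox: int, sigma: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise, marginal sd ``sigma``, shape (n_scans, n_vox)."""
    if sigma == 0.0:
        return np.zeros((n_scans, n_vox))
    innov_sd = sigma * np.sqrt(1.0 - phi ** 2)
    e = innov_sd * rng.standard_normal((n_scans, n_vox))
    e[0] = sigma * rng.standard_normal(n_vox)
    return signal.lfilter([1.0], [1.0, -phi], e, axis=0)


def simulate_bold(trials: pd.DataFrame, config: CohortConfig, truth: Mapping,
                  seed):
    """Generate the 4D functional volume plus masks and nuisance series.

    Returns ``(bold, masks, motion, blink_regressor)``.  ``truth`` must hold
    ``lc_amplitude`` (the CI − II effect, signal units) and may hold
    ``ppi_coupling`` (amplitude of an LC-seed × CI interaction injected into
    the amygdala).
    """
    rng = _rng(seed)
    grid = tuple(config.grid_shape)
    n_vox = int(np.prod(grid))
    n_scans = config.n_scans
    masks = make_masks(config)

    design = build_design(trials, config.tr_seconds, n_scans,
                          nuisance=None, hp_cutoff_s=None)
    cond_cols = {name: design.X[:, i] for i, name in enumerate(design.names)
                 if design.is_condition[i]}
    any_trial = sum(cond_cols.values())

    a = float(truth["lc_amplitude"])
    ppi_c = float(truth.get("ppi_coupling", 0.0))

    # condition amplitude per voxel: nuclei respond to every trial; the LC
    # signal support (1SD mask) additionally carries the CI > II difference
    amp_common = np.zeros(n_vox)
    for name in NUCLEI:
        amp_common[masks[name].ravel() > 0] = config.common_evoked
    lc_support = masks["lc_1sd"].ravel() > 0
    amyg_support = masks["amygdala"].ravel() > 0

    sigs = np.outer(any_trial, amp_common)  # (n_scans, n_vox)
    lc_diff = np.zeros(n_vox)
    lc_diff[lc_support] = a
    ci = cond_cols.get("CI", np.zeros(n_scans))
    ii = cond_cols.get("II", np.zeros(n_scans))
    sigs += np.outer(ci - ii, lc_diff) / 2.0

    # clean LC seed series (for the planted PPI interaction)
    lc_series_clean = any_trial * config.common_evoked + (ci - ii) * a / 2.0
    if ppi_c != 0.0:
        inter = (lc_series_clean - lc_series_clean.mean()) * ci
        sigs[:, amyg_support] += ppi_c * inter[:, None]

    # noise: AR(1) everywhere + shared physiological components + motion drift
    noise = _ar1_noise(rng, n_scans, n_vox, config.noise.sigma,
                       config.noise.ar1_phi)

    t = np.arange(n_scans) * config.tr_seconds
    csf_vox = masks["csf"].ravel() > 0
    nuclei_vox = amp_common > 0
    for amp, f in zip(config.noise.physio_amps, config.noise.physio_freqs_hz):
        if amp == 0.0:
            continue
        comp = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        comp = comp + 0.3 * _ar1_noise(rng, n_scans, 1, 1.0, 0.8)[:, 0]
        comp = (comp - comp.mean()) / comp.std()
        gains = rng.uniform(0.8, 1.2, int(csf_vox.sum()))
        noise[:, csf_vox] += amp * np.outer(comp, gains)
        noise[:, nuclei_vox] += config.noise.physio_leak * amp * comp[:, None]

    motion = np.cumsum(0.02 * rng.standard_normal((n_scans, 6)), axis=0)
    if config.noise.motion_coupling != 0.0 and config.noise.sigma > 0:
        m1 = motion[:, 0]
        sd = m1.std()
        if sd > 0:
            noise += config.noise.motion_coupling * ((m1 - m1.mean()) / sd)[:, None]

    blink = _ar1_noise(rng, n_scans, 1, 1.0, 0.5)[:, 0] if config.noise.sigma > 0 \
        else np.zeros(n_scans)

    bold = config.baseline_signal + sigs + noise
    return bold.T.reshape(grid + (n_scans,)), masks, motion, blink


# ---------------------------------------------------------------------------
# pupil

def _evoked_kernel(fs: float) -> np.ndarray:
    """Sustained dilation kernel: raised-cosine ramp over [0, 1.5] s, unit
    plateau to 5 s, raised-cosine decay to 7 s.  Peak (= plateau) is 1, so
    configured amplitudes read as evoked-window values."""
    t = np.arange(0.0, 7.0, 1.0 / fs)
    k = np.zeros_like(t)
    ramp = (t >= 0) & (t < 1.5)
    k[ramp] = 0.5 * (1 - np.cos(np.pi * t[ramp] / 1.5))
    k[(t >= 1.5) & (t < 5.0)] = 1.0
    dec = (t >= 5.0)
    k[dec] = 0.5 * (1 + np.cos(np.pi * (t[dec] - 5.0) / 2.0))
    return k


def _conflict_kernel(fs: float) -> np.ndarray:
    """Early conflict-detection component: raised-cosine bump on [0, 0.9] s,
    unit peak at 0.45 s.  Kept short so that a trial's conflict surplus has
    fully decayed before the *next* trial's pre-trial analysis window —
    otherwise the fixed previous-trial congruency of CI/II trials would leak
    a systematic offset into the pre-trial contrast."""
    t = np.arange(0.0, 0.9, 1.0 / fs)
    return 0.5 * (1 - np.cos(2 * np.pi * t / 0.9))


def _pretrial_kernel(fs: float) -> tuple[np.ndarray, int]:
    """Pre-trial carry-over plateau on [−3.5, −1.0] s with raised-cosine
    edges on [−4, −3.5] and [−1.0, −0.5]; returns (kernel, offset_samples)
    where the kernel starts ``offset_samples`` before the onset sample."""
    t = np.arange(-4.0, -0.5, 1.0 / fs)
    k = np.zeros_like(t)
    up = (t >= -4.0) & (t < -3.5)
    k[up] = 0.5 * (1 - np.cos(np.pi * (t[up] + 4.0) / 0.5))
    k[(t >= -3.5) & (t < -1.0)] = 1.0
    down = (t >= -1.0)
    k[down] = 0.5 * (1 + np.cos(np.pi * (t[down] + 1.0) / 0.5))
    return k, int(round(4.0 * fs))


def _compose_event_signal(onsets, trial_types, congruency, fs: float, n: int,
                          base: float, cse: float, conflict: float,
                          pre: float) -> np.ndarray:
    """Deterministic event-locked pupil signal for given raw amplitudes."""
    ek = _evoked_kernel(fs)
    ck = _conflict_kernel(fs)
    pk, pk_offset = _pretrial_kernel(fs)
    trace = np.zeros(n)
    evoked_amp = (base + (cse / 2.0) * ((trial_types == "CI").astype(float)
                                        - (trial_types == "II").astype(float)))
    conflict_amp = (conflict / 2.0) * np.where(congruency == "I", 1.0, -1.0)
    for on, amp, camp, typ in zip(onsets, evoked_amp, conflict_amp, trial_types):
        i0 = int(round(on * fs))
        seg = min(len(ek), n - i0)
        if seg > 0:
            trace[i0:i0 + seg] += amp * ek[:seg]
        seg = min(len(ck), n - i0)
        if seg > 0:
            trace[i0:i0 + seg] += camp * ck[:seg]
        if typ == "II" and pre != 0.0:
            j0 = i0 - pk_offset
            ks, js = (0, j0) if j0 >= 0 else (-j0, 0)
            seg = min(len(pk) - ks, n - js)
            if seg > 0:
                trace[js:js + seg] += pre * pk[ks:ks + seg]
    return trace


@lru_cache(maxsize=8)
def _insitu_compensation(fs: float, soa: float, jitter: float,
                         offset: float) -> tuple[float, float, float]:
    """In-situ attenuation of configured pupil effects under the standard
    0.05–4 Hz analysis band-pass.

    The high-pass removes a noticeable fraction of slow sustained responses
    (roughly cutoff × feature width), and with overlapping trials the
    residual attenuation differs from the isolated-kernel value.  A
    deterministic noiseless reference schedule is therefore pushed through
    the filter cascade and epoched, and each unit effect's recovered size is
    measured; injected amplitudes are divided by these factors so that
    configured effect sizes read as post-pipeline (z-unit) values.
    Returns ``(f_cse_current, f_pre_window, f_conflict_peak)``.
    """
    from .pupil import (CUR_WINDOW_MS, PRE_WINDOW_MS, condition_contrast,
                        epoch, _window_slice)

    trials = generate_trial_sequence(200, 12345, soa_seconds=soa,
                                     jitter_seconds=jitter,
                                     initial_offset_seconds=offset)
    onsets = trials["onset_seconds"].to_numpy(float)
    tt = trials["trial_type"].to_numpy()
    congr = trials["congruency"].to_numpy()
    n = int(round((onsets[-1] + 8.0) * fs))
    sos_hp = signal.butter(3, 0.05, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(3, 4.0, btype="lowpass", fs=fs, output="sos")

    def measure(base, cse, conflict, pre):
        x = _compose_event_signal(onsets, tt, congr, fs, n, base, cse,
                                  conflict, pre)
        x = signal.sosfiltfilt(sos_lp, signal.sosfiltfilt(sos_hp, x))
        df = pd.DataFrame({"time_ms": np.arange(n) * 1000.0 / fs, "pupil": x,
                           "blink_flag": 0, "run": 1})
        return epoch(df, trials)

    def windows(es):
        diff = condition_contrast(es, "CI", "II")
        cur = float(diff[_window_slice(es.times_ms, CUR_WINDOW_MS)].mean())
        pre = float(diff[_window_slice(es.times_ms, PRE_WINDOW_MS)].mean())
        return cur, pre

    # response matrix of (current-window, pre-window) CI−II means to unit
    # cse and unit pre-carry-over injections, including filter cross-talk
    a11, a21 = windows(measure(0.0, 1.0, 0.0, 0.0))
    a12, a22 = windows(measure(0.0, 0.0, 0.0, 1.0))

    es = measure(0.0, 0.0, 1.0, 0.0)
    f_conf = float(condition_contrast(es, "I", "C").max())
    return ((a11, a12), (a21, a22)), f_conf


def simulate_pupil(trials: pd.DataFrame, config: CohortConfig,
                   seed) -> pd.DataFrame:
    """250 Hz pupil trace with event-locked dilations and blink gaps.

    Incongruent trials evoke larger dilations than congruent ones; II trials
    carry a pre-trial elevation (conflict carry-over from the preceding
    incongruent trial) and a reduced evoked response relative to CI.  Noise
    is band-limited (smooth) so that configured z-unit effect sizes survive
    the 0.05–4 Hz analysis band; blinks are contiguous NaN gaps flagged in
    ``blink_flag``.
    """
    p = config.pupil
    fs = p.fs_hz
    onsets = trials["onset_seconds"].to_numpy(float)
    if len(onsets) == 0:
        raise InvalidArgumentError("no trials")
    duration = float(onsets[-1] + 8.0)
    n = int(round(duration * fs))
    if n <= 0:
        raise InvalidArgumentError("zero-length trace")
    rng = _rng(seed)
    t = np.arange(n) / fs

    trace = np.zeros(n)
    # slow drift (mostly removed by the 0.05 Hz high-pass downstream)
    for f in (0.008, 0.015):
        trace += p.drift_sd * np.sin(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    # band-limited noise: white at 8 Hz, cubic-smoothed to the sample grid
    coarse_n = int(np.ceil(duration * 8.0)) + 4
    coarse = rng.standard_normal(coarse_n)
    cs = CubicSpline(np.arange(coarse_n) / 8.0, coarse)
    smooth = cs(t)
    trace += p.noise_sd * smooth / max(smooth.std(), 1e-12)

    A, f_conf = _insitu_compensation(
        fs, config.soa_seconds, config.jitter_seconds,
        config.initial_offset_seconds)
    # injected (cse, pre) amplitudes solving for the configured post-pipeline
    # window effects: current-window CI−II = cse_evoked, pre-window = −carryover
    inj = np.linalg.solve(np.asarray(A),
                          [p.cse_evoked, -p.pre_carryover])
    trace += _compose_event_signal(
        onsets, trials["trial_type"].to_numpy(),
        trials["congruency"].to_numpy(), fs, n,
        base=p.base_evoked,
        cse=float(inj[0]),
        conflict=p.conflict_effect / f_conf,
        pre=float(inj[1]))

    blink_flag = np.zeros(n, dtype=int)
    if p.blink_rate_hz > 0:
        n_blinks = rng.poisson(p.blink_rate_hz * duration)
        starts = np.sort(rng.uniform(0, duration, n_blinks))
        for s in starts:
            d = rng.uniform(*p.blink_dur_ms) / 1000.0
            i0, i1 = int(s * fs), min(int((s + d) * fs), n)
            blink_flag[i0:i1] = 1
    trace = trace.copy()
    trace[blink_flag == 1] = np.nan

    return pd.DataFrame({
        "time_ms": (np.arange(n) * (1000.0 / fs)).round(3),
        "pupil": trace,
        "blink_flag": blink_flag,
        "run": 1,
    })


# ---------------------------------------------------------------------------
# symptoms

def simulate_symptoms(lc_amplitudes: np.ndarray, config: CohortConfig,
                      seed) -> pd.DataFrame:
    """Longitudinal STAI/PHQ panel with copula-controlled LC coupling.

    A Gaussian copula links the rank-normal scores of the true LC amplitudes
    to a shared latent symptom-change factor at Pearson level
    ``2·sin(π·rho_s/6)``, which yields Spearman ``rho_s`` between amplitude
    and mean change.  Both instruments' changes are affine in the latent
    (plus a small instrument-specific offset and an antisymmetric t1/t2
    split that cancels in the mean), so the configured rank coupling carries
    through to the derived change scores up to integer rounding.
    """
    amps = np.asarray(lc_amplitudes, dtype=float)
    n = len(amps)
    rho_s = config.symptom_coupling_rho
    rng = _rng(seed)
    ranks = stats.rankdata(amps, method="average")
    z1 = stats.norm.ppf((ranks - 0.5) / n)
    z1 = z1 / max(z1.std(), 1e-12)
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    latent = r * z1 + np.sqrt(max(0.0, 1.0 - r ** 2)) * rng.standard_normal(n)

    def panel(t0_mean, t0_sd, lo, hi, scale, drift, inst_sd, split_sd):
        t0 = np.clip(np.round(t0_mean + t0_sd * rng.standard_normal(n)), lo, hi)
        inst = inst_sd * rng.standard_normal(n)
        split = split_sd * rng.standard_normal(n)
        mean_change = drift + scale * latent + inst
        t1 = np.round(t0 + mean_change + split)
        t2 = np.round(t0 + mean_change - split)
        return t0.astype(int), np.clip(t1, lo, hi * 2).astype(int), \
            np.clip(t2, lo, hi * 2).astype(int)

    stai = panel(35, 8, 20, 80, scale=5.0, drift=4.0, inst_sd=0.75, split_sd=2.0)
    phq = panel(4, 2.5, 0, 27, scale=2.5, drift=1.5, inst_sd=0.4, split_sd=1.2)
    return pd.DataFrame({
        "subject": np.arange(1, n + 1),
        "STAI_t0": stai[0], "STAI_t1": stai[1], "STAI_t2": stai[2],
        "PHQ_t0": phq[0], "PHQ_t1": phq[1], "PHQ_t2": phq[2],
        "pretrauma": np.clip(np.round(10 + 4 * rng.standard_normal(n)), 0, None).astype(int),
        "age": np.clip(np.round(24 + 2.5 * rng.standard_normal(n)), 18, 40).astype(int),
        "gender": rng.choice(["f", "m"], n),
    })


# ---------------------------------------------------------------------------
# whole-cohort assembly

def generate_subject(config: CohortConfig, subject_id: int, streams: Mapping,
                     truth: Mapping) -> SubjectDataset:
    trials = generate_trial_sequence(
        config.n_trials, np.random.default_rng(streams["trials"]),
        soa_seconds=config.soa_seconds, jitter_seconds=config.jitter_seconds,
        initial_offset_seconds=config.initial_offset_seconds,
        trial_duration_seconds=config.trial_duration_seconds,
        imbalance_cap=config.imbalance_cap)
    trials = simulate_behavior(trials, config.behavior,
                               np.random.default_rng(streams["behavior"]))
    bold, masks, motion, blink = simulate_bold(
        trials, config, truth, np.random.default_rng(streams["bold"]))
    pupil = simulate_pupil(trials, config,
                           np.random.default_rng(streams["pupil"]))
    return SubjectDataset(subject_id=subject_id, trials=trials, bold=bold,
                          masks=masks, motion=motion, blink_regressor=blink,
                          pupil=pupil, truth=dict(truth))


def _draw_truths(config: CohortConfig, amp_ss) -> list[dict]:
    rng = np.random.default_rng(amp_ss)
    amps = config.lc_amplitude_mean + config.lc_amplitude_sd * \
        rng.standard_normal(config.n_subjects)
    coup = config.ppi_coupling_mean + config.ppi_coupling_sd * \
        rng.standard_normal(config.n_subjects)
    return [{
        "lc_amplitude": float(a),
        "ppi_coupling": float(c),
        "pupil_conflict": config.pupil.conflict_effect,
        "pupil_cse": config.pupil.cse_evoked,
        "pupil_pre_carryover": config.pupil.pre_carryover,
    } for a, c in zip(amps, coup)]


def generate_cohort_data(config: CohortConfig):
    """In-memory cohort: ``(subjects, symptoms)``."""
    config.validate()
    sub_streams, cohort_level = cohort_streams(config.seed, config.n_subjects)
    truths = _draw_truths(config, cohort_level["amplitudes"])
    subjects = [generate_subject(config, i + 1, sub_streams[i], truths[i])
                for i in range(config.n_subjects)]
    amps = np.array([t["lc_amplitude"] for t in truths])
    symptoms = simulate_symptoms(amps, config,
                                 np.random.default_rng(cohort_level["symptoms"]))
    return subjects, symptoms


def generate_cohort(config: CohortConfig, out_dir) -> dict:
    """Write a full cohort to disk; returns the manifest (also saved)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, symptoms = generate_cohort_data(config)
    config.to_yaml(out / "config.yaml")
    symptoms.to_csv(out / "symptoms.csv", index=False)
    manifest = {"n_subjects": config.n_subjects, "seed": config.seed,
                "subjects": {}, "files": {}}
    for sub in subjects:
        sdir = out / cio.subject_dirname(sub.subject_id)
        (sdir / "masks").mkdir(parents=True, exist_ok=True)
        cio.write_nifti(sdir / "bold.nii.gz", sub.bold, config.voxel_size_mm)
        for name, m in sub.masks.items():
            cio.write_nifti(sdir / "masks" / f"{name}.nii.gz", m,
                            config.voxel_size_mm)
        cio.write_events(sdir / "events.tsv", sub.trials)
        nuis = pd.DataFrame(sub.motion,
                            columns=[f"motion{i + 1}" for i in range(6)])
        nuis["blink"] = sub.blink_regressor
        nuis.to_csv(sdir / "nuisance.csv", index=False, float_format="%.8f")
        sub.pupil.to_csv(sdir / "pupil.csv", index=False, float_format="%.6f")
        cio.write_json(sdir / "truth.json", sub.truth)
        manifest["subjects"][cio.subject_dirname(sub.subject_id)] = sorted(
            str(p.relative_to(out)) for p in sdir.rglob("*") if p.is_file())
    for rel in ["symptoms.csv"] + [f for fl in manifest["subjects"].values() for f in fl]:
        if not rel.endswith(".nii.gz"):  # gzip headers embed mtime; hash text files only
            manifest["files"][rel] = cio.sha256_file(out / rel)
    cio.write_json(out / "manifest.json", manifest)
    return manifest
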