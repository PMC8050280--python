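"""Pupillometry: preprocessing, epoching, cluster statistics, and PDD.

Pupil diameter tracks noradrenergic arousal, so conflict-evoked dilation is
the peripheral readout of the same upregulation response probed in the
imaging data.  The pipeline is: linear interpolation over blink gaps, a
0.05 Hz high-pass followed by a 4 Hz low-pass (zero-phase, 3rd-order
Butterworth), run-wise z-scoring, epoching ±5 s around trial onsets, and
per-subject condition contrasts.  Group inference on contrast waveforms
uses a one-sample cluster-based permutation test with whole-subject
sign-flips and max-cluster-mass correction, which controls the family-wise
error over time points.

The pupil dilation distance (PDD) summarises the CI > II profile in one
scalar per subject: the CI−II difference averaged over the current-trial
window (1530–4862 ms) minus the same difference over the pre-trial window
(−3044 to −1222 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import InsufficientDataError, InvalidArgumentError, LcstressError

__all__ = [
    "EpochSet",
    "ClusterResult",
    "preprocess",
    "epoch",
    "condition_contrast",
    "cluster_permutation_test",
    "pdd",
    "PRE_WINDOW_MS",
    "CUR_WINDOW_MS",
]

FS_HZ = 250.0
EPOCH_HALF_S = 5.0
EPOCH_HALF_SAMPLES = int(EPOCH_HALF_S * FS_HZ)  # 1250
EPOCH_LEN = 2 * EPOCH_HALF_SAMPLES + 1          # 2501

PRE_WINDOW_MS = (-3044.0, -1222.0)
CUR_WINDOW_MS = (1530.0, 4862.0)


@dataclass(frozen=True)
class EpochSet:
    data: np.ndarray            # (n_epochs, 2501)
    trial_type: np.ndarray      # per-epoch trial_type label
    congruency: np.ndarray      # per-epoch C/I label
    times_ms: np.ndarray        # (2501,) −5000 … +5000
    n_dropped: int


@dataclass(frozen=True)
class ClusterResult:
    clusters: list              # (start_ms, end_ms, mass, corrected_p)
    t_series: np.ndarray
    threshold: float
    n_permutations: int


def preprocess(trace: pd.DataFrame, hp_hz: float = 0.05,
               lp_hz: float = 4.0) -> pd.DataFrame:
    """Blink interpolation, band-pass (high-pass then low-pass), run z-score."""
    out = trace.copy()
    sos_hp = signal.butter(3, hp_hz, btype="highpass", fs=FS_HZ, output="sos")
    sos_lp = signal.butter(3, lp_hz, btype="lowpass", fs=FS_HZ, output="sos")
    for run, idx in out.groupby("run").groups.items():
        x = out.loc[idx, "pupil"].to_numpy(float)
        flags = out.loc[idx, "blink_flag"].to_numpy() == 1
        bad = flags | ~np.isfinite(x)
        if bad.all():
            raise LcstressError(f"run {run!r} is fully blinked; unrecoverable")
        if len(x) < 20 * FS_HZ:
            raise InvalidArgumentError(
                f"run {run!r} shorter than 20 s; high-pass not meaningful")
        if bad.any():
            good = np.flatnonzero(~bad)
            x[bad] = np.interp(np.flatnonzero(bad), good, x[good])
        x = signal.sosfiltfilt(sos_hp, x)
        x = signal.sosfiltfilt(sos_lp, x)
        x = (x - x.mean()) / x.std(ddof=0)
        out.loc[idx, "pupil"] = x
    return out


def epoch(trace: pd.DataFrame, trials: pd.DataFrame) -> EpochSet:
    """Extract ±5 s epochs around trial onsets (2501 samples at 250 Hz).

    Trials whose window would cross a run edge are dropped and counted.
    """
    x = trace["pupil"].to_numpy(float)
    t_ms = trace["time_ms"].to_numpy(float)
    n = len(x)
    epochs, types, congrs = [], [], []
    dropped = 0
    for _, row in trials.iterrows():
        onset_ms = row["onset_seconds"] * 1000.0
        k = int(round((onset_ms - t_ms[0]) / (1000.0 / FS_HZ)))
        lo, hi = k - EPOCH_HALF_SAMPLES, k + EPOCH_HALF_SAMPLES
        if lo < 0 or hi >= n:
            dropped += 1
            continue
        epochs.append(x[lo:hi + 1])
        types.append(row["trial_type"])
        congrs.append(row["congruency"])
    if not epochs:
        raise InsufficientDataError("no epochs survive the edge rule")
    times = (np.arange(EPOCH_LEN) - EPOCH_HALF_SAMPLES) * (1000.0 / FS_HZ)
    return EpochSet(data=np.asarray(epochs), trial_type=np.asarray(types),
                    congruency=np.asarray(congrs), times_ms=times,
                    n_dropped=dropped)


def _select(epochs: EpochSet, label: str) -> np.ndarray:
    if label in ("C", "I"):
        sel = epochs.congruency == label
    else:
        sel = epochs.trial_type == label
    if not sel.any():
        raise InsufficientDataError(f"no epochs for condition {label!r}")
    return epochs.data[sel]


def condition_contrast(epochs: EpochSet, a: str, b: str) -> np.ndarray:
    """Per-subject difference waveform mean(a) − mean(b), per time point."""
    return _select(epochs, a).mean(axis=0) - _select(epochs, b).mean(axis=0)


def cluster_permutation_test(waveforms: np.ndarray, n_perm: int = 1000,
                             alpha: float = 0.05, seed=None) -> ClusterResult:
    """One-sample cluster-mass permutation test across subjects.

    Pointwise two-sided one-sample t against zero; contiguous runs with
    |t| above the critical t at ``alpha`` form clusters whose mass is the
    sum of |t|.  The null is built from whole-subject sign flips, taking the
    maximum cluster mass per permutation; corrected
    p = (1 + #{null ≥ observed}) / (1 + n_perm).
    """
    W = np.asarray(waveforms, dtype=float)
    n_sub, n_time = W.shape
    if n_sub < 8:
        raise InvalidArgumentError("need at least 8 subjects")
    rng = np.random.default_rng(seed)
    thresh = stats.t.ppf(1.0 - alpha / 2.0, df=n_sub - 1)

    msq = np.mean(W ** 2, axis=0)  # invariant under sign flips

    def t_series(mean):
        var = (msq - mean ** 2) * n_sub / (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return mean / np.sqrt(var / n_sub)

    def clusters_of(ts):
        """Contiguous supra-threshold runs as (start, stop, mass) tuples."""
        supra = np.abs(ts) > thresh
        edges = np.diff(supra.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        stops = np.flatnonzero(edges == -1) + 1
        if supra[0]:
            starts = np.concatenate([[0], starts])
        if supra[-1]:
            stops = np.concatenate([stops, [n_time]])
        return [(int(i), int(j) - 1, float(np.abs(ts[i:j]).sum()))
                for i, j in zip(starts, stops)]

    def max_mass(ts):
        supra = np.abs(ts) > thresh
        if not supra.any():
            return 0.0
        edges = np.diff(supra.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        if supra[0]:
            starts = np.concatenate([[0], starts])
        csum = np.concatenate([[0.0], np.cumsum(np.where(supra, np.abs(ts), 0.0))])
        stops = np.flatnonzero(edges == -1) + 1
        if supra[-1]:
            stops = np.concatenate([stops, [n_time]])
        return float(np.max(csum[stops] - csum[starts]))

    obs_t = t_series(W.mean(axis=0))
    obs_clusters = clusters_of(obs_t)

    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    means = flips @ W / n_sub
    null_max = np.array([max_mass(t_series(m)) for m in means])

    dt_ms = 1000.0 / FS_HZ
    results = []
    for i, j, mass in obs_clusters:
        pval = (1.0 + np.sum(null_max >= mass)) / (1.0 + n_perm)
        results.append((i * dt_ms, j * dt_ms, mass, float(pval)))
    return ClusterResult(clusters=results, t_series=obs_t,
                         threshold=float(thresh), n_permutations=n_perm)


def _window_slice(times_ms: np.ndarray, window_ms) -> slice:
    """Inclusive window snapped outward to the 4 ms sample grid."""
    lo, hi = window_ms
    if lo < times_ms[0] or hi > times_ms[-1]:
        raise InvalidArgumentError(f"window {window_ms} outside the epoch")
    dt = 1000.0 / FS_HZ
    i0 = int(np.floor((lo - times_ms[0]) / dt))
    i1 = int(np.ceil((hi - times_ms[0]) / dt))
    return slice(i0, i1 + 1)


def pdd(epochs: EpochSet, pre_window_ms=PRE_WINDOW_MS,
        cur_window_ms=CUR_WINDOW_MS) -> float:
    """Pupil dilation distance: (CI−II) current-window mean minus
    (CI−II) pre-trial-window mean."""
    diff = condition_contrast(epochs, "CI", "II")
    pre = diff[_window_slice(epochs.times_ms, pre_window_ms)].mean()
    cur = diff[_window_slice(epochs.times_ms, cur_window_ms)].mean()
    return float(cur - pre)
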