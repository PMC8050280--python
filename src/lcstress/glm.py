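"""First-level event-related GLM with AR(1) prewhitening.

The model regresses every voxel's BOLD time series on HRF-convolved
condition indicators for the four trial-sequence conditions (CC, CI, IC,
II; first trials of a run go into a throw-away column), plus unconvolved
nuisance series (motion, blinks, CSF principal components), an optional
discrete-cosine high-pass set, and an intercept.  Temporal autocorrelation
is modelled as a global first-order autoregressive process estimated from
pooled OLS residuals; data and design are prewhitened with the exact AR(1)
Cholesky factor and refit.  The CI > II contrast on the whitened fit is
the conflict-upregulation response used throughout the pipeline, and the
psychophysiological-interaction (PPI) design adds seed and seed-by-condition
columns to quantify condition-dependent coupling with a seed region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import (
    DegenerateDesignError,
    GridMismatchError,
    InvalidArgumentError,
)
from .roi import weighted_roi_average

__all__ = [
    "CONDITIONS",
    "DesignMatrix",
    "GlmResult",
    "ContrastMap",
    "canonical_hrf",
    "build_design",
    "csf_nuisance_pcs",
    "fit_glm_ar1",
    "contrast_tmap",
    "contrast_vector",
    "ppi_design",
    "ppi_coupling",
]

#: condition column order; "first" absorbs run-initial trials with no
#: previous-trial label
CONDITIONS = ("CC", "CI", "IC", "II", "first")


@dataclass(frozen=True)
class DesignMatrix:
    names: tuple[str, ...]
    X: np.ndarray  # (n_scans, n_regressors)
    is_condition: np.ndarray  # bool per column
    tr: float
    hp_cutoff_s: float | None = None

    def __post_init__(self):
        if len(self.names) != self.X.shape[1]:
            raise InvalidArgumentError("names/column mismatch")
        if len(set(self.names)) != len(self.names):
            raise InvalidArgumentError("duplicated design column names")

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def zero_columns(self) -> np.ndarray:
        """Boolean mask of all-zero columns (e.g. an unrealised condition)."""
        return ~np.any(self.X != 0.0, axis=0)


@dataclass(frozen=True)
class GlmResult:
    design: DesignMatrix
    betas: np.ndarray        # (n_regressors, *grid)
    sigma2: np.ndarray       # (*grid) residual variance on whitened fit
    phi: float               # pooled AR(1) coefficient
    df: float                # effective residual degrees of freedom
    xtx_inv: np.ndarray      # (k, k) inverse Gram of the whitened design

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.betas.shape[1:]


@dataclass(frozen=True)
class ContrastMap:
    contrast: np.ndarray
    effect: np.ndarray  # (*grid)
    t: np.ndarray       # (*grid)
    df: float


def canonical_hrf(tr_seconds: float, oversampling: int = 16,
                  duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma haemodynamic response function, sampled at
    ``tr_seconds / oversampling`` resolution and normalised to unit peak.

    Response gamma has shape 6 / scale 1 s (mode 5 s), undershoot shape 16
    (mode 15 s), undershoot ratio 1/6.
    """
    if tr_seconds <= 0:
        raise InvalidArgumentError("tr must be positive")
    dt = tr_seconds / oversampling
    t = np.arange(0.0, duration_s, dt)

    def gamma_pdf(x, shape):
        with np.errstate(divide="ignore"):
            logpdf = (shape - 1) * np.log(x) - x - gammaln(shape)
        out = np.exp(logpdf)
        out[x <= 0] = 0.0
        return out

    h = gamma_pdf(t, 6.0) - gamma_pdf(t, 16.0) / 6.0
    return h / h.max()


def _dct_highpass(n_scans: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis (constant excluded), SPM convention."""
    order = int(np.floor(2.0 * n_scans * tr / cutoff_s))
    if order < 1:
        return np.empty((n_scans, 0))
    n = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_scans))
            for k in range(1, order + 1)]
    return np.column_stack(cols)


def build_design(trials, tr: float, n_scans: int,
                 nuisance: Mapping[str, np.ndarray] | None = None,
                 hp_cutoff_s: float | None = 128.0,
                 oversampling: int = 16) -> DesignMatrix:
    """HRF-convolved condition regressors + nuisance + drift basis + intercept.

    ``trials`` is a trial table with columns ``onset_seconds``,
    ``duration_seconds`` and ``trial_type``; event indicators are built on a
    ``tr / oversampling`` grid, convolved with the canonical HRF and sampled
    at scan acquisition times.  Nuisance series are appended unconvolved.
    """
    if tr <= 0 or n_scans <= 0:
        raise InvalidArgumentError("tr and n_scans must be positive")
    onsets = np.asarray(trials["onset_seconds"], dtype=float)
    durations = np.asarray(trials["duration_seconds"], dtype=float)
    types = np.asarray(trials["trial_type"], dtype=object)
    total_t = n_scans * tr
    if np.any(onsets >= total_t):
        raise InvalidArgumentError("trial onsets extend beyond the acquisition")

    dt = tr / oversampling
    n_fine = int(np.ceil(total_t / dt))
    hrf = canonical_hrf(tr, oversampling)
    scan_idx = (np.arange(n_scans) * tr / dt).round().astype(int)

    # scale so one isolated event of the typical duration peaks at 1:
    # condition betas then read as peak evoked amplitudes in signal units
    ref_dur = float(np.median(durations)) if len(durations) else 1.0
    ref_box = np.ones(max(1, int(round(ref_dur / dt))))
    ref_peak = float(np.convolve(ref_box, hrf).max())

    cols, names, is_cond = [], [], []
    for cond in CONDITIONS:
        sel = types == cond
        if cond == "first" and not sel.any():
            continue
        stick = np.zeros(n_fine)
        for on, du in zip(onsets[sel], durations[sel]):
            i0 = int(round(on / dt))
            i1 = max(i0 + 1, int(round((on + du) / dt)))
            stick[i0:min(i1, n_fine)] = 1.0
        conv = np.convolve(stick, hrf)[:n_fine] / ref_peak
        cols.append(conv[scan_idx])
        names.append(cond)
        is_cond.append(True)

    if nuisance:
        for name, series in nuisance.items():
            series = np.asarray(series, dtype=float)
            if series.shape != (n_scans,):
                raise InvalidArgumentError(
                    f"nuisance series {name!r} has length {series.shape}, expected {n_scans}")
            cols.append(series)
            names.append(name)
            is_cond.append(False)

    if hp_cutoff_s is not None:
        drift = _dct_highpass(n_scans, tr, hp_cutoff_s)
        for j in range(drift.shape[1]):
            cols.append(drift[:, j])
            names.append(f"dct{j + 1}")
            is_cond.append(False)

    cols.append(np.ones(n_scans))
    names.append("intercept")
    is_cond.append(False)

    return DesignMatrix(tuple(names), np.column_stack(cols),
                        np.asarray(is_cond), tr, hp_cutoff_s)


def csf_nuisance_pcs(bold: np.ndarray, csf_mask: np.ndarray, k: int = 5,
                     mask_threshold: float = 0.5):
    """First ``k`` principal components of the demeaned CSF voxel-by-time
    matrix, ordered by explained variance, unit normalised.

    Returns ``(components, explained_variance)`` with components shaped
    ``(n_scans, k)``.
    """
    bold = np.asarray(bold, dtype=float)
    csf_mask = np.asarray(csf_mask, dtype=float)
    if bold.shape[:-1] != csf_mask.shape:
        raise GridMismatchError("bold and CSF mask grids differ")
    vox = csf_mask > mask_threshold
    n_vox = int(vox.sum())
    if n_vox < k:
        raise InvalidArgumentError(
            f"only {n_vox} CSF voxels above threshold, need at least k={k}")
    ts = bold[vox].T  # (n_scans, n_vox)
    ts = ts - ts.mean(axis=0)
    u, s, _ = np.linalg.svd(ts, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if rank < k:
        raise InvalidArgumentError(f"CSF matrix rank {rank} < k={k}")
    comps = u[:, :k]
    expl = s[:k] ** 2 / (ts.shape[0] - 1)
    return comps, expl


def _whiten_matrix_apply(arr: np.ndarray, phi: float) -> np.ndarray:
    """Apply the exact AR(1) whitening transform along axis 0."""
    out = np.empty_like(arr)
    out[0] = arr[0] * np.sqrt(1.0 - phi ** 2)
    out[1:] = arr[1:] - phi * arr[:-1]
    return out


def fit_glm_ar1(bold: np.ndarray, design: DesignMatrix,
                ar1: str | float = "pooled") -> GlmResult:
    """Fit the GLM with AR(1) prewhitening.

    The AR coefficient is estimated once from OLS residuals pooled over all
    voxels (``ar1="pooled"``, the default), or fixed to a given float.  Data
    and design are then whitened with the exact AR(1) Cholesky factor and
    refit by OLS.
    """
    bold = np.asarray(bold, dtype=float)
    grid = bold.shape[:-1]
    n_scans = bold.shape[-1]
    X = design.X
    k = X.shape[1]
    if design.n_scans != n_scans:
        raise InvalidArgumentError("design and data disagree on n_scans")
    if n_scans <= k + 5:
        raise InvalidArgumentError("too few scans for the number of regressors")

    Y = bold.reshape(-1, n_scans).T  # (n_scans, n_vox)
    keep = ~design.zero_columns()
    Xr = X[:, keep]
    rank = np.linalg.matrix_rank(Xr)
    if rank < Xr.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")

    Q, R = np.linalg.qr(Xr)
    beta_ols = np.linalg.solve(R, Q.T @ Y)
    resid = Y - Xr @ beta_ols

    if ar1 == "pooled":
        num = float(np.sum(resid[1:] * resid[:-1]))
        den = float(np.sum(resid[:-1] ** 2))
        phi = 0.0 if den == 0.0 else num / den
        phi = float(np.clip(phi, -0.95, 0.95))
    else:
        phi = float(ar1)
        if not abs(phi) < 1:
            raise InvalidArgumentError("|phi| must be < 1")

    Xw = _whiten_matrix_apply(Xr, phi)
    Yw = _whiten_matrix_apply(Y, phi)
    gram = Xw.T @ Xw
    try:
        xtx_inv_r = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("singular whitened design") from exc
    Qw, Rw = np.linalg.qr(Xw)
    beta_w = np.linalg.solve(Rw, Qw.T @ Yw)
    resid_w = Yw - Xw @ beta_w
    df = float(n_scans - Xr.shape[1])
    sigma2 = np.einsum("ij,ij->j", resid_w, resid_w) / df

    betas_full = np.zeros((k, Y.shape[1]))
    betas_full[keep] = beta_w
    xtx_inv = np.full((k, k), np.nan)
    xtx_inv[np.ix_(keep, keep)] = xtx_inv_r

    return GlmResult(design=design,
                     betas=betas_full.reshape((k,) + grid),
                     sigma2=sigma2.reshape(grid),
                     phi=phi, df=df, xtx_inv=xtx_inv)


def contrast_vector(design: DesignMatrix, weights: Mapping[str, float]) -> np.ndarray:
    """Build a contrast vector from ``{column_name: weight}``."""
    c = np.zeros(len(design.names))
    for name, w in weights.items():
        c[design.index(name)] = w
    return c


def contrast_tmap(glm: GlmResult, contrast: Sequence[float]) -> ContrastMap:
    """Effect and t maps for a linear contrast of the whitened fit."""
    c = np.asarray(contrast, dtype=float)
    k = glm.betas.shape[0]
    if c.shape != (k,):
        raise InvalidArgumentError(f"contrast length {c.shape} != {k} regressors")
    if not np.any(c):
        raise InvalidArgumentError("contrast vector is all zero")
    zero_cols = glm.design.zero_columns()
    if np.any(c[zero_cols] != 0.0):
        raise InvalidArgumentError("contrast touches an all-zero design column")
    effect = np.tensordot(c, glm.betas, axes=(0, 0))
    quad = float(c @ np.nan_to_num(glm.xtx_inv) @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(quad * glm.sigma2)
    return ContrastMap(contrast=c, effect=effect, t=t, df=glm.df)


def ppi_design(design: DesignMatrix, seed_series: np.ndarray) -> DesignMatrix:
    """Append seed main effect and seed-by-CI / seed-by-II interactions.

    Interactions are element-wise products of the mean-centred seed time
    course with the convolved CI and II condition regressors.
    """
    seed = np.asarray(seed_series, dtype=float)
    if seed.shape != (design.n_scans,):
        raise InvalidArgumentError("seed series length must equal n_scans")
    if np.ptp(seed) == 0.0:
        raise DegenerateDesignError("constant seed time course")
    seed_c = seed - seed.mean()
    ci = design.X[:, design.index("CI")]
    ii = design.X[:, design.index("II")]
    extra = np.column_stack([seed_c, seed_c * ci, seed_c * ii])
    names = design.names + ("ppi_seed", "ppi_seed_x_CI", "ppi_seed_x_II")
    is_cond = np.concatenate([design.is_condition, [False, True, True]])
    return DesignMatrix(names, np.column_stack([design.X, extra]),
                        is_cond, design.tr, design.hp_cutoff_s)


def ppi_coupling(bold: np.ndarray, design_ppi: DesignMatrix,
                 roi_mask: np.ndarray) -> float:
    """Weighted-ROI average of the seed-by-CI minus seed-by-II effect."""
    glm = fit_glm_ar1(bold, design_ppi)
    c = contrast_vector(design_ppi, {"ppi_seed_x_CI": 1.0, "ppi_seed_x_II": -1.0})
    cmap = contrast_tmap(glm, c)
    return weighted_roi_average(cmap.effect, roi_mask)
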