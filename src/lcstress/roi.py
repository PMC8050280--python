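"""Probabilistic-ROI signal extraction and quality control.

Small brainstem nuclei cannot be summarised by hard masks without either
diluting or truncating the signal, so ROI values are probability-weighted
averages: every voxel's value is weighted by its membership probability in
the ROI.  Temporal signal-to-noise (tSNR) maps provide the accompanying
quality check, and a leave-one-subject-out (LOSO) sphere extraction gives
per-subject values that are unbiased by the subject's own data: each
subject's value is read from a sphere centred on the group peak computed
from all *other* subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, InvalidArgumentError, InvalidMaskError

__all__ = [
    "weighted_roi_average",
    "tsnr_map",
    "roi_tsnr",
    "loso_sphere_extract",
    "LosoExtraction",
]


def weighted_roi_average(values: np.ndarray, mask: np.ndarray) -> float:
    """Probability-weighted average ``sum(w*x)/sum(w)`` over voxels with w > 0.

    NaN voxels (e.g. zero-variance tSNR sentinels) are excluded together
    with their weight.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if values.shape != mask.shape:
        raise GridMismatchError(
            f"value grid {values.shape} != mask grid {mask.shape}")
    if np.any(mask < 0) or np.any(mask > 1):
        raise InvalidMaskError("mask probabilities must lie in [0, 1]")
    sel = (mask > 0) & np.isfinite(values)
    wsum = float(mask[sel].sum())
    if wsum <= 0.0:
        raise InvalidMaskError("mask has no positive-weight finite voxels")
    return float(np.sum(mask[sel] * values[sel]) / wsum)


def tsnr_map(bold: np.ndarray) -> np.ndarray:
    """Per-voxel temporal SNR: mean of the time series divided by its
    standard deviation (sample sd, ddof=1).  Zero-variance voxels map to NaN.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.shape[-1] < 3:
        raise InvalidArgumentError("tSNR needs at least 3 time points")
    mean = bold.mean(axis=-1)
    sd = bold.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = mean / sd
    out[sd == 0.0] = np.nan
    return out


def roi_tsnr(tsnr: np.ndarray, mask: np.ndarray) -> float:
    """Weighted-average tSNR over an ROI, ignoring zero-variance sentinels."""
    return weighted_roi_average(tsnr, mask)


@dataclass(frozen=True)
class LosoExtraction:
    values: np.ndarray        # (n_subjects,)
    peaks: np.ndarray         # (n_subjects, 3) voxel indices
    clipped: np.ndarray       # bool per subject: sphere clipped at grid edge


def _sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    r_vox = radius_mm / voxel_size_mm
    r_int = int(np.floor(r_vox))
    ax = np.arange(-r_int, r_int + 1)
    di, dj, dk = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = di ** 2 + dj ** 2 + dk ** 2 <= r_vox ** 2 + 1e-12
    return np.column_stack([di[keep], dj[keep], dk[keep]])


def loso_sphere_extract(contrast_maps: np.ndarray, search_mask: np.ndarray,
                        voxel_size_mm: float, radius_mm: float = 5.0) -> LosoExtraction:
    """Leave-one-subject-out peak/sphere extraction.

    For every subject ``s``: average the maps of all other subjects, find the
    arg-max voxel within ``search_mask`` (> 0), and return subject ``s``'s
    mean value inside a sphere of ``radius_mm`` around that voxel (voxel
    centre within radius, inclusive; ties broken by lowest linear index).
    Spheres extending beyond the grid are clipped, with a per-subject flag.
    """
    maps = np.asarray(contrast_maps, dtype=float)
    if maps.ndim != 4:
        raise InvalidArgumentError("contrast_maps must be (n_subjects, x, y, z)")
    n_sub = maps.shape[0]
    if n_sub < 3:
        raise InvalidArgumentError("need at least 3 subjects")
    grid = maps.shape[1:]
    mask = np.asarray(search_mask, dtype=float)
    if mask.shape != grid:
        raise GridMismatchError("search mask grid mismatch")
    in_mask = mask > 0
    if not in_mask.any():
        raise InvalidMaskError("empty search mask")

    offsets = _sphere_offsets(radius_mm, voxel_size_mm)
    total = maps.sum(axis=0)
    flat_mask = in_mask.ravel()
    values = np.empty(n_sub)
    peaks = np.empty((n_sub, 3), dtype=int)
    clipped = np.zeros(n_sub, dtype=bool)
    for s in range(n_sub):
        group = (total - maps[s]) / (n_sub - 1)
        flat = np.where(flat_mask, group.ravel(), -np.inf)
        peak = np.unravel_index(int(np.argmax(flat)), grid)
        coords = offsets + np.asarray(peak)
        inside = np.all((coords >= 0) & (coords < np.asarray(grid)), axis=1)
        if not inside.all():
            clipped[s] = True
            coords = coords[inside]
        values[s] = maps[s][tuple(coords.T)].mean()
        peaks[s] = peak
    return LosoExtraction(values=values, peaks=peaks, clipped=clipped)
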