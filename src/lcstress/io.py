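"""On-disk cohort layout and readers/writers.

A cohort directory holds one sub-directory per subject::

    cohort/
      manifest.json
      symptoms.csv                   # one row per subject
      sub-01/
        bold.nii.gz                  # 4D functional volume
        masks/<roi>.nii.gz           # 3D probabilistic masks
        events.tsv                   # onset, duration, trial_type, valence, rt_ms, accuracy
        nuisance.csv                 # 6 motion series + blink regressor
        pupil.csv                    # time_ms, pupil, blink_flag, run
        truth.json                   # generator ground truth (never read by analyses)

Analysis modules consume these files through the readers here; the
``truth.json`` ground truth is read only by tests and reports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "subject_dirname",
    "write_nifti",
    "read_nifti",
    "write_events",
    "read_events",
    "sha256_file",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type", "valence", "rt_ms", "accuracy"]


def subject_dirname(subject_id: int) -> str:
    return f"sub-{subject_id:02d}"


def write_nifti(path: Path, data: np.ndarray, voxel_size_mm: float) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def write_events(path: Path, trials: pd.DataFrame) -> None:
    out = pd.DataFrame({
        "onset": trials["onset_seconds"],
        "duration": trials["duration_seconds"],
        "trial_type": trials["trial_type"],
        "valence": trials["valence"],
        "rt_ms": trials["rt_ms"],
        "accuracy": trials["accuracy"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: Path) -> pd.DataFrame:
    """Read a BIDS-style events table back into the internal trial-table form.

    Congruency and previous-trial congruency are reconstructed from the
    trial_type labels (second letter = current trial, first = previous).
    """
    tab = pd.read_csv(path, sep="\t")
    tt = tab["trial_type"].astype(str)
    congr = np.where(tt == "first", "?", tt.str[1])
    prev = np.where(tt == "first", "none", tt.str[0])
    # a run-initial trial still has its own congruency; recover it from the
    # following trial's previous-congruency label where possible
    congr = congr.astype(object)
    for i in np.flatnonzero(congr == "?"):
        congr[i] = prev[i + 1] if i + 1 < len(prev) else "C"
    return pd.DataFrame({
        "trial_index": np.arange(len(tab)),
        "onset_seconds": tab["onset"].to_numpy(float),
        "duration_seconds": tab["duration"].to_numpy(float),
        "congruency": congr,
        "prev_congruency": prev,
        "trial_type": tt,
        "valence": tab["valence"],
        "rt_ms": tab["rt_ms"].to_numpy(float),
        "accuracy": tab["accuracy"].to_numpy(float),
    })


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
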