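"""Head-motion metrics from rigid-body realignment parameters.

A resting-state fMRI scan yields one six-vector of rigid-body realignment
parameters per TR (repetition time): three rotations in degrees (roll,
pitch, yaw) and three translations in mm (dS, dL, dP), in the AFNI
convention.  Motion per TR is summarised by norms of the backward first
difference of that six-vector:

- **ENORM** — the Euclidean (L2) norm of the difference, AFNI's standard
  per-TR motion index;
- **FD** (framewise displacement) — the L1 norm of the same difference.

Degrees and millimetres are combined without rescaling, matching the AFNI
pipeline.  Scan-level summaries are the means of these per-TR values over
the T−1 differences; the natural log of mean ENORM is the dependent
variable of the downstream prediction models (the raw mean is strongly
right-skewed across subjects).

FD ≥ ENORM holds elementwise (L1 ≥ L2) and is therefore preserved by the
scan-level means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotionParams",
    "MotionSummary",
    "enorm_series",
    "fd_series",
    "summarize_motion",
    "read_1d",
    "write_1d",
    "motion_summary_table",
    "write_summary_tsv",
    "read_summary_tsv",
]

#: canonical column order (AFNI .1D): rotations in degrees, then translations in mm
PARAM_COLUMNS = ("roll", "pitch", "yaw", "dS", "dL", "dP")


class InvalidMotionInput(ValueError):
    """Raised for malformed realignment-parameter input."""


@dataclass(frozen=True)
class MotionParams:
    """A T×6 realignment-parameter time series for one subject.

    Columns are ``roll, pitch, yaw`` (degrees) then ``dS, dL, dP`` (mm).
    ``tr_seconds`` is carried as metadata only; no metric depends on it.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 6:
            raise InvalidMotionInput(
                f"expected a T x 6 matrix, got shape {values.shape}"
            )
        if values.shape[0] < 2:
            raise InvalidMotionInput("need at least 2 TRs to form a difference")
        if not np.all(np.isfinite(values)):
            raise InvalidMotionInput("realignment parameters must be finite")
        if not self.tr_seconds > 0:
            raise InvalidMotionInput("tr_seconds must be positive")
        object.__setattr__(self, "values", values)

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MotionSummary:
    """Scan-level motion summary for one subject.

    ``log_mean_enorm`` / ``log_mean_fd`` are natural logs and are NaN when
    the corresponding mean is zero (a zero-motion scan); callers must treat
    NaN as "undefined", not as a numeric value — see :func:`motion_summary_table`.
    """

    subject_id: str
    mean_enorm: float
    mean_fd: float
    log_mean_enorm: float
    log_mean_fd: float
    n_trs: int

    @property
    def log_defined(self) -> bool:
        return not math.isnan(self.log_mean_enorm)


def _diffs(params: MotionParams) -> np.ndarray:
    return np.diff(params.values, axis=0)


def enorm_series(params: MotionParams) -> np.ndarray:
    """Per-TR ENORM: L2 norm of the backward difference of the six parameters.

    Returns T−1 non-negative values (one per inter-TR interval).
    """
    return np.linalg.norm(_diffs(params), axis=1)


def fd_series(params: MotionParams) -> np.ndarray:
    """Per-TR framewise displacement: L1 norm of the same backward difference."""
    return np.abs(_diffs(params)).sum(axis=1)


def summarize_motion(params: MotionParams) -> MotionSummary:
    """Average the per-TR metrics over the T−1 differences and take natural logs.

    The average runs over the T−1 difference values only (no padded leading
    zero), so the summary does not depend on a padding convention.  For a
    zero-motion scan the means are 0 and the log fields are NaN sentinels.
    """
    enorm = enorm_series(params)
    fd = fd_series(params)
    mean_enorm = float(enorm.mean())
    mean_fd = float(fd.mean())
    return MotionSummary(
        subject_id=params.subject_id,
        mean_enorm=mean_enorm,
        mean_fd=mean_fd,
        log_mean_enorm=math.log(mean_enorm) if mean_enorm > 0 else math.nan,
        log_mean_fd=math.log(mean_fd) if mean_fd > 0 else math.nan,
        n_trs=params.n_trs,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

# How to map a file's column order/units onto the canonical AFNI layout.
# SPM realignment files are (tx ty tz rx ry rz) with rotations in radians;
# FSL MCFLIRT .par files are (rx ry rz tx ty tz) with rotations in radians.
_DIALECTS = {
    "afni": (np.arange(6), False),
    "spm": (np.array([3, 4, 5, 0, 1, 2]), True),
    "fsl": (np.array([0, 1, 2, 3, 4, 5]), True),
}


def read_1d(
    path,
    order: str = "afni",
    tr_seconds: float = 2.0,
    subject_id: str | None = None,
) -> MotionParams:
    """Read a whitespace-delimited six-column realignment file.

    Lines starting with ``#`` are ignored.  ``order`` selects the input
    dialect: ``afni`` (rotations in degrees first — canonical), ``spm``
    (translations first, rotations in radians) or ``fsl`` (rotations in
    radians first).  Non-AFNI dialects are reordered and their rotations
    converted to degrees.
    """
    if order not in _DIALECTS:
        raise ValueError(f"unknown column-order dialect {order!r}")
    raw = np.loadtxt(path, comments="#", ndmin=2)
    if raw.ndim != 2 or raw.shape[1] != 6:
        raise InvalidMotionInput(
            f"{path}: expected 6 columns, got shape {raw.shape}"
        )
    perm, radians = _DIALECTS[order]
    values = raw[:, perm]
    if radians:
        values = values.copy()
        values[:, :3] = np.degrees(values[:, :3])
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    return MotionParams(values=values, tr_seconds=tr_seconds, subject_id=subject_id)


def write_1d(params: MotionParams, path) -> None:
    """Write a MotionParams series as an AFNI-style six-column text file."""
    header = "  ".join(PARAM_COLUMNS)
    np.savetxt(path, params.values, fmt="%.6f", header=header)


_SUMMARY_COLUMNS = [
    "subject_id",
    "mean_enorm",
    "mean_fd",
    "log_mean_enorm",
    "log_mean_fd",
    "n_trs",
]


def motion_summary_table(
    cohort: Iterable[MotionParams], drop_zero_motion: bool = True
) -> pd.DataFrame:
    """Summarise a cohort of motion series into one row per subject.

    Zero-motion scans have an undefined log outcome; by default they are
    dropped with a warning (they cannot enter the log-scale models), never
    silently imputed.
    """
    rows = [summarize_motion(p) for p in cohort]
    frame = pd.DataFrame([r.__dict__ for r in rows], columns=_SUMMARY_COLUMNS)
    if drop_zero_motion:
        zero = ~np.array([r.log_defined for r in rows])
        if zero.any():
            dropped = frame.loc[zero, "subject_id"].tolist()
            warnings.warn(
                f"dropping {len(dropped)} zero-motion scan(s) with undefined "
                f"log motion: {dropped}",
                stacklevel=2,
            )
            frame = frame.loc[~zero].reset_index(drop=True)
    return frame


def write_summary_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
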