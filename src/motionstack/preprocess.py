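"""Feature-table container, k-nearest-neighbour imputation and residualization.

The predictor table is a subjects × variables matrix with a block label per
variable (``physical`` vs ``psychological``; psychological variables carry a
``drug``/``nondrug`` sub-label) and possibly missing cells.  Missing values
are imputed once, globally, by k-nearest neighbours *without using the
outcome*, before any cross-validation.

Residualization isolates the psychological variance not shared with the
physical block: each psychological variable is replaced by its OLS residual
on an intercept plus all physical variables, fitted on the full sample, and
the physical variables are dropped.  The full-sample fit (outside any CV
loop) reproduces the analysis procedure being studied; it is a known,
deliberate leakage caveat, discussed in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "FeatureTable",
    "UnimputableError",
    "knn_impute",
    "residualize_psychological",
]

BLOCKS = ("physical", "psychological")


class UnimputableError(ValueError):
    """Raised when a variable cannot be imputed (e.g. missing everywhere)."""


@dataclass
class FeatureTable:
    """Subjects × predictors with block labels and (possibly) missing cells.

    ``values`` is a DataFrame indexed by subject id; ``block`` maps every
    column to ``physical``/``psychological``; ``subblock`` maps psychological
    columns to ``drug``/``nondrug``.
    """

    values: pd.DataFrame
    block: dict[str, str]
    subblock: dict[str, str] = field(default_factory=dict)
    max_missing_fraction: float = 0.0625

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        labelled = set(self.block)
        if set(cols) != labelled:
            missing = set(cols) - labelled
            extra = labelled - set(cols)
            raise ValueError(
                f"block labels must partition the variables "
                f"(unlabelled: {sorted(missing)}, unknown: {sorted(extra)})"
            )
        bad = {v: b for v, b in self.block.items() if b not in BLOCKS}
        if bad:
            raise ValueError(f"unknown block labels: {bad}")
        frac = self.missing_fraction()
        over = frac[frac > self.max_missing_fraction + 1e-12]
        if len(over):
            raise ValueError(
                "variables exceed the allowed missing fraction "
                f"({self.max_missing_fraction}): {dict(over.round(4))}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def variables_in_block(self, block: str) -> list[str]:
        return [v for v in self.variables if self.block[v] == block]

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=0)

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def subset(self, which: str) -> "FeatureTable":
        """Restrict to a predictor subset: 'physical', 'psychological' or 'all'."""
        if which == "all":
            return self
        if which not in BLOCKS:
            raise ValueError(f"unknown subset {which!r}")
        keep = self.variables_in_block(which)
        if not keep:
            raise ValueError(f"subset {which!r} selects zero variables")
        return FeatureTable(
            values=self.values[keep].copy(),
            block={v: self.block[v] for v in keep},
            subblock={v: s for v, s in self.subblock.items() if v in keep},
            max_missing_fraction=self.max_missing_fraction,
        )

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- I/O: CSV of values + TSV sidecar of block labels ------------------

    def to_csv(self, values_path, sidecar_path) -> None:
        self.values.to_csv(values_path, index_label="subject_id")
        rows = [
            {
                "variable": v,
                "block": self.block[v],
                "subblock": self.subblock.get(v, ""),
            }
            for v in self.variables
        ]
        pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)

    @classmethod
    def from_csv(
        cls, values_path, sidecar_path, max_missing_fraction: float = 0.0625
    ) -> "FeatureTable":
        values = pd.read_csv(values_path, index_col="subject_id")
        values.index.name = None
        side = pd.read_csv(sidecar_path, sep="\t").fillna("")
        block = dict(zip(side["variable"], side["block"]))
        subblock = {
            v: s for v, s in zip(side["variable"], side["subblock"]) if s
        }
        return cls(
            values=values,
            block=block,
            subblock=subblock,
            max_missing_fraction=max_missing_fraction,
        )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def knn_impute(table: FeatureTable, k: int = 5) -> FeatureTable:
    """Impute missing cells by the mean of the k nearest subjects.

    Distances are Euclidean on z-scored variables, computed over the
    variables observed in common for each subject pair and rescaled by the
    number of shared dimensions (Gower-style normalisation), so subjects
    with different missingness patterns remain comparable.  The outcome is
    never consulted.  Observed cells pass through unchanged, which also
    makes the operation idempotent on complete tables.  Distance ties are
    broken by subject order (deterministic).
    """
    if not 1 <= k < table.n_subjects:
        raise ValueError(f"k must satisfy 1 <= k < n_subjects, got {k}")
    all_missing = table.values.columns[table.values.isna().all(axis=0)]
    if len(all_missing):
        raise UnimputableError(
            f"variable(s) missing for every subject: {list(all_missing)}"
        )
    if (~table.values.notna()).all(axis=1).any():
        empty = table.values.index[table.values.isna().all(axis=1)]
        raise UnimputableError(
            f"subject(s) with no observed values: {list(empty)}"
        )
    if table.is_complete:
        return FeatureTable(
            values=table.values.copy(),
            block=dict(table.block),
            subblock=dict(table.subblock),
            max_missing_fraction=table.max_missing_fraction,
        )

    x = table.matrix()
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / sd
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    z_full = imputer.fit_transform(z)
    filled = z_full * sd + mean
    # restore observed cells exactly (no float round-trip drift)
    observed = ~np.isnan(x)
    filled[observed] = x[observed]
    values = pd.DataFrame(
        filled, index=table.values.index, columns=table.values.columns
    )
    return FeatureTable(
        values=values,
        block=dict(table.block),
        subblock=dict(table.subblock),
        max_missing_fraction=table.max_missing_fraction,
    )


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------


def residualize_psychological(table: FeatureTable) -> FeatureTable:
    """Replace psychological variables by their OLS residuals on the physical block.

    Each psychological variable is regressed on an intercept plus all
    physical variables over the full sample; its residual vector replaces
    it.  Physical variables are dropped from the output.  Residuals are, by
    construction, orthogonal to the physical block (sample correlations
    ~1e-12).
    """
    if not table.is_complete:
        raise ValueError("residualization requires an imputed (complete) table")
    phys = table.variables_in_block("physical")
    psych = table.variables_in_block("psychological")
    if not phys:
        raise ValueError("no physical variables to residualize against")
    if not psych:
        raise ValueError("no psychological variables to residualize")

    x = np.column_stack(
        [np.ones(table.n_subjects), table.values[phys].to_numpy(dtype=float)]
    )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns by greedy QR-style elimination
        collinear = []
        kept = [0]  # intercept
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                collinear.append(phys[j - 1])
        raise ValueError(
            f"physical block is rank-deficient; collinear variable(s): {collinear}"
        )

    y = table.values[psych].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    values = pd.DataFrame(resid, index=table.values.index, columns=psych)
    return FeatureTable(
        values=values,
        block={v: "psychological" for v in psych},
        subblock={v: s for v, s in table.subblock.items() if v in psych},
        max_missing_fraction=table.max_missing_fraction,
    )
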