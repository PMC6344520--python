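"""Univariate comparison statistics, partial dependence, and the study report.

Complements the ensemble analysis with the mass-univariate view common in
the motion-QC literature — per-variable Pearson correlations with the
log-motion outcome, Fisher-z 95% confidence intervals and
Benjamini–Hochberg FDR-corrected p-values — plus partial-dependence curves
for selected predictors, and the four-model variance-partition report
(physical-only / psychological-only / combined / residualized
psychological).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureTable, knn_impute, residualize_psychological
from .stacking import (
    CVPlan,
    ModelSummary,
    StackedEnsemble,
    nested_cv,
    summarize,
)

__all__ = [
    "PDPCurve",
    "StudyReport",
    "univariate_correlations",
    "partial_dependence",
    "study_report",
    "top_importance_table",
    "write_report",
]

MODEL_SUBSETS = ("physical", "psychological", "all", "residualized")


# ---------------------------------------------------------------------------
# univariate correlations
# ---------------------------------------------------------------------------


def univariate_correlations(table: FeatureTable, y: np.ndarray) -> pd.DataFrame:
    """Pearson r per variable vs the outcome, with Fisher-z CIs and BH-FDR.

    Returns one row per variable: ``r``, ``ci_lo``/``ci_hi`` (95%,
    Fisher z; degenerate when |r| = 1), raw ``p``, ``p_fdr``
    (Benjamini–Hochberg across all variables in the table), and ``sign``
    (``+``/``-``).  A zero-variance variable is reported with
    ``defined = False`` and NaN statistics rather than silently dropped.
    """
    if not table.is_complete:
        raise ValueError("correlations require an imputed (complete) table")
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    rows = []
    for var in table.variables:
        x = table.values[var].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append(
                dict(variable=var, r=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                     p=np.nan, sign="", defined=False)
            )
            continue
        r, p = stats.pearsonr(x, y)
        if abs(r) >= 1.0 - 1e-15:  # degenerate: CI collapses to the point
            lo = hi = r
        else:
            z = math.atanh(r)
            half = 1.96 / math.sqrt(n - 3)
            lo, hi = math.tanh(z - half), math.tanh(z + half)
        rows.append(
            dict(variable=var, r=float(r), ci_lo=float(lo), ci_hi=float(hi),
                 p=float(p), sign="+" if r >= 0 else "-", defined=True)
        )
    frame = pd.DataFrame(rows).set_index("variable")
    frame["p_fdr"] = np.nan
    defined = frame["defined"].to_numpy()
    if defined.any():
        _, p_adj, _, _ = multipletests(
            frame.loc[defined, "p"].to_numpy(), method="fdr_bh"
        )
        frame.loc[defined, "p_fdr"] = p_adj
    return frame


# ---------------------------------------------------------------------------
# partial dependence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PDPCurve:
    variable: str
    grid: np.ndarray
    mean_prediction: np.ndarray


def partial_dependence(
    ensemble: StackedEnsemble,
    X: np.ndarray,
    variable,
    n_grid: int = 20,
    variable_names: list[str] | None = None,
) -> PDPCurve:
    """Mean stacked prediction as one predictor sweeps a quantile grid.

    ``variable`` is a column index, or a name if ``variable_names`` is
    given.  A quantile grid (not a uniform one) keeps skewed predictors
    well covered.  All other predictors stay at their observed values.
    """
    X = np.asarray(X, dtype=float)
    if isinstance(variable, str):
        if variable_names is None:
            raise ValueError("variable given by name but no variable_names")
        if variable not in variable_names:
            raise ValueError(f"variable {variable!r} is not in the model")
        j = variable_names.index(variable)
        name = variable
    else:
        j = int(variable)
        if not 0 <= j < X.shape[1]:
            raise ValueError(f"variable index {j} is not in the model")
        name = variable_names[j] if variable_names else f"x{j}"
    grid = np.unique(np.quantile(X[:, j], np.linspace(0.0, 1.0, n_grid)))
    means = np.empty(grid.size)
    work = X.copy()
    for i, g in enumerate(grid):
        work[:, j] = g
        means[i] = float(ensemble.predict(work).mean())
    return PDPCurve(variable=name, grid=grid, mean_prediction=means)


# ---------------------------------------------------------------------------
# the four-model study report
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """Per-subset model summaries plus the univariate correlation table."""

    summaries: dict[str, ModelSummary]
    correlations: pd.DataFrame
    plan: CVPlan


def study_report(
    table: FeatureTable,
    y: np.ndarray,
    plan: CVPlan,
    learners=None,
    subsets: tuple[str, ...] = MODEL_SUBSETS,
    knn_k: int = 5,
    repeats_by_subset: dict[str, int] | None = None,
) -> StudyReport:
    """Run the full variance-partition analysis on one cohort.

    Imputes the table once globally (if needed), runs repeated nested CV
    for each requested predictor subset — ``residualized`` means the
    psychological variables after OLS residualization on the physical
    block — and summarizes R² and stacked VI per subset.
    ``repeats_by_subset`` optionally overrides ``plan.n_repeats`` for
    individual subsets (e.g. fewer repeats for secondary models).
    """
    unknown = set(subsets) - set(MODEL_SUBSETS)
    if unknown:
        raise ValueError(f"unknown subset(s): {sorted(unknown)}")
    y = np.asarray(y, dtype=float).ravel()
    complete = table if table.is_complete else knn_impute(table, k=knn_k)
    repeats_by_subset = repeats_by_subset or {}

    summaries: dict[str, ModelSummary] = {}
    for which in subsets:
        n_rep = repeats_by_subset.get(which, plan.n_repeats)
        sub_plan = CVPlan(
            k_inner=plan.k_inner,
            k_outer=plan.k_outer,
            n_repeats=n_rep,
            n_search=plan.n_search,
            seed=plan.seed,
        )
        if which == "residualized":
            resid = residualize_psychological(complete)
            reps = nested_cv(resid, y, sub_plan, learners=learners, subset="all")
            variables = resid.variables
        else:
            reps = nested_cv(complete, y, sub_plan, learners=learners, subset=which)
            variables = (
                complete.variables
                if which == "all"
                else complete.variables_in_block(which)
            )
        summaries[which] = summarize(reps, variables=variables)

    correlations = univariate_correlations(complete, y)
    return StudyReport(summaries=summaries, correlations=correlations, plan=plan)


def top_importance_table(summary: ModelSummary, n_top: int = 10) -> pd.DataFrame:
    """Variables ranked by mean stacked VI, with 95% CIs; top ``n_top`` flagged."""
    order = np.argsort(summary.mean_vi)[::-1]
    frame = pd.DataFrame(
        {
            "variable": [summary.variables[i] for i in order],
            "mean_vi": summary.mean_vi[order],
            "ci_lo": summary.ci_vi[order, 0],
            "ci_hi": summary.ci_vi[order, 1],
        }
    )
    frame["top"] = [i < n_top for i in range(len(frame))]
    return frame


def write_report(report: StudyReport, out_dir) -> None:
    """Write machine-readable TSVs: model R², per-variable VI, correlations."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r2_rows = [
        {
            "model": which,
            "mean_r2": s.mean_r2,
            "ci_lo": s.ci_r2[0],
            "ci_hi": s.ci_r2[1],
            "n_repeats": s.n_repeats,
        }
        for which, s in report.summaries.items()
    ]
    pd.DataFrame(r2_rows).to_csv(out / "model_r2.tsv", sep="\t", index=False)
    vi_rows = []
    for which, s in report.summaries.items():
        table = top_importance_table(s, n_top=10)
        table.insert(0, "model", which)
        vi_rows.append(table)
    pd.concat(vi_rows).to_csv(
        out / "variable_importance.tsv", sep="\t", index=False
    )
    report.correlations.to_csv(
        out / "univariate_correlations.tsv", sep="\t", na_rep="NA"
    )
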