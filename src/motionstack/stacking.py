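"""Repeated nested cross-validation with R²-weighted stacking.

The inference engine behind the variance-partition analysis:

- **inner loop** (default 10-fold, on each outer-training set): random-search
  candidate hyperparameters per learner, scored by fold-level R²; the
  one-SE rule picks the simplest setting within one standard error of the
  best; the learner is refit on the full outer-training set;
- **stacking**: base predictions are combined by an arithmetic mean
  weighted by each learner's expected out-of-sample R² — the R² of its
  pooled inner-CV predictions at the chosen setting (negative R² clamped
  to zero; uniform fallback when all are non-positive);
- **outer loop**: stacked predictions on the held-out folds are pooled over
  the whole sample and compared with the observed outcome,
  R² = 1 − SS_res/SS_tot;
- **repeats** (default 20 fresh partitions): the mean and mean ± 1.96·SD of
  the repeat-level R² (and of each stacked variable importance) form the
  reported point estimates and 95% confidence intervals.

Variable importance is computed on the outer-training refits, min-max
scaled to [0, 100] per learner per fold, combined with the stacking
weights, then averaged across outer folds within a repeat.

Seeding: the plan's master seed spawns per-repeat, per-fold and per-learner
child seeds through ``numpy.random.SeedSequence``, so results are
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold

from .learners import FittedBase, Learner, make_learners
from .preprocess import FeatureTable

__all__ = [
    "CVPlan",
    "StackedEnsemble",
    "RepeatResult",
    "ModelSummary",
    "one_se_select",
    "tune_learner",
    "stack",
    "ensemble_predict",
    "stacked_vi",
    "nested_cv",
    "summarize",
    "pooled_r2",
]


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation design: fold counts, repeats, search breadth, master seed."""

    k_inner: int = 10
    k_outer: int = 10
    n_repeats: int = 20
    n_search: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_inner < 2 or self.k_outer < 2:
            raise ValueError("fold counts must be at least 2")
        if self.n_repeats < 1 or self.n_search < 1:
            raise ValueError("n_repeats and n_search must be positive")


@dataclass
class StackedEnsemble:
    """Six fitted base learners and their normalized stacking weights."""

    bases: list[FittedBase]
    weights: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return ensemble_predict(self, X)


@dataclass
class RepeatResult:
    """One nested-CV repeat: pooled outer predictions, R², stacked VI (0–100)."""

    pooled_predictions: np.ndarray
    r2: float
    stacked_vi: np.ndarray


@dataclass
class ModelSummary:
    """Across-repeat summary for one predictor subset."""

    mean_r2: float
    ci_r2: tuple[float, float]
    mean_vi: np.ndarray
    ci_vi: np.ndarray  # (p, 2)
    variables: list[str]
    n_repeats: int
    r2_values: np.ndarray = field(default_factory=lambda: np.empty(0))


def pooled_r2(y: np.ndarray, pred: np.ndarray) -> float:
    """R² = 1 − SS_res/SS_tot of pooled predictions against observations."""
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("outcome has zero variance")
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# one-SE rule
# ---------------------------------------------------------------------------


def _setting_hash(setting) -> int:
    return int.from_bytes(
        hashlib.sha256(repr(sorted(setting)).encode()).digest()[:8], "big"
    )


def one_se_select(
    cv_scores: Mapping, complexity_key: Callable[[dict], tuple]
):
    """Simplest hyperparameter setting within one SE of the best mean R².

    ``cv_scores`` maps a hashable setting (tuple of sorted ``(name, value)``
    pairs) to ``(mean_r2, se_r2)`` where the SE comes from the inner-fold
    scores (SD/√k).  Candidates with ``mean_r2 >= best_mean - best_se`` are
    ranked by ``complexity_key`` (smaller = simpler); remaining ties break
    on a deterministic hash of the setting.
    """
    if not cv_scores:
        raise ValueError("empty cross-validation score map")
    items = list(cv_scores.items())
    best_setting, (best_mean, best_se) = max(
        items, key=lambda kv: (kv[1][0], -_setting_hash(kv[0]))
    )
    threshold = best_mean - best_se
    candidates = [s for s, (m, _) in items if m >= threshold]
    return min(
        candidates, key=lambda s: (complexity_key(dict(s)), _setting_hash(s))
    )


def _freeze(hypers: dict) -> tuple:
    return tuple(sorted(hypers.items()))


# ---------------------------------------------------------------------------
# inner-loop tuning
# ---------------------------------------------------------------------------


def tune_learner(
    learner: Learner,
    X: np.ndarray,
    y: np.ndarray,
    k_inner: int,
    n_search: int,
    seed_seq: np.random.SeedSequence,
    compute_vi: bool = True,
) -> FittedBase:
    """Random search + k-fold inner CV + one-SE rule; refit on all rows.

    Returns the refit learner with ``train_r2_cv`` set to the chosen
    setting's mean inner-CV R² (the stacking weight input) and, optionally,
    its raw variable importance computed on the refit.
    """
    draw_seed, fit_seed, fold_seed, vi_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(4)
    )
    rng = np.random.default_rng(draw_seed)
    if learner.search_budget is not None:
        n_search = min(n_search, learner.search_budget)
    settings = learner.sample_hypers(rng, n_search, X.shape[1])

    kf = KFold(n_splits=k_inner, shuffle=True, random_state=fold_seed)
    folds = list(kf.split(X))
    scores: dict[tuple, tuple[float, float]] = {}
    cv_preds: dict[tuple, np.ndarray] = {}
    for hypers in settings:
        key = _freeze(hypers)
        if key in scores:
            continue
        fold_r2 = np.empty(len(folds))
        pooled = np.empty_like(y)
        for i, (tr, va) in enumerate(folds):
            model = learner.fit(X[tr], y[tr], hypers, seed=fit_seed)
            pooled[va] = learner.predict(model, X[va])
            fold_r2[i] = pooled_r2(y[va], pooled[va])
        scores[key] = (
            float(fold_r2.mean()),
            float(fold_r2.std(ddof=1) / math.sqrt(len(folds))),
        )
        cv_preds[key] = pooled

    chosen = one_se_select(scores, learner.complexity_key)
    hypers = dict(chosen)
    model = learner.fit(X, y, hypers, seed=fit_seed, final=True)
    # The stacking weight input is the R² of the *pooled* inner-CV
    # predictions of the chosen setting — one predicted value per
    # training row, exactly the per-learner prediction set the stacked
    # model is built from.  (The mean of fold-local R²s would carry a
    # ~1/n_fold negative offset from the tiny per-fold baselines.)
    fitted = FittedBase(
        learner=learner,
        hypers=hypers,
        model=model,
        train_r2_cv=pooled_r2(y, cv_preds[chosen]),
    )
    if compute_vi:
        fitted.vi_raw = np.asarray(
            learner.variable_importance(model, X, y, seed=vi_seed), dtype=float
        )
    return fitted


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------


def stack(bases: Sequence[FittedBase]) -> StackedEnsemble:
    """Weights ∝ max(inner-CV R², 0), normalized to the simplex.

    A weighted mean with negative weights is uninterpretable, so negative
    expected R² is clamped to zero; if every base is non-positive the
    weights fall back to uniform.
    """
    r2 = np.array([b.train_r2_cv for b in bases], dtype=float)
    clamped = np.maximum(r2, 0.0)
    total = clamped.sum()
    if total > 0:
        weights = clamped / total
    else:
        weights = np.full(len(bases), 1.0 / len(bases))
    return StackedEnsemble(bases=list(bases), weights=weights)


def ensemble_predict(ensemble: StackedEnsemble, X: np.ndarray) -> np.ndarray:
    preds = np.stack([b.predict(X) for b in ensemble.bases])
    return ensemble.weights @ preds


def _minmax_scale_vi(vi: np.ndarray) -> np.ndarray:
    span = float(vi.max() - vi.min())
    if span == 0:
        # a constant importance vector carries no ranking information
        return np.zeros_like(vi)
    return 100.0 * (vi - vi.min()) / span


def stacked_vi(
    bases: Sequence[FittedBase], weights: np.ndarray
) -> np.ndarray:
    """Weighted average of per-learner VI, each min-max scaled to [0, 100]."""
    scaled = np.stack([_minmax_scale_vi(b.vi_raw) for b in bases])
    return np.asarray(weights, dtype=float) @ scaled


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


def _resolve_design(table, y, subset):
    if isinstance(table, FeatureTable):
        sub = table.subset(subset) if subset is not None else table
        if not sub.is_complete:
            raise ValueError("feature table has missing cells; impute first")
        return sub.matrix(), sub.variables
    X = np.asarray(table, dtype=float)
    if subset not in (None, "all"):
        raise ValueError("block subsets require a FeatureTable input")
    return X, [f"x{j}" for j in range(X.shape[1])]


def nested_cv(
    table,
    y: np.ndarray,
    plan: CVPlan,
    learners: Sequence[Learner] | None = None,
    subset: str | None = None,
    audit_hook: Callable | None = None,
) -> list[RepeatResult]:
    """Repeated nested CV of the stacked ensemble on one predictor subset.

    ``table`` is a complete :class:`FeatureTable` (with ``subset`` one of
    ``physical``/``psychological``/``all``) or a plain matrix.  Each repeat
    draws a fresh outer partition; within each outer fold all learners are
    tuned by inner CV on the training rows only, stacked, and used to
    predict the held-out rows.  ``audit_hook(repeat, fold, train_idx,
    test_idx)`` is invoked per fold so callers can fingerprint the
    partition and verify that no outer-validation row enters training.
    """
    X, _variables = _resolve_design(table, y, subset)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("outcome length does not match the table")
    if X.shape[1] == 0:
        raise ValueError("predictor subset selects zero variables")
    if learners is None:
        learners = make_learners()

    master = np.random.SeedSequence(plan.seed)
    repeat_seqs = master.spawn(plan.n_repeats)
    results: list[RepeatResult] = []
    for rep, rep_seq in enumerate(repeat_seqs):
        outer_seed = int(rep_seq.generate_state(1)[0] % (2**31))
        kf = KFold(n_splits=plan.k_outer, shuffle=True, random_state=outer_seed)
        pooled = np.empty_like(y)
        fold_vis = []
        fold_seqs = rep_seq.spawn(plan.k_outer)
        for fold, ((train, test), fold_seq) in enumerate(
            zip(kf.split(X), fold_seqs)
        ):
            if audit_hook is not None:
                audit_hook(rep, fold, train, test)
            learner_seqs = fold_seq.spawn(len(learners))
            bases = [
                tune_learner(
                    lrn,
                    X[train],
                    y[train],
                    plan.k_inner,
                    plan.n_search,
                    seq,
                )
                for lrn, seq in zip(learners, learner_seqs)
            ]
            ensemble = stack(bases)
            pooled[test] = ensemble.predict(X[test])
            fold_vis.append(stacked_vi(bases, ensemble.weights))
        results.append(
            RepeatResult(
                pooled_predictions=pooled,
                r2=pooled_r2(y, pooled),
                stacked_vi=np.mean(fold_vis, axis=0),
            )
        )
    return results


def summarize(
    repeats: Sequence[RepeatResult], variables: Sequence[str] | None = None
) -> ModelSummary:
    """Mean and mean ± 1.96·SD of R² and VI across repeat-level values."""
    if len(repeats) == 0:
        raise ValueError("no repeats to summarize")
    r2 = np.array([r.r2 for r in repeats], dtype=float)
    vi = np.stack([r.stacked_vi for r in repeats])
    if len(repeats) == 1:
        warnings.warn("single repeat: confidence intervals are degenerate")
        sd_r2 = 0.0
        sd_vi = np.zeros(vi.shape[1])
    else:
        sd_r2 = float(r2.std(ddof=1))
        sd_vi = vi.std(axis=0, ddof=1)
    mean_r2 = float(r2.mean())
    mean_vi = vi.mean(axis=0)
    p = vi.shape[1]
    if variables is None:
        variables = [f"x{j}" for j in range(p)]
    return ModelSummary(
        mean_r2=mean_r2,
        ci_r2=(mean_r2 - 1.96 * sd_r2, mean_r2 + 1.96 * sd_r2),
        mean_vi=mean_vi,
        ci_vi=np.column_stack(
            [mean_vi - 1.96 * sd_vi, mean_vi + 1.96 * sd_vi]
        ),
        variables=list(variables),
        n_repeats=len(repeats),
        r2_values=r2,
    )
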