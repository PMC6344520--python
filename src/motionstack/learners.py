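"""Six base regression learners behind a uniform contract.

The ensemble combines elastic net (ENET), principal-component regression
(PCR), partial least squares (PLS), RBF support-vector regression (SVR),
random forest (RF) and a conditional inference forest (CF).  Every learner
exposes the same surface:

- ``sample_hypers(rng, n, p)`` — random-search draws from its
  hyperparameter space;
- ``complexity_key(hypers)`` — a total order over settings (smaller =
  simpler) used by the one-SE rule;
- ``fit(X, y, hypers, seed)`` / ``predict(model, X)``;
- ``variable_importance(model, X, y, seed)`` — the learner-specific VI:
  absolute standardized coefficients (ENET), loading-weighted absolute
  coefficients mapped back to predictors (PCR/PLS), out-of-bag permutation
  increase in MSE (RF/CF), and for SVR a model-free "filter": the R² of a
  per-feature loess (local quadratic) regression of the outcome on that
  feature alone.

Linear-family learners standardize predictors internally and return
predictions on the original outcome scale, so ensemble members are
exchangeable downstream.
"""

from __future__ import annotations

import math
import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "Learner",
    "FittedBase",
    "ENetLearner",
    "PCRLearner",
    "PLSLearner",
    "SVRLearner",
    "RFLearner",
    "CIForestLearner",
    "make_learners",
    "LEARNER_NAMES",
    "loess_filter_vi",
]

LEARNER_NAMES = ("ENET", "PCR", "PLS", "SVR", "RF", "CF")


class DegenerateOutcomeError(ValueError):
    """Raised when the outcome has zero variance."""


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X/y shape mismatch: {X.shape} vs {y.shape}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite (impute first)")
    if np.std(y) == 0:
        raise DegenerateOutcomeError("outcome has zero variance")
    return X, y


class Learner(ABC):
    """Uniform base-learner contract."""

    name: str
    #: optional per-learner cap on random-search draws (None = use plan value)
    search_budget: int | None = None

    @abstractmethod
    def sample_hypers(self, rng: np.random.Generator, n_draws: int, p: int) -> list[dict]:
        ...

    @abstractmethod
    def complexity_key(self, hypers: dict) -> tuple:
        """Total order over settings; lexicographically smaller = simpler."""

    @abstractmethod
    def fit(
        self, X: np.ndarray, y: np.ndarray, hypers: dict, seed: int = 0,
        final: bool = False,
    ):
        """Fit at one hyperparameter setting.

        ``final`` marks the refit on a full outer-training set (as opposed
        to a scoring fit inside the inner CV); ensemble learners may grow
        more trees there, since tree count is a variance knob rather than a
        tuned hyperparameter.
        """

    @abstractmethod
    def predict(self, model, X: np.ndarray) -> np.ndarray:
        ...

    @abstractmethod
    def variable_importance(
        self, model, X: np.ndarray, y: np.ndarray, seed: int = 0
    ) -> np.ndarray:
        """Non-negative relevance per predictor (length p, unscaled)."""

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} {self.name}>"


@dataclass
class FittedBase:
    """One tuned-and-fitted base learner inside an ensemble."""

    learner: Learner
    hypers: dict
    model: object
    train_r2_cv: float = math.nan  # expected out-of-sample R² from inner CV
    vi_raw: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.learner.predict(self.model, X)


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------


class ENetLearner(Learner):
    name = "ENET"

    def __init__(self, max_iter: int = 10000, search_budget: int | None = None):
        self.max_iter = max_iter
        self.search_budget = search_budget

    def sample_hypers(self, rng, n_draws, p):
        return [
            {
                "alpha": float(10.0 ** rng.uniform(-4, 0)),
                "l1_ratio": float(rng.uniform(0.0, 1.0)),
            }
            for _ in range(n_draws)
        ]

    def complexity_key(self, hypers):
        # heavier penalty is simpler; at equal penalty, sparser (more L1) is simpler
        return (-hypers["alpha"], -hypers["l1_ratio"])

    def fit(self, X, y, hypers, seed=0, final=False):
        X, y = _check_xy(X, y)
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "model",
                    ElasticNet(
                        alpha=hypers["alpha"],
                        l1_ratio=hypers["l1_ratio"],
                        max_iter=self.max_iter,
                    ),
                ),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence at extreme draws
            pipe.fit(X, y)
        return pipe

    def predict(self, model, X):
        return model.predict(np.asarray(X, dtype=float))

    def variable_importance(self, model, X, y, seed=0):
        return np.abs(model.named_steps["model"].coef_)


# ---------------------------------------------------------------------------
# principal-component regression
# ---------------------------------------------------------------------------


class PCRLearner(Learner):
    name = "PCR"

    def __init__(self, max_components: int = 30, search_budget: int | None = None):
        self.max_components = max_components
        self.search_budget = search_budget

    def sample_hypers(self, rng, n_draws, p):
        # component counts act on a ratio scale: sample log-uniformly so the
        # informative low-dimensional settings are well covered
        hi = min(self.max_components, p)
        import math as _m
        return [
            {"n_components": int(round(2.0 ** rng.uniform(0.0, _m.log2(hi))))}
            for _ in range(n_draws)
        ]

    def complexity_key(self, hypers):
        return (hypers["n_components"],)

    def fit(self, X, y, hypers, seed=0, final=False):
        X, y = _check_xy(X, y)
        k = min(hypers["n_components"], X.shape[1], X.shape[0] - 1)
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("pca", PCA(n_components=k, svd_solver="full")),
                ("model", LinearRegression()),
            ]
        )
        pipe.fit(X, y)
        return pipe

    def predict(self, model, X):
        return model.predict(np.asarray(X, dtype=float))

    def variable_importance(self, model, X, y, seed=0):
        # effective standardized coefficient per original predictor:
        # beta_z = V^T gamma, with V the loadings and gamma the component coefs
        loadings = model.named_steps["pca"].components_  # (k, p)
        gamma = model.named_steps["model"].coef_  # (k,)
        return np.abs(loadings.T @ gamma)


# ---------------------------------------------------------------------------
# partial least squares
# ---------------------------------------------------------------------------


class PLSLearner(Learner):
    name = "PLS"

    def __init__(self, max_components: int = 30, search_budget: int | None = None):
        self.max_components = max_components
        self.search_budget = search_budget

    def sample_hypers(self, rng, n_draws, p):
        # component counts act on a ratio scale: sample log-uniformly so the
        # informative low-dimensional settings are well covered
        hi = min(self.max_components, p)
        import math as _m
        return [
            {"n_components": int(round(2.0 ** rng.uniform(0.0, _m.log2(hi))))}
            for _ in range(n_draws)
        ]

    def complexity_key(self, hypers):
        return (hypers["n_components"],)

    def fit(self, X, y, hypers, seed=0, final=False):
        X, y = _check_xy(X, y)
        k = min(hypers["n_components"], X.shape[1], X.shape[0] - 1)
        model = PLSRegression(n_components=k, scale=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-null deflation warnings
            model.fit(X, y)
        # predictor SDs, for reporting VI on the standardized scale
        x_sd = X.std(axis=0, ddof=1)
        return (model, np.where(x_sd > 0, x_sd, 1.0))

    def predict(self, model, X):
        pls, _ = model
        return pls.predict(np.asarray(X, dtype=float)).ravel()

    def variable_importance(self, model, X, y, seed=0):
        pls, x_sd = model
        coef = np.asarray(pls.coef_).reshape(-1)  # original-scale coefficients
        return np.abs(coef) * x_sd


# ---------------------------------------------------------------------------
# support-vector regression + loess filter VI
# ---------------------------------------------------------------------------


def _loess_fit_r2(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    n_eval: int = 25,
) -> float:
    """R² of a loess (tricube-weighted local polynomial) fit of y on a single x.

    The smoother is evaluated on a quantile grid and interpolated to the
    sample points; the span is the fraction of points inside each local
    window.  Returns 0 for a constant feature; the result is clipped to
    [0, 1].
    """
    n = x.size
    if np.ptp(x) == 0 or n <= degree + 1:
        return 0.0
    r = max(int(math.ceil(span * n)), degree + 2)
    r = min(r, n)
    grid = np.unique(np.quantile(x, np.linspace(0.0, 1.0, n_eval)))
    # batched weighted local polynomial fits, one per grid point
    t = x[None, :] - grid[:, None]  # (G, n)
    d = np.abs(t)
    h = np.partition(d, r - 1, axis=1)[:, r - 1]
    h = np.where(h > 0, h, np.maximum(d.max(axis=1), np.finfo(float).tiny))
    w = (1.0 - np.clip(d / h[:, None], 0.0, 1.0) ** 3) ** 3
    basis = np.stack([t**k for k in range(degree + 1)], axis=2)  # (G, n, q)
    wb = basis * w[:, :, None]
    gram = np.einsum("gnq,gnr->gqr", wb, basis)  # (G, q, q)
    rhs = np.einsum("gnq,n->gq", wb, y)  # (G, q)
    # ridge jitter guards near-singular windows (duplicated x values)
    gram += 1e-10 * np.eye(degree + 1)[None]
    fitted_grid = np.linalg.solve(gram, rhs[:, :, None])[:, 0, 0]
    fitted = np.interp(x, grid, fitted_grid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot
    return float(np.clip(r2, 0.0, 1.0))


def loess_filter_vi(
    X: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Filter-style VI: per-feature loess R² of the outcome on that feature alone."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    return np.array(
        [_loess_fit_r2(X[:, j], y, span=span, degree=degree) for j in range(X.shape[1])]
    )


class SVRLearner(Learner):
    name = "SVR"

    def __init__(
        self,
        loess_span: float = 0.75,
        loess_degree: int = 2,
        search_budget: int | None = None,
    ):
        self.loess_span = loess_span
        self.loess_degree = loess_degree
        self.search_budget = search_budget

    def sample_hypers(self, rng, n_draws, p):
        return [
            {
                "C": float(10.0 ** rng.uniform(-2, 3)),
                "epsilon": float(10.0 ** rng.uniform(-3, 0)),
            }
            for _ in range(n_draws)
        ]

    def complexity_key(self, hypers):
        # smaller C (more regularization) is simpler; then wider epsilon tube
        return (hypers["C"], -hypers["epsilon"])

    def fit(self, X, y, hypers, seed=0, final=False):
        X, y = _check_xy(X, y)
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("model", SVR(kernel="rbf", C=hypers["C"], epsilon=hypers["epsilon"])),
            ]
        )
        pipe.fit(X, y)
        return pipe

    def predict(self, model, X):
        return model.predict(np.asarray(X, dtype=float))

    def variable_importance(self, model, X, y, seed=0):
        # model-free filter: the SVR itself exposes no per-feature weights
        return loess_filter_vi(X, y, span=self.loess_span, degree=self.loess_degree)


# ---------------------------------------------------------------------------
# out-of-bag permutation importance (shared by RF and CF)
# ---------------------------------------------------------------------------


def _oob_permutation_vi(
    tree_predictors: list,
    oob_indices: list[np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Mean over trees of the OOB MSE increase when one feature is permuted.

    One permutation of the OOB rows is drawn per tree and shared across
    features; negative averages are floored at zero.
    """
    n, p = X.shape
    rng = np.random.default_rng(seed)
    vi = np.zeros(p)
    n_used = 0
    for predict, oob in zip(tree_predictors, oob_indices):
        if oob.size < 2:
            continue
        Xo = X[oob].copy()
        yo = y[oob]
        base_mse = float(np.mean((yo - predict(Xo)) ** 2))
        perm = rng.permutation(oob.size)
        for j in range(p):
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[perm]
            vi[j] += float(np.mean((yo - predict(Xo)) ** 2)) - base_mse
            Xo[:, j] = saved
        n_used += 1
    if n_used == 0:
        return np.zeros(p)
    return np.maximum(vi / n_used, 0.0)


def _sklearn_tree_fast_predict(tree):
    """C-level prediction for a fitted sklearn tree, skipping input validation."""

    def predict(X):
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        return tree.tree_.predict(X32).reshape(-1)

    return predict


def _sklearn_forest_oob_indices(forest, n: int) -> list[np.ndarray] | None:
    import inspect

    try:
        from sklearn.ensemble._forest import (
            _generate_unsampled_indices,
            _get_n_samples_bootstrap,
        )

        # the private signatures grew a sample_weight argument over releases
        if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
            n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
        else:
            n_boot = _get_n_samples_bootstrap(n, forest.max_samples)
        if "sample_weight" in inspect.signature(_generate_unsampled_indices).parameters:
            gen = lambda rs: _generate_unsampled_indices(rs, n, n_boot, None)
        else:
            gen = lambda rs: _generate_unsampled_indices(rs, n, n_boot)
        return [np.asarray(gen(est.random_state)) for est in forest.estimators_]
    except Exception:  # private API moved: fall back gracefully
        return None


class RFLearner(Learner):
    name = "RF"

    def __init__(
        self,
        n_trees: int = 500,
        n_trees_tune: int | None = None,
        min_samples_leaf: int = 5,
        vi_max_trees: int | None = None,
        search_budget: int | None = None,
    ):
        self.n_trees = n_trees
        self.n_trees_tune = n_trees_tune if n_trees_tune is not None else n_trees
        self.min_samples_leaf = min_samples_leaf
        self.vi_max_trees = vi_max_trees
        self.search_budget = search_budget

    def _mtry_range(self, p: int) -> tuple[int, int]:
        lo = max(1, int(round(math.sqrt(p))))
        hi = max(lo, int(round(p / 3)))
        return lo, hi

    def sample_hypers(self, rng, n_draws, p):
        lo, hi = self._mtry_range(p)
        return [{"mtry": int(rng.integers(lo, hi + 1))} for _ in range(n_draws)]

    def complexity_key(self, hypers):
        return (hypers["mtry"],)  # fewer candidate features per split = simpler

    def fit(self, X, y, hypers, seed=0, final=False):
        X, y = _check_xy(X, y)
        model = RandomForestRegressor(
            n_estimators=self.n_trees if final else self.n_trees_tune,
            max_features=min(hypers["mtry"], X.shape[1]),
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=True,
            random_state=seed % (2**31),
            n_jobs=1,
        )
        model.fit(X, y)
        return model

    def predict(self, model, X):
        return model.predict(np.asarray(X, dtype=float))

    def variable_importance(self, model, X, y, seed=0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        oob = _sklearn_forest_oob_indices(model, X.shape[0])
        if oob is None:
            warnings.warn(
                "out-of-bag indices unavailable from this scikit-learn build; "
                "computing permutation importance on the training sample instead"
            )
            return _whole_model_permutation_vi(model.predict, X, y, seed)
        predictors = [_sklearn_tree_fast_predict(t) for t in model.estimators_]
        if self.vi_max_trees is not None:
            predictors = predictors[: self.vi_max_trees]
            oob = oob[: self.vi_max_trees]
        return _oob_permutation_vi(predictors, oob, X, y, seed)


def _whole_model_permutation_vi(predict, X, y, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    base = float(np.mean((y - predict(X)) ** 2))
    perm = rng.permutation(X.shape[0])
    vi = np.zeros(X.shape[1])
    Xw = X.copy()
    for j in range(X.shape[1]):
        saved = Xw[:, j].copy()
        Xw[:, j] = saved[perm]
        vi[j] = float(np.mean((y - predict(Xw)) ** 2)) - base
        Xw[:, j] = saved
    return np.maximum(vi, 0.0)


# ---------------------------------------------------------------------------
# conditional inference forest
# ---------------------------------------------------------------------------


class _CITree:
    """Flat-array regression tree; split variable chosen by association test."""

    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def finalize(self):
        self.feature = np.asarray(self.feature, dtype=np.int64)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int64)
        while True:
            feats = self.feature[node]
            active = feats >= 0
            if not active.any():
                break
            idx = np.nonzero(active)[0]
            cur = node[idx]
            go_left = X[idx, feats[idx]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.left[cur], self.right[cur])
        return self.value[node]


def _association_pvalues(Xs: np.ndarray, yc: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for the Pearson correlation of each column with y.

    Uses the asymptotic t reference distribution of the correlation
    coefficient (the large-sample limit of the permutation null).
    """
    xc = Xs - Xs.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = math.sqrt(float((yc**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.nan_to_num(np.clip(r, -0.999999, 0.999999))
    dof = max(n - 2, 1)
    t = np.abs(r) * np.sqrt(dof / (1.0 - r**2))
    return 2.0 * stats.t.sf(t, dof)


def _best_cutpoint(x: np.ndarray, y: np.ndarray, min_leaf: int) -> float | None:
    """Threshold minimizing the two-sided SSE, or None if no valid split exists."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = xs.size
    c1 = np.cumsum(ys)
    c2 = np.cumsum(ys**2)
    total1, total2 = c1[-1], c2[-1]
    sizes = np.arange(1, n)
    valid = (sizes >= min_leaf) & (n - sizes >= min_leaf) & (xs[:-1] < xs[1:])
    if not valid.any():
        return None
    nl = sizes[valid].astype(float)
    nr = n - nl
    s1l, s2l = c1[:-1][valid], c2[:-1][valid]
    sse = (s2l - s1l**2 / nl) + ((total2 - s2l) - (total1 - s1l) ** 2 / nr)
    best = np.argmin(sse)
    pos = np.nonzero(valid)[0][best]
    return float(0.5 * (xs[pos] + xs[pos + 1]))


class _CIForest:
    """Bagged ensemble of association-test trees with stored OOB indices."""

    def __init__(self, trees: list[_CITree], oob: list[np.ndarray]):
        self.trees = trees
        self.oob = oob

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / len(self.trees)


def _build_ci_tree(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    mtry: int,
    alpha: float,
    min_split: int,
    min_leaf: int,
    max_depth: int,
) -> _CITree:
    tree = _CITree()
    p = X.shape[1]

    def grow(idx: np.ndarray, depth: int) -> int:
        node = tree._new_node()
        tree.value[node] = float(y[idx].mean())
        n_node = idx.size
        if n_node < min_split or depth >= max_depth:
            return node
        feats = rng.choice(p, size=min(mtry, p), replace=False)
        yc = y[idx] - y[idx].mean()
        if not np.any(yc):
            return node
        pvals = _association_pvalues(X[np.ix_(idx, feats)], yc, n_node)
        j = int(np.argmin(pvals))
        # Sidak adjustment for testing mtry candidate variables at this node
        p_adj = 1.0 - (1.0 - min(pvals[j], 1.0)) ** len(feats)
        if p_adj > alpha:
            return node
        cut = _best_cutpoint(X[idx, feats[j]], y[idx], min_leaf)
        if cut is None:
            return node
        go_left = X[idx, feats[j]] <= cut
        left = grow(idx[go_left], depth + 1)
        right = grow(idx[~go_left], depth + 1)
        tree.feature[node] = int(feats[j])
        tree.threshold[node] = cut
        tree.left[node] = left
        tree.right[node] = right
        return node

    grow(np.arange(X.shape[0]), 0)
    tree.finalize()
    return tree


class CIForestLearner(Learner):
    """Conditional inference forest: split variable by smallest association p-value.

    At each node the candidate (mtry-subsampled) feature most associated
    with the response — smallest correlation-test p-value, Sidak-adjusted
    for the number of candidates — is selected; growth stops when no
    candidate is significant at ``alpha``.  This separates variable
    selection from cutpoint search, reducing the split bias of exhaustive
    CART-style search.  ``engine="extratrees"`` substitutes a bagged
    extremely-randomized-trees model (with a warning) for users who prefer
    a C-backed approximation.
    """

    name = "CF"

    def __init__(
        self,
        n_trees: int = 500,
        n_trees_tune: int | None = None,
        alpha: float = 0.05,
        min_split: int = 20,
        min_leaf: int = 5,
        max_depth: int = 25,
        engine: str = "native",
        vi_max_trees: int | None = None,
        search_budget: int | None = None,
    ):
        if engine not in ("native", "extratrees"):
            raise ValueError(f"unknown CF engine {engine!r}")
        self.n_trees = n_trees
        self.n_trees_tune = n_trees_tune if n_trees_tune is not None else n_trees
        self.vi_max_trees = vi_max_trees
        self.alpha = alpha
        self.min_split = min_split
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.engine = engine
        self.search_budget = search_budget

    def _mtry_range(self, p: int) -> tuple[int, int]:
        lo = max(1, int(round(math.sqrt(p))))
        hi = max(lo, int(round(p / 3)))
        return lo, hi

    def sample_hypers(self, rng, n_draws, p):
        lo, hi = self._mtry_range(p)
        return [{"mtry": int(rng.integers(lo, hi + 1))} for _ in range(n_draws)]

    def complexity_key(self, hypers):
        return (hypers["mtry"],)

    def fit(self, X, y, hypers, seed=0, final=False):
        X, y = _check_xy(X, y)
        if self.engine == "extratrees":
            warnings.warn(
                "CF engine 'extratrees': substituting extremely randomized "
                "trees for the native conditional inference forest"
            )
            model = ExtraTreesRegressor(
                n_estimators=self.n_trees if final else self.n_trees_tune,
                max_features=min(hypers["mtry"], X.shape[1]),
                min_samples_leaf=self.min_leaf,
                bootstrap=True,
                random_state=seed % (2**31),
                n_jobs=1,
            )
            model.fit(X, y)
            return model
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        trees, oob = [], []
        for _ in range(self.n_trees if final else self.n_trees_tune):
            boot = rng.integers(0, n, size=n)
            mask = np.ones(n, dtype=bool)
            mask[boot] = False
            trees.append(
                _build_ci_tree(
                    X[boot],
                    y[boot],
                    rng,
                    hypers["mtry"],
                    self.alpha,
                    self.min_split,
                    self.min_leaf,
                    self.max_depth,
                )
            )
            oob.append(np.nonzero(mask)[0])
        return _CIForest(trees, oob)

    def predict(self, model, X):
        return model.predict(np.asarray(X, dtype=float))

    def variable_importance(self, model, X, y, seed=0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if isinstance(model, _CIForest):
            predictors = [t.predict for t in model.trees]
            oob = model.oob
            if self.vi_max_trees is not None:
                predictors = predictors[: self.vi_max_trees]
                oob = oob[: self.vi_max_trees]
            return _oob_permutation_vi(predictors, oob, X, y, seed)
        oob = _sklearn_forest_oob_indices(model, X.shape[0])
        if oob is None:
            return _whole_model_permutation_vi(model.predict, X, y, seed)
        predictors = [_sklearn_tree_fast_predict(t) for t in model.estimators_]
        return _oob_permutation_vi(predictors, oob, X, y, seed)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY = {
    "ENET": ENetLearner,
    "PCR": PCRLearner,
    "PLS": PLSLearner,
    "SVR": SVRLearner,
    "RF": RFLearner,
    "CF": CIForestLearner,
}


def make_learners(
    names: tuple[str, ...] = LEARNER_NAMES,
    overrides: dict[str, dict] | None = None,
) -> list[Learner]:
    """Instantiate base learners by name, with optional constructor overrides.

    ``overrides`` maps a learner name to keyword arguments of its
    constructor, e.g. ``{"RF": {"n_trees": 100}, "CF": {"alpha": 0.01}}``.
    """
    overrides = overrides or {}
    unknown = set(names) - set(_REGISTRY)
    if unknown:
        raise ValueError(f"unknown learner(s): {sorted(unknown)}")
    return [_REGISTRY[name](**overrides.get(name, {})) for name in names]
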