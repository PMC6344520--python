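"""One-SE rule, stacking algebra, nested CV plumbing, repeat summaries."""

import numpy as np
import pytest

from motionstack import CVPlan, make_learners, nested_cv, one_se_select, stack, summarize
from motionstack.learners import FittedBase, ENetLearner
from motionstack.stacking import (
    _freeze,
    ensemble_predict,
    pooled_r2,
    stacked_vi,
    tune_learner,
)


def base(r2, vi=None):
    return FittedBase(
        learner=None, hypers={}, model=None, train_r2_cv=r2,
        vi_raw=None if vi is None else np.asarray(vi, dtype=float),
    )


class TestOneSE:
    def complexity(self, setting):
        return (setting["c"],)

    def test_single_candidate_returned(self):
        scores = {_freeze({"c": 3}): (0.5, 0.1)}
        assert one_se_select(scores, self.complexity) == _freeze({"c": 3})

    def test_simpler_setting_within_one_se_wins(self):
        scores = {
            _freeze({"c": 1}): (0.30, 0.05),  # simple
            _freeze({"c": 9}): (0.33, 0.05),  # best but complex
        }
        assert one_se_select(scores, self.complexity) == _freeze({"c": 1})

    def test_out_of_band_simple_setting_not_chosen(self):
        scores = {
            _freeze({"c": 1}): (0.10, 0.05),
            _freeze({"c": 9}): (0.33, 0.05),
        }
        assert one_se_select(scores, self.complexity) == _freeze({"c": 9})

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            one_se_select({}, self.complexity)

    def test_always_weakly_simpler_than_best(self, rng):
        """Property over random score maps: selection never adds complexity."""
        for _ in range(100):
            n = int(rng.integers(2, 15))
            scores = {
                _freeze({"c": int(c)}): (float(rng.normal()), float(rng.uniform(0.01, 0.2)))
                for c in rng.choice(1000, size=n, replace=False)
            }
            best = max(scores, key=lambda s: scores[s][0])
            chosen = one_se_select(scores, self.complexity)
            assert self.complexity(dict(chosen)) <= self.complexity(dict(best))
            assert scores[chosen][0] >= scores[best][0] - scores[best][1]


class TestStackingAlgebra:
    def test_weights_proportional_to_clamped_r2(self):
        ens = stack([base(r) for r in (0.1, 0.1, 0.2, 0.0, -0.3, -0.1)])
        np.testing.assert_allclose(
            ens.weights, [0.25, 0.25, 0.5, 0.0, 0.0, 0.0], atol=1e-12
        )
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_r2_gives_uniform_weights(self):
        ens = stack([base(0.15)] * 4)
        np.testing.assert_allclose(ens.weights, 0.25)

    def test_all_nonpositive_falls_back_to_uniform(self):
        ens = stack([base(r) for r in (-0.2, 0.0, -0.5)])
        np.testing.assert_allclose(ens.weights, 1 / 3)

    def test_stacked_prediction_is_weighted_mean(self, rng):
        X = rng.standard_normal((50, 3))
        y = X[:, 0] + 0.1 * rng.standard_normal(50)
        enet = ENetLearner()
        m1 = enet.fit(X, y, {"alpha": 1e-4, "l1_ratio": 0.5})
        m2 = enet.fit(X, y, {"alpha": 1.0, "l1_ratio": 0.9})
        b1 = FittedBase(enet, {}, m1, train_r2_cv=0.6)
        b2 = FittedBase(enet, {}, m2, train_r2_cv=0.2)
        ens = stack([b1, b2])
        np.testing.assert_allclose(
            ensemble_predict(ens, X),
            0.75 * b1.predict(X) + 0.25 * b2.predict(X),
            atol=1e-12,
        )


class TestStackedVI:
    def test_single_base_identity(self):
        b = base(0.5, vi=[0.0, 2.0, 8.0])
        out = stacked_vi([b], np.array([1.0]))
        np.testing.assert_allclose(out, [0.0, 25.0, 100.0])

    def test_two_base_average(self):
        b1 = base(0.5, vi=[1.0, 0.0])
        b2 = base(0.5, vi=[0.0, 3.0])
        out = stacked_vi([b1, b2], np.array([0.5, 0.5]))
        np.testing.assert_allclose(out, [50.0, 50.0])

    def test_constant_vi_contributes_zero(self):
        b1 = base(0.5, vi=[2.0, 2.0])  # carries no ranking information
        b2 = base(0.5, vi=[0.0, 1.0])
        out = stacked_vi([b1, b2], np.array([0.5, 0.5]))
        np.testing.assert_allclose(out, [0.0, 50.0])

    def test_result_bounded_in_0_100(self, rng):
        bases = [base(0.1, vi=rng.uniform(size=7)) for _ in range(4)]
        w = rng.dirichlet(np.ones(4))
        out = stacked_vi(bases, w)
        assert out.min() >= 0 and out.max() <= 100


class TestSummarize:
    class R:
        def __init__(self, r2, vi):
            self.r2 = r2
            self.stacked_vi = np.asarray(vi, dtype=float)
            self.pooled_predictions = np.empty(0)

    def test_identical_repeats_give_zero_width_ci(self):
        s = summarize([self.R(0.2, [1, 2])] * 3)
        assert s.ci_r2 == (pytest.approx(0.2), pytest.approx(0.2))

    def test_two_repeat_arithmetic(self):
        s = summarize([self.R(0.10, [0]), self.R(0.12, [0])])
        assert s.mean_r2 == pytest.approx(0.11)
        sd = np.std([0.10, 0.12], ddof=1)
        assert s.ci_r2[0] == pytest.approx(0.11 - 1.96 * sd)
        assert s.ci_r2[1] == pytest.approx(0.11 + 1.96 * sd)

    def test_single_repeat_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = summarize([self.R(0.3, [1.0])])
        assert s.ci_r2 == (pytest.approx(0.3), pytest.approx(0.3))


@pytest.fixture(scope="module")
def mini_setup():
    rng = np.random.default_rng(21)
    X = rng.standard_normal((36, 4))
    y = 0.8 * X[:, 0] + rng.standard_normal(36)
    learners = make_learners(("ENET", "PCR"), overrides={"ENET": {"search_budget": 3},
                                                         "PCR": {"search_budget": 3}})
    return X, y, learners


class TestNestedCV:
    def test_pooled_r2_matches_brute_force_oracle(self, mini_setup):
        """R² reported per repeat equals 1 - SS_res/SS_tot of its pooled predictions."""
        X, y, learners = mini_setup
        plan = CVPlan(k_inner=3, k_outer=3, n_repeats=2, n_search=3, seed=5)
        reps = nested_cv(X, y, plan, learners=learners)
        for rep in reps:
            ss_res = float(np.sum((y - rep.pooled_predictions) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            assert rep.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
            assert np.all(rep.stacked_vi >= 0) and np.all(rep.stacked_vi <= 100)

    def test_partition_audit_no_leakage(self, mini_setup):
        """Every subject is validated exactly once per repeat, never trained on."""
        X, y, learners = mini_setup
        plan = CVPlan(k_inner=3, k_outer=4, n_repeats=2, n_search=2, seed=1)
        log = []
        nested_cv(X, y, plan, learners=learners,
                  audit_hook=lambda r, f, tr, te: log.append((r, f, tr.copy(), te.copy())))
        for rep in range(2):
            folds = [(tr, te) for r, f, tr, te in log if r == rep]
            assert len(folds) == 4
            seen = np.concatenate([te for _, te in folds])
            assert sorted(seen) == list(range(len(y)))  # exact cover
            for tr, te in folds:
                assert len(np.intersect1d(tr, te)) == 0

    def test_bit_identical_under_same_master_seed(self, mini_setup):
        X, y, learners = mini_setup
        plan = CVPlan(k_inner=3, k_outer=3, n_repeats=2, n_search=3, seed=99)
        a = nested_cv(X, y, plan, learners=learners)
        b = nested_cv(X, y, plan, learners=learners)
        for ra, rb in zip(a, b):
            assert ra.r2 == rb.r2
            np.testing.assert_array_equal(ra.pooled_predictions, rb.pooled_predictions)
            np.testing.assert_array_equal(ra.stacked_vi, rb.stacked_vi)

    def test_empty_subset_rejected(self, mini_setup):
        X, y, learners = mini_setup
        plan = CVPlan(k_inner=3, k_outer=3, n_repeats=1, n_search=2, seed=0)
        with pytest.raises(ValueError):
            nested_cv(X[:, :0], y, plan, learners=learners)

    def test_tune_learner_reports_chosen_setting_score(self, mini_setup):
        X, y, _ = mini_setup
        enet = ENetLearner(search_budget=4)
        fitted = tune_learner(
            enet, X, y, k_inner=3, n_search=4,
            seed_seq=np.random.SeedSequence(3),
        )
        assert set(fitted.hypers) == {"alpha", "l1_ratio"}
        assert fitted.train_r2_cv <= 1.0
        assert fitted.vi_raw.shape == (X.shape[1],)
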