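"""Univariate correlations, FDR, partial dependence, study report plumbing."""

import numpy as np
import pandas as pd
import pytest

from motionstack import (
    CVPlan,
    make_learners,
    partial_dependence,
    stack,
    study_report,
    univariate_correlations,
)
from motionstack.learners import ENetLearner, FittedBase
from motionstack.reporting import top_importance_table, write_report


def _table(values, n_physical):
    cols = [f"v{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, columns=cols,
                         index=[f"s{i}" for i in range(len(values))])
    block = {c: "physical" if j < n_physical else "psychological"
             for j, c in enumerate(cols)}
    sub = {c: "nondrug" for j, c in enumerate(cols) if j >= n_physical}
    from motionstack import FeatureTable
    return FeatureTable(values=frame, block=block, subblock=sub,
                        max_missing_fraction=1.0)


class TestUnivariate:
    def test_perfect_correlation_flagged_degenerate(self, rng):
        y = rng.standard_normal(50)
        t = _table(np.column_stack([y, rng.standard_normal(50)]), 1)
        rep = univariate_correlations(t, y)
        assert rep.loc["v0", "r"] == pytest.approx(1.0)
        assert rep.loc["v0", "ci_lo"] == rep.loc["v0", "ci_hi"] == pytest.approx(1.0)

    def test_near_perfect_negative_correlation(self, rng):
        y = rng.standard_normal(464)
        x = -y + 1e-3 * rng.standard_normal(464)
        t = _table(x[:, None], 1)
        rep = univariate_correlations(t, y)
        assert rep.loc["v0", "r"] < -0.999
        assert rep.loc["v0", "sign"] == "-"

    def test_zero_variance_variable_reported_undefined(self, rng):
        y = rng.standard_normal(30)
        t = _table(np.column_stack([np.ones(30), y]), 1)
        rep = univariate_correlations(t, y)
        assert not rep.loc["v0", "defined"]
        assert np.isnan(rep.loc["v0", "r"])
        assert rep.loc["v1", "defined"]

    def test_fdr_matches_brute_force_step_up(self, rng):
        """Benjamini–Hochberg output equals an explicit step-up oracle."""
        y = rng.standard_normal(200)
        X = rng.standard_normal((200, 12))
        X[:, 0] += 0.5 * y  # some real signal among nulls
        X[:, 1] += 0.3 * y
        rep = univariate_correlations(_table(X, 6), y)
        p = rep["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):  # step-up from the largest p
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(rep["p_fdr"].to_numpy(), adj, atol=1e-12)
        assert np.all(rep["p_fdr"] >= rep["p"] - 1e-15)

    def test_top_physical_variable_correlation_matches_calibration(self):
        """The strongest physical predictor correlates ~0.28 with log-motion.

        Generator-consistency check at large n: the loading range is
        calibrated so the best physical variable's population Pearson r
        with the outcome sits at the BMI-motion benchmark value.
        """
        from motionstack import CohortSpec, generate_cohort

        cohort = generate_cohort(
            CohortSpec(n_subjects=20_000, missing_rate_max=0.0, seed=6)
        )
        rep = univariate_correlations(cohort.features, cohort.outcome)
        phys = cohort.features.variables_in_block("physical")
        assert rep.loc[phys, "r"].max() == pytest.approx(0.28, abs=0.05)

    def test_sign_matches_regression_slope(self, rng):
        y = rng.standard_normal(150)
        X = rng.standard_normal((150, 8)) + np.outer(y, rng.normal(size=8) * 0.3)
        rep = univariate_correlations(_table(X, 4), y)
        for j, var in enumerate(rep.index):
            slope = np.polyfit(X[:, j], y, 1)[0]
            assert (rep.loc[var, "sign"] == "+") == (slope >= 0)


def _linear_ensemble(X, y, alpha=1e-6):
    enet = ENetLearner()
    model = enet.fit(X, y, {"alpha": alpha, "l1_ratio": 0.0})
    return stack([FittedBase(enet, {}, model, train_r2_cv=0.9)])


class TestPartialDependence:
    def test_linear_model_pdp_has_model_slope(self, rng):
        X = rng.standard_normal((300, 3))
        y = 2.0 * X[:, 0]
        ens = _linear_ensemble(X, y)
        curve = partial_dependence(ens, X, 0, n_grid=20)
        slope = (curve.mean_prediction[-1] - curve.mean_prediction[0]) / (
            curve.grid[-1] - curve.grid[0]
        )
        assert slope == pytest.approx(2.0, abs=1e-3)
        assert np.all(np.diff(curve.grid) > 0)

    def test_null_model_pdp_is_flat(self, rng):
        X = rng.standard_normal((100, 3))
        y = X[:, 1] + 0.1 * rng.standard_normal(100)
        ens = _linear_ensemble(X, y, alpha=1e8)  # all coefficients shrunk to 0
        curve = partial_dependence(ens, X, 1, n_grid=10)
        assert np.ptp(curve.mean_prediction) < 1e-9

    def test_invariant_to_subject_order(self, rng):
        X = rng.standard_normal((120, 4))
        y = X[:, 0] - X[:, 2] + 0.2 * rng.standard_normal(120)
        ens = _linear_ensemble(X, y)
        perm = rng.permutation(120)
        a = partial_dependence(ens, X, 2, n_grid=15)
        b = partial_dependence(ens, X[perm], 2, n_grid=15)
        np.testing.assert_allclose(a.grid, b.grid, atol=1e-12)
        np.testing.assert_allclose(a.mean_prediction, b.mean_prediction, atol=1e-10)

    def test_unknown_variable_rejected(self, rng):
        X = rng.standard_normal((50, 2))
        ens = _linear_ensemble(X, X[:, 0])
        with pytest.raises(ValueError, match="not in the model"):
            partial_dependence(ens, X, 7)
        with pytest.raises(ValueError, match="not in the model"):
            partial_dependence(ens, X, "bmi", variable_names=["a", "b"])


class TestStudyReport:
    def test_four_model_report_structure_and_outputs(self, small_cohort,
                                                     tiny_learners, tmp_path):
        plan = CVPlan(k_inner=3, k_outer=3, n_repeats=2, n_search=3, seed=4)
        report = study_report(
            small_cohort.features, small_cohort.outcome, plan,
            learners=tiny_learners,
        )
        assert set(report.summaries) == {
            "physical", "psychological", "all", "residualized",
        }
        for which, s in report.summaries.items():
            assert s.ci_r2[0] <= s.mean_r2 <= s.ci_r2[1]
            assert len(s.variables) == len(s.mean_vi)
        # residualized model drops the physical block
        assert set(report.summaries["residualized"].variables) == set(
            small_cohort.features.variables_in_block("psychological")
        )
        top = top_importance_table(report.summaries["physical"], n_top=3)
        assert top["top"].sum() == 3
        assert top["mean_vi"].is_monotonic_decreasing

        write_report(report, tmp_path)
        for name in ("model_r2.tsv", "variable_importance.tsv",
                     "univariate_correlations.tsv"):
            assert (tmp_path / name).exists()
        r2_table = pd.read_csv(tmp_path / "model_r2.tsv", sep="\t")
        assert set(r2_table["model"]) == set(report.summaries)

    def test_report_reproducible_under_master_seed(self, small_cohort, tiny_learners):
        plan = CVPlan(k_inner=3, k_outer=3, n_repeats=2, n_search=2, seed=11)
        a = study_report(small_cohort.features, small_cohort.outcome, plan,
                         learners=tiny_learners, subsets=("physical",))
        b = study_report(small_cohort.features, small_cohort.outcome, plan,
                         learners=tiny_learners, subsets=("physical",))
        assert a.summaries["physical"].mean_r2 == b.summaries["physical"].mean_r2
        np.testing.assert_array_equal(
            a.summaries["physical"].mean_vi, b.summaries["physical"].mean_vi
        )

    def test_unknown_subset_rejected(self, small_cohort, tiny_learners):
        plan = CVPlan(k_inner=3, k_outer=3, n_repeats=1, n_search=2, seed=0)
        with pytest.raises(ValueError, match="unknown subset"):
            study_report(small_cohort.features, small_cohort.outcome, plan,
                         learners=tiny_learners, subsets=("physio",))
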