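import numpy as np
import pytest
import statsmodels.api as sm

from deggnet.diff_interaction import adjust_bh, build_interaction_design, huber_fit, scan_network
from deggnet.diff_interaction import test_edge as edge_interaction_test
from deggnet.exceptions import RankDeficiencyError, ValidationError
from deggnet.subgroup_networks import SpecificNetwork

from .conftest import make_annotation, make_expression, two_gene_study
from .test_network_core import net_from


class TestHuberFit:
    def test_exact_line_recovered_with_floored_scale(self):
        x = np.linspace(0, 5, 30)
        y = 2 * x + 1
        X = np.column_stack([np.ones_like(x), x])
        fit = huber_fit(y, X, ["intercept", "x"])
        assert fit.coefficients["intercept"] == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-8)
        assert fit.scale_floored and fit.converged

    def test_equals_ols_when_no_large_residuals(self, rng):
        # all standardized residuals below the Huber constant -> weights are
        # identically one and the M-estimate is the least-squares solution
        checked = 0
        for _ in range(10):
            n = 60
            X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
            beta = np.array([1.0, 2.0, -1.0])
            # bounded sinusoidal noise keeps max|resid| below the Huber cut
            y = X @ beta + 0.3 * np.sin(1.7 * np.arange(n) + rng.uniform(0, 6.28))
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ ols
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if np.max(np.abs(resid / scale)) >= 1.345:
                continue  # this draw has a large standardized residual
            fit = huber_fit(y, X)
            np.testing.assert_allclose(fit.params, ols, rtol=1e-6)
            checked += 1
        assert checked > 0

    def test_resists_gross_outlier_where_ols_does_not(self, rng):
        n = 20
        x = np.linspace(0, 10, n)
        y = 3.0 * x + rng.normal(0, 0.3, size=n)
        y[7] += 100.0
        X = np.column_stack([np.ones(n), x])
        fit = huber_fit(y, X, ["intercept", "x"])
        ols_slope = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert abs(fit.coefficients["x"] - 3.0) / 3.0 < 0.05
        assert abs(ols_slope - 3.0) / 3.0 > 0.05

    def test_matches_statsmodels_rlm(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0]) + rng.standard_t(df=3, size=n)
        ours = huber_fit(y, X)
        theirs = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(scale_est="mad")
        # scale-update details differ slightly between implementations
        np.testing.assert_allclose(ours.params, theirs.params, rtol=0.01, atol=0.01)

    def test_rank_deficiency_names_column(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(RankDeficiencyError, match="dup"):
            huber_fit(rng.normal(size=n), X, ["intercept", "x", "dup"])

    def test_too_few_observations_rejected(self):
        X = np.ones((2, 2))
        with pytest.raises(ValidationError):
            huber_fit(np.zeros(2), X)


class TestBuildDesign:
    def test_largest_group_is_reference(self, rng):
        import pandas as pd

        groups = pd.Series(["small"] * 3 + ["big"] * 5)
        X, names, ref = build_interaction_design(rng.normal(size=8), groups)
        assert ref == "big"
        assert names == ["intercept", "x", "group[small]", "group[small]:x"]

    def test_categorical_covariate_one_hot(self, rng):
        import pandas as pd

        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        cov = pd.DataFrame({"sex": ["F", "F", "F", "M", "M", "F", "F", "M"]})
        X, names, _ = build_interaction_design(rng.normal(size=8), groups, cov)
        assert names[-1] == "sex[M]"  # F is the more frequent reference


class TestTestEdge:
    def test_orientation_and_null_three_groups(self, rng):
        n = 90
        x = rng.normal(5, 1, size=n)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.5, size=n)
        expr, annot = two_gene_study(x, y, ["g1"] * 30 + ["g2"] * 30 + ["g3"] * 30)
        res = edge_interaction_test(expr, annot, ("GB", "GA"))
        assert (res.predictor_gene, res.response_gene) == ("GA", "GB")
        assert res.df == 2
        assert set(res.per_group_slope) == {"g1", "g2", "g3"}
        slopes = list(res.per_group_slope.values())
        se = 2 * 0.5 / np.sqrt(30)  # generous bound on slope spread under the null
        assert max(slopes) - min(slopes) < 4 * se
        assert res.n_per_group == {"g1": 30, "g2": 30, "g3": 30}

    def test_planted_slope_difference_detected(self, rng):
        x = rng.normal(5, 1, size=100)
        y = np.where(np.arange(100) < 50, 1.0 * x, 0.0 * x) + rng.normal(0, 0.3, 100)
        expr, annot = two_gene_study(x, y, ["a"] * 50 + ["b"] * 50)
        res = edge_interaction_test(expr, annot, ("GA", "GB"))
        assert res.p_raw < 1e-6
        assert res.per_group_slope["a"] == pytest.approx(1.0, abs=0.2)
        assert res.per_group_slope["b"] == pytest.approx(0.0, abs=0.2)

    def test_group_label_permutation_invariance(self, rng):
        x = rng.normal(5, 1, size=60)
        y = 0.5 * x + rng.normal(0, 0.4, size=60)
        labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        expr, annot1 = two_gene_study(x, y, labels)
        swap = {"a": "c", "b": "b", "c": "a"}
        _, annot2 = two_gene_study(x, y, [swap[l] for l in labels])
        r1 = edge_interaction_test(expr, annot1, ("GA", "GB"))
        r2 = edge_interaction_test(expr, annot2, ("GA", "GB"))
        assert r1.interaction_stat == pytest.approx(r2.interaction_stat, rel=1e-6)
        assert r1.p_raw == pytest.approx(r2.p_raw, rel=1e-6)
        for lab in "abc":
            assert r1.per_group_slope[lab] == pytest.approx(
                r2.per_group_slope[swap[lab]], rel=1e-6
            )

    def test_predictor_translation_invariance(self, rng):
        x = rng.normal(5, 1, size=40)
        y = 0.7 * x + rng.normal(0, 0.4, size=40)
        expr1, annot = two_gene_study(x, y, ["a"] * 20 + ["b"] * 20)
        expr2, _ = two_gene_study(x + 10.0, y, ["a"] * 20 + ["b"] * 20)
        r1 = edge_interaction_test(expr1, annot, ("GA", "GB"))
        r2 = edge_interaction_test(expr2, annot, ("GA", "GB"))
        assert r1.p_raw == pytest.approx(r2.p_raw, rel=1e-6)
        assert r1.per_group_slope["a"] == pytest.approx(r2.per_group_slope["a"], rel=1e-6)

    def test_small_group_rejected(self, rng):
        x = rng.normal(size=10)
        expr, annot = two_gene_study(x, x, ["a"] * 8 + ["b"] * 2)
        with pytest.raises(ValidationError, match="'b'"):
            edge_interaction_test(expr, annot, ("GA", "GB"))

    def test_unmeasured_gene_is_lookup_error(self, rng):
        x = rng.normal(size=12)
        expr, annot = two_gene_study(x, x + rng.normal(size=12), ["a"] * 6 + ["b"] * 6)
        with pytest.raises(KeyError):
            edge_interaction_test(expr, annot, ("GA", "GZ"))

    def test_equals_ols_design_solution_under_unit_weights(self, rng):
        # bounded noise keeps every Huber weight at one, so the full
        # interaction model must match the closed-form least-squares fit
        x = rng.normal(5, 1, size=30)
        y = 2.0 + 0.5 * x + 0.2 * np.sin(1.7 * np.arange(30))  # bounded, spread noise
        expr, annot = two_gene_study(x, y, ["a"] * 15 + ["b"] * 15)
        res = edge_interaction_test(expr, annot, ("GA", "GB"))
        import pandas as pd

        X, names, _ = build_interaction_design(x, pd.Series(["a"] * 15 + ["b"] * 15), predictor_name="GA")
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ ols
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        assert np.max(np.abs(resid / scale)) < 1.345  # unit-weight precondition
        np.testing.assert_allclose(res.fit.params, ols, rtol=1e-5, atol=1e-8)


class TestAdjustBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.03]), [0.03])

    def test_hand_computed_stepup(self):
        # p*n/i = (.04, .04, .04, .04); running min from the top keeps .04
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_all_equal(self):
        np.testing.assert_allclose(adjust_bh([0.2] * 5), [0.2] * 5)

    def test_matches_statsmodels_multipletests(self, rng):
        p = rng.uniform(size=50)
        expected = sm.stats.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adjust_bh(p), expected, rtol=1e-12)

    def test_order_preserving_and_bounded(self, rng):
        p = rng.uniform(size=17)
        adj = adjust_bh(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])


class TestScanNetwork:
    def test_bh_applied_over_tested_edges_and_skips_logged(self, rng, caplog):
        n = 30
        genes = ["GA", "GB", "GC", "GD"]
        vals = rng.normal(5, 1, size=(4, n))
        expr = make_expression(vals, genes=genes)
        annot = make_annotation(["a"] * 15 + ["b"] * 15)
        net = net_from([("GA", "GB"), ("GC", "GD"), ("GA", "GZ")])  # GZ unmeasured
        with caplog.at_level("INFO"):
            results = scan_network(SpecificNetwork("a", net), expr, annot)
        assert len(results) == 2
        assert "skipping edge" in caplog.text
        expected = adjust_bh([r.p_raw for r in results])
        np.testing.assert_allclose([r.p_adjusted for r in results], expected)
        assert all(r.p_adjusted >= r.p_raw - 1e-15 for r in results)

    def test_zero_variance_edge_skipped(self, rng):
        n = 20
        x = rng.normal(size=n)
        y = np.ones(n)  # constant response gene
        expr, annot = two_gene_study(x, y, ["a"] * 10 + ["b"] * 10)
        net = net_from([("GA", "GB")])
        results = scan_network(SpecificNetwork("a", net), expr, annot)
        assert results == []
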