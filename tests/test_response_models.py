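import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from deggnet.exceptions import RankDeficiencyError, ValidationError
from deggnet.io_formats import SampleAnnotation
from deggnet.response_models import (
    evaluate_pairs,
    fit_ratio_logistic,
    roc_auc,
    select_response_samples,
)

from .conftest import make_expression


def binary_annotation(outcomes, samples=None, **covariates):
    samples = samples or [f"s{i}" for i in range(len(outcomes))]
    resp = ["Good" if o else "None" for o in outcomes]
    return SampleAnnotation(
        pd.DataFrame({"subgroup": resp, "response": resp, **covariates}, index=samples)
    )


def brute_force_auc(scores, labels):
    """Exhaustive count over positive-negative pairs, ties worth 1/2."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSelectResponseSamples:
    def test_moderate_excluded_then_class_too_small(self):
        annot = SampleAnnotation(
            pd.DataFrame(
                {
                    "subgroup": ["x"] * 5,
                    "response": ["Good", "Moderate", "None", "Good", "Moderate"],
                },
                index=[f"s{i}" for i in range(5)],
            )
        )
        with pytest.raises(ValidationError, match="None=1"):
            select_response_samples(annot)

    def test_binary_outcome_coding(self):
        annot = binary_annotation([1] * 5 + [0] * 4)
        out = select_response_samples(annot)
        assert len(out) == 9
        assert out.outcome.tolist() == [1.0] * 5 + [0.0] * 4

    def test_all_moderate_rejected(self):
        annot = SampleAnnotation(
            pd.DataFrame(
                {"subgroup": ["x"] * 4, "response": ["Moderate"] * 4},
                index=[f"s{i}" for i in range(4)],
            )
        )
        with pytest.raises(ValidationError):
            select_response_samples(annot)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_pairwise_enumeration_oracle(self):
        scores = [3, 1, 2, 5, 4, 0]
        labels = [1, 0, 1, 1, 0, 0]
        expected = brute_force_auc(scores, labels)
        assert expected == pytest.approx(7 / 9)
        assert roc_auc(scores, labels).auc == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_and_trapezoid(self, rng):
        for _ in range(10):
            scores = rng.normal(size=40)
            scores[rng.integers(0, 40, 5)] = scores[0]  # inject ties
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            curve = roc_auc(scores, labels)
            assert curve.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
            assert curve.auc == pytest.approx(curve.auc_trapezoid, abs=1e-12)
            assert curve.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=25)
        labels = np.r_[np.ones(10), np.zeros(15)]
        curve = roc_auc(scores, labels)
        assert (curve.tpr[0], curve.fpr[0]) == (0.0, 0.0)
        assert (curve.tpr[-1], curve.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.tpr) >= 0) and np.all(np.diff(curve.fpr) >= 0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(np.exp(scores / 2) + 7, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc == pytest.approx(
            1 - roc_auc(scores, 1 - labels).auc, abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])


def planted_pair_study(rng, n=150, effect=2.0):
    g1 = rng.normal(6, 1, size=n)
    g2 = rng.normal(4, 1, size=n)
    t = (g1 - g1.mean()) * (g2 - g2.mean())
    eta = effect * t / t.std()
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    expr = make_expression(np.vstack([g1, g2]), genes=["GP1", "GP2"])
    annot = binary_annotation(y)
    return expr, annot, y


class TestFitRatioLogistic:
    def test_planted_interaction_detected(self, rng):
        for _ in range(10):
            expr, annot, y = planted_pair_study(rng)
            if min((y == 1).sum(), (y == 0).sum()) < 3:
                continue
            res = fit_ratio_logistic(expr, annot, "GP1", "GP2")
            assert res.interaction_p < 0.01
            assert res.auc_with > res.auc_without
            assert res.n_good + res.n_none == len(y)
            break

    def test_loglikelihood_never_increases_when_term_removed(self, rng):
        expr, annot, _ = planted_pair_study(rng, effect=1.0)
        res = fit_ratio_logistic(expr, annot, "GP1", "GP2")
        assert res.loglike_without <= res.loglike_with + 1e-8

    def test_constant_gene_is_rank_deficiency(self, rng):
        n = 40
        g1 = np.full(n, 5.0)
        g2 = rng.normal(size=n)
        expr = make_expression(np.vstack([g1, g2]), genes=["GC", "GV"])
        annot = binary_annotation(rng.integers(0, 2, size=n).tolist())
        with pytest.raises(RankDeficiencyError, match="GC"):
            fit_ratio_logistic(expr, annot, "GC", "GV")

    def test_perfect_separation_flagged_auc_still_reported(self):
        n = 24
        g1 = np.r_[np.linspace(0, 1, 12), np.linspace(5, 6, 12)]
        g2 = np.linspace(0, 1, n)
        expr = make_expression(np.vstack([g1, g2]), genes=["GS1", "GS2"])
        annot = binary_annotation([0] * 12 + [1] * 12)
        res = fit_ratio_logistic(expr, annot, "GS1", "GS2")
        assert res.separation_flag
        assert np.isnan(res.interaction_p)
        assert res.auc_with == 1.0

    def test_numeric_covariate_enters_model(self, rng):
        expr, annot, y = planted_pair_study(rng, n=120)
        age = rng.normal(52, 16, size=120)
        annot = binary_annotation(y.tolist(), age=age)
        res = fit_ratio_logistic(expr, annot, "GP1", "GP2", covariates=["age"])
        assert "age" in res.coefficients

    def test_coefficients_backtransformed_to_raw_scale(self, rng):
        # scores computed from raw-scale coefficients must reproduce the
        # fitted linear predictor used for the AUC
        expr, annot, _ = planted_pair_study(rng, n=100, effect=1.0)
        res = fit_ratio_logistic(expr, annot, "GP1", "GP2")
        g1 = expr.gene("GP1").to_numpy()
        g2 = expr.gene("GP2").to_numpy()
        ratio = (g1 - g1.mean()) * (g2 - g2.mean())
        eta = (
            res.coefficients["intercept"]
            + res.coefficients["GP1"] * g1
            + res.coefficients["GP2"] * g2
            + res.coefficients["ratio_product"] * ratio
        )
        y = annot.outcome.to_numpy()
        assert roc_auc(eta, y).auc == pytest.approx(res.auc_with, abs=1e-9)


class TestEvaluatePairs:
    def _edge_result(self, a, b, p):
        from deggnet.diff_interaction import DifferentialEdgeResult

        return DifferentialEdgeResult(
            gene_a=a,
            gene_b=b,
            response_gene=b,
            predictor_gene=a,
            per_group_slope={},
            interaction_stat=0.0,
            df=1,
            p_raw=p,
            p_adjusted=p,
            n_per_group={},
        )

    def test_no_significant_pairs_gives_empty_list(self, rng):
        expr, annot, _ = planted_pair_study(rng)
        out = evaluate_pairs([self._edge_result("GP1", "GP2", 0.5)], expr, annot)
        assert out == []

    def test_sorted_by_auc_descending(self, rng):
        n = 120
        g1 = rng.normal(6, 1, size=n)
        g2 = rng.normal(4, 1, size=n)
        g3 = rng.normal(5, 1, size=n)
        g4 = rng.normal(5, 1, size=n)
        t = (g1 - g1.mean()) * (g2 - g2.mean())
        y = (rng.random(n) < 1 / (1 + np.exp(-3 * t / t.std()))).astype(int)
        expr = make_expression(np.vstack([g1, g2, g3, g4]), genes=["GP1", "GP2", "GN1", "GN2"])
        annot = binary_annotation(y.tolist())
        out = evaluate_pairs(
            [self._edge_result("GP1", "GP2", 0.001), self._edge_result("GN1", "GN2", 0.001)],
            expr,
            annot,
        )
        assert len(out) == 2
        assert out[0].auc_with >= out[1].auc_with
        assert (out[0].gene_1, out[0].gene_2) == ("GP1", "GP2")
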