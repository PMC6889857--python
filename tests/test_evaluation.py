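import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnetscore.errors import DegenerateStatisticsError, ValidationError
from bnetscore.evaluation import (
    HIGH_VS_REST,
    LOW_VS_REST,
    evaluate_metrics,
    logistic_fit,
    pearson_r2,
    roc_auc,
    two_sample_t,
)
from bnetscore.panel_io import Risk


def brute_force_auc(scores, labels):
    """All-pairs oracle: concordant pairs + half ties over pos x neg pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3], [0, 0, 1]).auc == 1.0

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    def test_three_of_four_pairs(self):
        # pairs (pos, neg): (2,3) discordant; (2,1), (4,3), (4,1) concordant
        assert roc_auc([3, 1, 2, 4], [0, 0, 1, 1]).auc == 0.75

    def test_orientation_flag(self):
        result = roc_auc([3, 2, 1], [0, 0, 1], higher_is_positive=False)
        assert result.auc == 1.0 and result.orientation_applied

    def test_counts(self):
        result = roc_auc([1, 2, 3, 4], [0, 1, 1, 1])
        assert (result.n_pos, result.n_neg) == (3, 1)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            roc_auc([1, 2], [1, 1])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [0, 1])


@settings(max_examples=300, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.integers(min_value=0, max_value=5), st.integers(0, 1)),
        min_size=2,
        max_size=12,
    )
)
def test_midrank_equals_brute_force(data):
    scores = [float(s) for s, _ in data]
    labels = [y for _, y in data]
    if len(set(labels)) < 2:
        return
    assert roc_auc(scores, labels).auc == brute_force_auc(scores, labels)


@settings(max_examples=200, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.integers(min_value=-5, max_value=5), st.integers(0, 1)),
        min_size=2,
        max_size=20,
    )
)
def test_negation_complements_auc(data):
    scores = [float(s) for s, _ in data]
    labels = [y for _, y in data]
    if len(set(labels)) < 2:
        return
    forward = roc_auc(scores, labels).auc
    backward = roc_auc([-s for s in scores], labels).auc
    assert forward + backward == pytest.approx(1.0, abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=30)
    labels = rng.integers(0, 2, size=30)
    labels[0], labels[1] = 0, 1
    base = roc_auc(scores, labels).auc
    for transform in (np.exp, np.tanh, lambda x: 3 * x + 7, lambda x: x**3):
        assert roc_auc(transform(scores), labels).auc == pytest.approx(base, abs=1e-12)


class TestLogisticFit:
    def test_constant_scores(self):
        fit = logistic_fit([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert fit.slope == 0.0
        assert fit.chi2 == 0.0
        assert fit.converged

    def test_chi2_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        fit = logistic_fit(x, y)
        # recompute both log-likelihoods from the fitted coefficients
        eta = fit.intercept + fit.slope * x
        ll_model = float(np.sum(y * eta) - np.sum(np.logaddexp(0, eta)))
        pbar = y.mean()
        ll_null = len(y) * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))
        assert fit.chi2 == pytest.approx(2 * (ll_model - ll_null), abs=1e-6)
        assert fit.converged and not fit.separation_detected

    def test_slope_recovery_simulation(self):
        # generative oracle: logit(p) = 0.5 + 1.5 * score, n = 2000
        rng = np.random.default_rng(2024)
        x = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-(0.5 + 1.5 * x)))
        y = (rng.uniform(size=2000) < p).astype(int)
        fit = logistic_fit(x, y)
        assert fit.slope == pytest.approx(1.5, abs=0.15)
        assert fit.intercept == pytest.approx(0.5, abs=0.15)

    def test_separation_detected(self):
        fit = logistic_fit([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1])
        assert fit.separation_detected
        assert not fit.converged
        assert fit.chi2 > 0

    def test_quasi_separation_detected(self):
        fit = logistic_fit([1.0, 2.0, 3.0, 3.0, 4.0, 5.0], [0, 0, 0, 1, 1, 1])
        assert fit.separation_detected

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            logistic_fit([1.0, 2.0], [1, 1])

    def test_chi2_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=150)
        y = (rng.uniform(size=150) < 1 / (1 + np.exp(-x))).astype(int)
        base = logistic_fit(x, y)
        scaled = logistic_fit(1000.0 * x - 3.0, y)
        assert scaled.chi2 == pytest.approx(base.chi2, abs=1e-6)
        assert scaled.slope == pytest.approx(base.slope / 1000.0, rel=1e-5)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(29)
        x = rng.normal(size=120)
        y = (rng.uniform(size=120) < 1 / (1 + np.exp(-(0.2 + 0.9 * x)))).astype(int)
        fit = logistic_fit(x, y)
        sm_fit = statsmodels.Logit(y, np.column_stack([np.ones_like(x), x])).fit(disp=0)
        assert fit.intercept == pytest.approx(sm_fit.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(sm_fit.params[1], abs=1e-6)
        assert fit.loglik_model == pytest.approx(sm_fit.llf, abs=1e-8)

    def test_null_type_one_error_quick(self):
        # 2000 null replicates; the 10k version lives in the acceptance suite
        rng = np.random.default_rng(77)
        cut = 3.841458820694124  # chi2(1) 0.95 quantile
        rejections = 0
        for _ in range(2000):
            x = rng.normal(size=60)
            y = rng.integers(0, 2, size=60)
            if y.min() == y.max():
                continue
            if logistic_fit(x, y).chi2 > cut:
                rejections += 1
        assert 0.03 <= rejections / 2000 <= 0.07


class TestPearsonR2:
    def test_exact_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r2(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_sign_blind(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r2(x, [-v for v in x]) == pytest.approx(1.0)

    def test_independent_large_n(self):
        rng = np.random.default_rng(101)
        assert pearson_r2(rng.normal(size=10000), rng.normal(size=10000)) < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(ValidationError):
            pearson_r2([1.0, 2.0], [3.0, 4.0])


class TestTwoSampleT:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0]
        t, df, p = two_sample_t(a, list(a))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=20), rng.normal(1.0, 1.0, size=25)
        fwd, rev = two_sample_t(a, b), two_sample_t(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)
        assert fwd.df == pytest.approx(rev.df)

    def test_large_effect(self):
        rng = np.random.default_rng(19)
        a = rng.normal(0.0, 1.0, size=50)
        b = rng.normal(2.0, 1.0, size=50)
        assert two_sample_t(a, b).p < 0.001

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_pooled_df(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0, 8.0]
        assert two_sample_t(a, b, equal_var=True).df == 5.0

    def test_welch_null_type_one_error(self):
        rng = np.random.default_rng(31)
        a = rng.normal(size=(10000, 15))
        b = rng.normal(size=(10000, 20))
        rejections = sum(
            two_sample_t(a[i], b[i]).p < 0.05 for i in range(10000)
        )
        assert 0.04 <= rejections / 10000 <= 0.06


class TestEvaluateMetrics:
    RISKS = (
        [Risk.LOW] * 5 + [Risk.INTERMEDIATE] * 5 + [Risk.HIGH] * 5
    )

    def _latent(self):
        return [float(i) for i in range(15)]  # strictly increasing with risk

    def test_perfect_metric_gets_unit_aucs(self):
        report = evaluate_metrics(self.RISKS, {"m": self._latent()})
        roc = report.metrics["m"].roc
        assert roc["low_vs_rest"].auc == 1.0
        assert roc["high_vs_rest"].auc == 1.0

    def test_identical_columns_identical_rows(self):
        scores = self._latent()
        report = evaluate_metrics(
            self.RISKS, {"a": scores, "b": list(scores)}, reference_metric="b"
        )
        a, b = report.metrics["a"], report.metrics["b"]
        assert a.roc["low_vs_rest"].auc == b.roc["low_vs_rest"].auc
        assert a.logistic.chi2 == pytest.approx(b.logistic.chi2, abs=1e-9)
        assert a.r2_vs_reference == pytest.approx(1.0)

    def test_noise_metric_null_auc(self):
        rng = np.random.default_rng(55)
        risks = [Risk.LOW] * 9 + [Risk.INTERMEDIATE] * 11 + [Risk.HIGH] * 8
        aucs = [
            evaluate_metrics(risks, {"noise": rng.normal(size=28)})
            .metrics["noise"]
            .roc["low_vs_rest"]
            .auc
            for _ in range(500)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_lower_is_riskier_orientation(self):
        inverted = [-v for v in self._latent()]
        report = evaluate_metrics(
            self.RISKS, {"ref": inverted}, orientations={"ref": False}
        )
        assert report.metrics["ref"].roc["low_vs_rest"].auc == 1.0
        assert report.metrics["ref"].roc["low_vs_rest"].orientation_applied

    def test_unlabeled_drugs_are_dropped(self):
        risks = [Risk.LOW, None, Risk.HIGH, Risk.HIGH, Risk.LOW, Risk.INTERMEDIATE]
        report = evaluate_metrics(risks, {"m": [1.0, 99.0, 5.0, 6.0, 2.0, 3.0]})
        assert report.n_drugs == 5
        assert report.metrics["m"].roc["low_vs_rest"].auc == 1.0

    def test_no_labels_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_metrics([None, None], {"m": [1.0, 2.0]})

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_metrics(self.RISKS, {"m": [1.0]})

    def test_logistic_dichotomy_selectable(self):
        scores = self._latent()
        low = evaluate_metrics(self.RISKS, {"m": scores})
        high = evaluate_metrics(
            self.RISKS, {"m": scores}, logistic_dichotomy=HIGH_VS_REST
        )
        assert low.metrics["m"].logistic_dichotomy == "low_vs_rest"
        assert high.metrics["m"].logistic_dichotomy == "high_vs_rest"

    def test_json_and_csv_shapes(self):
        report = evaluate_metrics(
            self.RISKS,
            {"a": self._latent(), "b": [-v for v in self._latent()]},
            reference_metric="b",
            orientations={"b": False},
        )
        data = report.to_dict()
        assert set(data["metrics"]) == {"a", "b"}
        rows = report.to_csv_rows()
        assert {row["metric"] for row in rows} == {"a", "b"}
        assert all("roc_auc_low_vs_rest" in row for row in rows)

    def test_dichotomy_definitions(self):
        assert LOW_VS_REST.positive_classes == frozenset({Risk.INTERMEDIATE, Risk.HIGH})
        assert HIGH_VS_REST.positive_classes == frozenset({Risk.HIGH})
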