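"""Expected risk, WBA, and the standard point metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskwba import (
    CohortComposition,
    ConfusionCounts,
    RiskWeights,
    aggregate_weight,
    expected_risk,
    normalized_expected_risk,
    risk_ratio,
    standard_metrics,
    wba,
    wba_weights,
)

rates = st.floats(0.0, 1.0)
pos_reals = st.floats(1e-3, 1e3)
counts = st.integers(0, 500)


class TestRiskRatio:
    @pytest.mark.parametrize(
        "w_fn, w_fp, p, n, expected",
        [(1, 1, 50, 50, 1.0), (10, 1, 50, 50, 10.0), (2, 1, 100, 400, 0.5)],
    )
    def test_values(self, w_fn, w_fp, p, n, expected):
        c = risk_ratio(RiskWeights(w_fp=w_fp, w_fn=w_fn), CohortComposition(p=p, n=n))
        assert c == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            risk_ratio(RiskWeights(w_fp=0.0, w_fn=1.0), CohortComposition(p=1, n=1))
        with pytest.raises(ZeroDivisionError):
            risk_ratio(RiskWeights(w_fp=1.0, w_fn=1.0), CohortComposition(p=1, n=0))


class TestExpectedRisk:
    def test_examples(self):
        w11 = RiskWeights(1.0, 1.0)
        assert expected_risk(0, 0, w11, CohortComposition(10, 10)) == 0
        assert expected_risk(1, 0, w11, CohortComposition(5, 100)) == 100
        # at P=N=1 and unit weights ER equals the normalized form at c_fn=1
        assert expected_risk(0.2173, 0.2173, w11, CohortComposition(1, 1)) == (
            pytest.approx(0.4346)
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            expected_risk(-0.1, 0.5, RiskWeights(1, 1), CohortComposition(1, 1))

    def test_normalized_form_examples(self):
        fpr = fnr = 0.2172991042535391  # sigma=0.3 model at s=0.5
        assert round(normalized_expected_risk(fpr, fnr, 1.0), 2) == 0.43
        assert round(normalized_expected_risk(fpr, fnr, 10.0), 2) == 2.39
        assert normalized_expected_risk(0, 0, 7.0) == 0

    @settings(derandomize=True, max_examples=100)
    @given(fpr=rates, fnr=rates, w_fp=pos_reals, w_fn=pos_reals, p=pos_reals, n=pos_reals)
    def test_linear_transform_identity(self, fpr, fnr, w_fp, w_fn, p, n):
        """ER equals (w_fp * N) times the normalized form, and WBA is its
        affine mirror (1 + c - ER~)/(1 + c)."""
        weights = RiskWeights(w_fp, w_fn)
        cohort = CohortComposition(p, n)
        c = risk_ratio(weights, cohort)
        er = expected_risk(fpr, fnr, weights, cohort)
        er_tilde = normalized_expected_risk(fpr, fnr, c)
        assert er == pytest.approx(er_tilde * w_fp * n, rel=1e-12)
        assert wba(1 - fnr, 1 - fpr, c) == pytest.approx(
            (1 + c - er_tilde) / (1 + c), rel=1e-12, abs=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(fpr=rates, fnr=rates, c=pos_reals, scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, fpr, fnr, c, scale):
        """Rescaling both cost weights leaves c_fn, ER~ and WBA unchanged."""
        w1 = RiskWeights(1.0, c)
        w2 = RiskWeights(scale, c * scale)
        cohort = CohortComposition(1.0, 1.0)
        assert risk_ratio(w1, cohort) == pytest.approx(risk_ratio(w2, cohort))
        assert expected_risk(fpr, fnr, w2, cohort) == pytest.approx(
            scale * expected_risk(fpr, fnr, w1, cohort), rel=1e-12
        )


class TestWba:
    def test_examples(self):
        assert wba(1, 1, 3.7) == 1.0
        # (4 * 0.8 + 0.6) / 5: the costly-FN ratio up-weights sensitivity
        assert wba(0.8, 0.6, 4.0) == pytest.approx(0.76)

    @settings(derandomize=True, max_examples=50)
    @given(tpr=rates, tnr=rates)
    def test_reduces_to_balanced_accuracy_at_unit_ratio(self, tpr, tnr):
        assert wba(tpr, tnr, 1.0) == pytest.approx((tpr + tnr) / 2)

    @settings(derandomize=True, max_examples=50)
    @given(tpr=rates, tnr=rates, c=pos_reals, eps=st.floats(0.0, 0.5))
    def test_monotone_in_error_rates(self, tpr, tnr, c, eps):
        """Raising either error rate can only lower WBA."""
        worse_tpr = max(tpr - eps, 0.0)
        worse_tnr = max(tnr - eps, 0.0)
        base = wba(tpr, tnr, c)
        assert wba(worse_tpr, tnr, c) <= base + 1e-12
        assert wba(tpr, worse_tnr, c) <= base + 1e-12

    def test_weights_sum_to_one(self):
        w_tp, w_tn = wba_weights(4.0)
        assert w_tp + w_tn == pytest.approx(1.0)
        assert w_tp / w_tn == pytest.approx(4.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wba(1.2, 0.5, 1.0)
        with pytest.raises(ValueError):
            wba(0.5, 0.5, 0.0)


class TestStandardMetrics:
    def test_perfect_classifier(self):
        r = standard_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        for name in ("acc", "ba", "f1", "mcc", "kappa", "tpr", "tnr", "gmean"):
            assert getattr(r, name) == pytest.approx(1.0)
        assert r.err == pytest.approx(0.0)

    def test_hand_evaluated_table(self):
        r = standard_metrics(ConfusionCounts(tp=45, fn=5, tn=45, fp=5))
        assert r.acc == pytest.approx(0.9)
        assert r.ba == pytest.approx(0.9)
        assert r.f1 == pytest.approx(0.9)
        assert r.mcc == pytest.approx(0.8)

    def test_fbeta_independent_of_beta_when_ppv_equals_tpr(self):
        r = standard_metrics(ConfusionCounts(tp=45, fn=5, tn=45, fp=5), beta=2.0)
        assert r.fbeta == pytest.approx(0.9)

    def test_undefined_ratios_are_nan_not_zero(self):
        # nothing predicted positive -> PPV, F1 undefined
        r = standard_metrics(ConfusionCounts(tp=0, fp=0, tn=50, fn=50))
        assert math.isnan(r.ppv) and math.isnan(r.f1) and math.isnan(r.mcc)
        assert r.tnr == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            standard_metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(tp=counts, fp=counts, tn=counts, fn=counts)
    def test_mcc_rate_form_equals_count_form(self, tp, fp, tn, fn):
        """The product-of-rates MCC equals the covariance (count) form
        whenever all four marginals are non-zero."""
        if min(tp + fn, tn + fp, tp + fp, tn + fn) == 0:
            return
        r = standard_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        num = tp * tn - fp * fn
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert r.mcc == pytest.approx(num / den, abs=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(tp=counts, fp=counts, tn=counts, fn=counts)
    def test_identity_weighted_kappa_equals_unweighted(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        r = standard_metrics(
            ConfusionCounts(tp, fp, tn, fn), kappa_weights=[[1, 0], [0, 1]]
        )
        if math.isnan(r.kappa):
            assert math.isnan(r.weighted_kappa)
        else:
            assert r.weighted_kappa == pytest.approx(r.kappa, abs=1e-12)

    def test_report_with_risk_ratio_and_serialization(self):
        r = standard_metrics(ConfusionCounts(45, 5, 45, 5), c_fn=4.0)
        assert r.wba == pytest.approx(wba(0.9, 0.9, 4.0))
        assert r.er_tilde == pytest.approx(normalized_expected_risk(0.1, 0.1, 4.0))
        d = r.to_dict()
        assert d["acc"] == pytest.approx(0.9)
        assert set(r.to_frame().columns) == set(d)


def test_aggregate_weight_sums_probability_severity_products():
    strata = [(0.1, 10.0), (0.01, 100.0)]
    assert aggregate_weight(strata) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        aggregate_weight([(1.5, 1.0)])
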