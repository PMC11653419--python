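"""Unit and property tests for the unequal-variance logistic SDT mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from uvsdt.sdt import (
    ConfusionProbabilities,
    LogisticComponent,
    SdtModel,
    UtilityContext,
    auc,
    cdf,
    confusion_at_criterion,
    criterion_for_beta,
    likelihood_ratio,
    logit_roc,
    lr_extremum,
    map_criterion_back,
    optimal_beta,
    pdf,
    reverse_model,
    roc_curve,
    unbiased_criterion,
)

component_strategy = st.builds(
    LogisticComponent,
    mu=st.floats(-10.0, 50.0),
    s=st.floats(5.0, 40.0),
)


def make_model(mu1, s1, mu2, s2, span=10.0):
    lo = min(mu1 - span * s1, mu2 - span * s2)
    hi = max(mu1 + span * s1, mu2 + span * s2)
    return SdtModel(LogisticComponent(mu1, s1), LogisticComponent(mu2, s2), lo, hi)


# ---------------------------------------------------------------------------
# distribution functions


@pytest.mark.parametrize(
    "mu, s, x, expected",
    [(0.0, 1.0, 0.0, 0.5), (37.0, 20.0, 37.0, 0.5), (0.0, 1.0, 100.0, 1.0)],
)
def test_cdf_location_and_tails(mu, s, x, expected):
    assert cdf(LogisticComponent(mu, s), x) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("mu, s", [(0.0, 1.0), (37.0, 20.0), (-5.0, 0.5)])
def test_pdf_peak_is_quarter_scale(mu, s):
    assert pdf(LogisticComponent(mu, s), mu) == pytest.approx(1.0 / (4.0 * s))


def test_pdf_matches_scipy_logistic(rng):
    comp = LogisticComponent(12.0, 7.5)
    x = rng.uniform(-50, 80, 40)
    np.testing.assert_allclose(
        pdf(comp, x), stats.logistic.pdf(x, loc=12.0, scale=7.5), rtol=1e-12
    )
    np.testing.assert_allclose(
        cdf(comp, x), stats.logistic.cdf(x, loc=12.0, scale=7.5), rtol=1e-12
    )


def test_distribution_functions_are_overflow_safe():
    comp = LogisticComponent(0.0, 1.0)
    for x in (-1e6, 1e6):
        assert np.isfinite(cdf(comp, x))
        assert np.isfinite(pdf(comp, x))


def test_invalid_scale_rejected():
    with pytest.raises(ValueError):
        LogisticComponent(0.0, -1.0)
    with pytest.raises(ValueError):
        LogisticComponent.from_theta(0.0, -0.1)


def test_theta_parameterization_roundtrip():
    comp = LogisticComponent.from_theta(-2.0, 0.05)
    assert comp.mu == pytest.approx(40.0)
    assert comp.s == pytest.approx(20.0)
    assert comp.theta1 == pytest.approx(-2.0)
    assert comp.theta2 == pytest.approx(0.05)


# ---------------------------------------------------------------------------
# confusion probabilities


def test_confusion_everything_above_low_criterion():
    m = make_model(-1.0, 1.0, 1.0, 1.0)
    c = confusion_at_criterion(m, -1e9)
    assert c.tp == pytest.approx(1.0) and c.fp == pytest.approx(1.0)
    assert c.tn == pytest.approx(0.0) and c.fn == pytest.approx(0.0)


def test_confusion_mirror_symmetry_at_midpoint():
    m = make_model(-1.0, 1.0, 1.0, 1.0)
    c = confusion_at_criterion(m, 0.0)
    assert c.tp == pytest.approx(1.0 - c.fp, abs=1e-15)


def test_confusion_matches_quadrature_of_pdf():
    """tp/fp are the pdf areas above the criterion (numeric quadrature oracle)."""
    m = make_model(-1.0, 1.0, 1.0, 2.0)
    c = confusion_at_criterion(m, 0.5)
    tp_num, _ = integrate.quad(lambda t: pdf(m.s2, t), 0.5, np.inf)
    fp_num, _ = integrate.quad(lambda t: pdf(m.s1, t), 0.5, np.inf)
    assert c.tp == pytest.approx(tp_num, abs=1e-9)
    assert c.fp == pytest.approx(fp_num, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(s1=component_strategy, s2=component_strategy, u=st.floats(0.01, 0.99))
def test_confusion_conservation_property(s1, s2, u):
    m = SdtModel(s1, s2, -200.0, 300.0)
    c = confusion_at_criterion(m, -200.0 + 500.0 * u)
    assert abs(c.tp + c.fn - 1.0) < 1e-12
    assert abs(c.fp + c.tn - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# ROC / AUC / logit-ROC


def test_roc_endpoints_reach_corners_on_wide_range():
    m = SdtModel(LogisticComponent(-1, 1), LogisticComponent(1, 1), -13.0, 13.0)
    roc = roc_curve(m, n_grid=512)
    assert roc.fp[0] < 1e-5 and roc.tp[0] < 1e-5
    assert roc.fp[-1] > 1 - 1e-5 and roc.tp[-1] > 1 - 1e-5


def test_roc_bounded_range_stays_interior():
    m = SdtModel(LogisticComponent(40, 20), LogisticComponent(20, 20), 0.0, 120.0)
    roc = roc_curve(m)
    assert roc.fp[0] > 0 and roc.tp[0] > 0
    assert roc.fp[-1] < 1 and roc.tp[-1] < 1


def test_roc_identical_components_lie_on_diagonal():
    m = SdtModel(LogisticComponent(0, 5), LogisticComponent(0, 5), -60.0, 60.0)
    roc = roc_curve(m)
    np.testing.assert_allclose(roc.fp, roc.tp, atol=1e-12)
    assert auc(roc, mode="closed") == pytest.approx(0.5, abs=1e-6)


def test_roc_monotone_along_grid():
    m = make_model(-1.0, 1.0, 1.0, 2.0)
    roc = roc_curve(m)
    assert np.all(np.diff(roc.fp) >= 0)
    assert np.all(np.diff(roc.tp) >= 0)


def test_partial_auc_nested_in_closed():
    m = SdtModel(LogisticComponent(40, 20), LogisticComponent(20, 20), 0.0, 120.0)
    roc = roc_curve(m)
    assert auc(roc, mode="partial") < auc(roc, mode="closed")


def test_auc_closed_matches_monte_carlo(rng):
    """Closed AUC on full support equals P(X2 > X1) (sampling oracle)."""
    m = SdtModel(LogisticComponent(-1, 1), LogisticComponent(1, 1), -25.0, 25.0)
    a = auc(roc_curve(m, n_grid=4096), mode="closed")
    n = 10**6
    x1 = rng.logistic(-1.0, 1.0, n)
    x2 = rng.logistic(1.0, 1.0, n)
    assert a == pytest.approx(np.mean(x2 > x1), abs=0.005)


@pytest.mark.parametrize(
    "mu1, s1, mu2, s2, slope, intercept",
    [
        (-1.0, 1.0, 1.0, 1.0, 1.0, 2.0),  # equal variance, accuracy index 2mu/s = 2
        (0.0, 2.0, 0.0, 1.0, 2.0, 0.0),  # pure scale ratio
        (40.0, 20.0, 20.0, 20.0, 1.0, -1.0),
    ],
)
def test_logit_roc_analytic_values(mu1, s1, mu2, s2, slope, intercept):
    m = make_model(mu1, s1, mu2, s2)
    lr = logit_roc(m)
    assert lr.slope == pytest.approx(slope)
    assert lr.intercept == pytest.approx(intercept)


@settings(max_examples=100, derandomize=True)
@given(s1=component_strategy, s2=component_strategy)
def test_logit_roc_empirical_matches_analytic(s1, s2):
    lo = max(s1.mu - 10 * s1.s, s2.mu - 10 * s2.s)
    hi = min(s1.mu + 10 * s1.s, s2.mu + 10 * s2.s)
    m = SdtModel(s1, s2, min(lo, hi - 1.0), max(hi, lo + 1.0))
    lr = logit_roc(m)
    assert lr.slope_empirical == pytest.approx(lr.slope, abs=1e-6, rel=1e-6)
    assert lr.intercept_empirical == pytest.approx(lr.intercept, abs=1e-6, rel=1e-6)


# ---------------------------------------------------------------------------
# likelihood ratio and criteria


def test_lr_identical_components_is_one():
    m = SdtModel(LogisticComponent(3, 2), LogisticComponent(3, 2), -10, 20)
    x = np.linspace(-10, 20, 50)
    np.testing.assert_allclose(likelihood_ratio(m, x), 1.0, atol=1e-12)


def test_lr_symmetric_model_at_midpoint():
    m = make_model(-1.0, 1.0, 1.0, 1.0)
    assert likelihood_ratio(m, 0.0) == pytest.approx(1.0, abs=1e-12)


def test_lr_matches_direct_pdf_quotient():
    m = make_model(-1.0, 1.0, 1.0, 2.0)
    expected = stats.logistic.pdf(3.0, 1.0, 2.0) / stats.logistic.pdf(3.0, -1.0, 1.0)
    assert likelihood_ratio(m, 3.0) == pytest.approx(expected, rel=1e-12)


def test_unbiased_criterion_symmetric_model():
    m = SdtModel(LogisticComponent(-1, 1), LogisticComponent(1, 1), -5.0, 5.0)
    res = unbiased_criterion(m)
    assert len(res.roots) == 1
    assert res.roots[0].x == pytest.approx(0.0, abs=1e-9)
    assert res.roots[0].class_below == "lenient"
    assert res.roots[0].class_above == "strict"


def test_unbiased_criterion_always_strict():
    # S2 dominates everywhere on the range: no crossing, flagged always strict
    m = SdtModel(LogisticComponent(-60, 30), LogisticComponent(0, 10), -5.0, 5.0)
    res = unbiased_criterion(m)
    grid = likelihood_ratio(m, np.linspace(-5, 5, 1000))
    assert np.all(grid > 1.0)
    assert res.roots == ()
    assert res.always == "strict"


def test_criterion_for_beta_one_equals_unbiased():
    m = make_model(-1.0, 1.0, 1.0, 2.0)
    assert criterion_for_beta(m, 1.0).values() == unbiased_criterion(m).values()


def test_criterion_for_beta_no_solution_above_max_lr():
    m = SdtModel(LogisticComponent(0, 2), LogisticComponent(0, 1), -8.0, 8.0)
    _, lr_max, _ = lr_extremum(m)
    res = criterion_for_beta(m, lr_max * 2.0)
    assert res.roots == ()


def test_criterion_roots_hit_target_ratio():
    m = make_model(-1.0, 1.0, 1.0, 2.0)
    for beta in (0.5, 1.0, 1.7):
        for root in criterion_for_beta(m, beta).roots:
            assert abs(likelihood_ratio(m, root.x) - beta) < 1e-8


def test_two_roots_with_unequal_scales():
    # s2 < s1: interior LR maximum, so a beta just below it crosses twice
    m = SdtModel(LogisticComponent(0, 2), LogisticComponent(0, 1), -8.0, 8.0)
    _, lr_max, kind = lr_extremum(m)
    assert kind == "maximum"
    res = criterion_for_beta(m, 0.9 * lr_max)
    assert len(res.roots) == 2


# ---------------------------------------------------------------------------
# extremum


def test_lr_extremum_equal_scales_is_monotone():
    m = make_model(-1.0, 1.0, 1.0, 1.0)
    assert lr_extremum(m) is None


@pytest.mark.parametrize("s1, s2, kind", [(2.0, 1.0, "maximum"), (1.0, 2.0, "minimum")])
def test_lr_extremum_kind_follows_scale_order(s1, s2, kind):
    m = SdtModel(LogisticComponent(0, s1), LogisticComponent(0, s2), -12.0, 12.0)
    out = lr_extremum(m)
    assert out is not None and out[2] == kind


def test_lr_extremum_dominates_grid():
    m = SdtModel(LogisticComponent(0, 2), LogisticComponent(1, 1), -12.0, 12.0)
    x_star, lr_star, kind = lr_extremum(m)
    grid = likelihood_ratio(m, np.linspace(-12, 12, 10_000))
    assert kind == "maximum"
    assert lr_star >= grid.max() - 1e-9


# ---------------------------------------------------------------------------
# utility context


def test_optimal_beta_unbiased_case():
    ctx = UtilityContext(0.5, 0.5, b_pp=2.0, b_nn=2.0, c_pn=2.0, c_np=2.0)
    assert optimal_beta(ctx) == pytest.approx(1.0)


def test_optimal_beta_arithmetic():
    ctx = UtilityContext(0.75, 0.25, b_pp=1.0, b_nn=3.0, c_pn=1.0, c_np=1.0)
    assert optimal_beta(ctx) == pytest.approx((0.25 / 0.75) * 4.0 / 2.0)


def test_optimal_beta_scale_invariance():
    a = UtilityContext(0.6, 0.4, 1.0, 2.0, 3.0, 4.0)
    b = UtilityContext(0.6, 0.4, 10.0, 20.0, 30.0, 40.0)
    assert optimal_beta(a) == pytest.approx(optimal_beta(b))


def test_optimal_beta_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        optimal_beta(UtilityContext(0.5, 0.5, 0.0, 1.0, 0.0, 1.0))


def test_utility_context_base_rates_validated():
    with pytest.raises(ValueError):
        UtilityContext(0.7, 0.4, 1, 1, 1, 1)


# ---------------------------------------------------------------------------
# reversal


def test_reverse_model_roundtrip():
    m = SdtModel(LogisticComponent(40, 20), LogisticComponent(20, 15), 0.0, 120.0)
    back = reverse_model(reverse_model(m, offset=120.0))
    assert back.s1 == m.s1 and back.s2 == m.s2
    assert back.x_min == m.x_min and back.x_max == m.x_max
    assert back.orientation == "as_is"


def test_reversed_criteria_map_back():
    m = SdtModel(LogisticComponent(40, 20), LogisticComponent(20, 15), 0.0, 120.0)
    rev = reverse_model(m, offset=120.0)
    c_orig = unbiased_criterion(m).values()
    c_rev = [map_criterion_back(rev, c) for c in unbiased_criterion(rev).values()]
    np.testing.assert_allclose(sorted(c_orig), sorted(c_rev), atol=1e-6)
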