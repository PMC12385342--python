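"""Unit, oracle and property tests for the agreement statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rvellipsoid.agreement import (
    bland_altman,
    ci_overlap_significant,
    classify_ccc,
    lin_ccc,
    median_with_ci,
    run_agreement,
)
from rvellipsoid.estimators import REFERENCE_LABEL, compute_all_variants


# ---------------------------------------------------------------- oracles

def ccc_from_definition(x, y):
    """Brute-force CCC: population moments straight from the definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sxy = ((x - mx) * (y - my)).sum() / n
    sx2 = ((x - mx) ** 2).sum() / n
    sy2 = ((y - my) ** 2).sum() / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def ols_from_definition(x, y):
    """Closed-form simple OLS slope and intercept."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean()


# ----------------------------------------------------------- median CI

def test_median_examples():
    med, ci = median_with_ci(np.zeros(10))
    assert med == 0 and ci == (0.0, 0.0)
    med, _ = median_with_ci([-1, 0, 2, 3, 5], alpha=0.5)
    assert med == 2


def test_median_small_n_returns_range_with_warning():
    with pytest.warns(UserWarning, match="whole sample range"):
        med, ci = median_with_ci([1.0, 2.0, 4.0])
    assert med == 2.0 and ci == (1.0, 4.0)


def test_median_ci_is_valid_order_statistic_interval():
    """Endpoints are sample order statistics and the defining binomial tail
    condition holds (coverage >= 95% by construction)."""
    rng = np.random.default_rng(3)
    for n in (6, 10, 20, 67):
        x = np.sort(rng.normal(size=n))
        _, (lo, hi) = median_with_ci(x)
        l = int(np.searchsorted(x, lo)) + 1  # 1-based rank
        assert hi == x[n - l]
        assert stats.binom.cdf(l - 1, n, 0.5) <= 0.025
        assert stats.binom.cdf(l, n, 0.5) > 0.025  # largest such rank


def test_median_empty_errors():
    with pytest.raises(ValueError):
        median_with_ci([])


# ----------------------------------------------------------------- CCC

def test_ccc_worked_examples():
    assert lin_ccc([1, 2, 3], [1, 2, 3]).ccc == pytest.approx(1.0)
    assert lin_ccc([1, 2, 3], [3, 2, 1]).ccc == pytest.approx(-1.0)
    res = lin_ccc([1, 2, 3], [2, 3, 4])
    assert res.ccc == pytest.approx(4 / 7, rel=1e-12)
    assert res.pearson_r == pytest.approx(1.0)
    assert res.bias_correction == pytest.approx(4 / 7, rel=1e-12)


def test_ccc_oracle_on_random_series():
    rng = np.random.default_rng(12)
    for _ in range(50):
        n = rng.integers(5, 21)
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(scale=0.5, size=n)
        res = lin_ccc(x, y)
        assert res.ccc == pytest.approx(ccc_from_definition(x, y), abs=1e-12)
        r = stats.pearsonr(x, y).statistic
        assert res.pearson_r == pytest.approx(r, abs=1e-10)
        assert res.ccc == pytest.approx(res.pearson_r * res.bias_correction, abs=1e-10)
        assert abs(res.ccc) <= abs(res.pearson_r) + 1e-12
        assert res.ci[0] <= res.ccc <= res.ci[1]


@given(xs=st.lists(st.floats(-100, 100), min_size=4, max_size=30, unique=True),
       shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
@settings(max_examples=100, deadline=None)
def test_ccc_invariances(xs, shift, scale):
    """CCC is symmetric and invariant under a common positive rescaling and
    common translation of both series."""
    x = np.array(xs)
    rng = np.random.default_rng(0)
    y = x + rng.normal(scale=0.1 * (x.std() + 1), size=len(x))
    a = lin_ccc(x, y).ccc
    assert lin_ccc(y, x).ccc == pytest.approx(a, abs=1e-10)
    assert lin_ccc(scale * x + shift, scale * y + shift).ccc == pytest.approx(a, abs=1e-8)


def test_ccc_equals_pearson_iff_moments_match():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = lin_ccc(x, 5.0 - x)  # same mean and SD: bias correction factor is 1
    assert res.ccc == pytest.approx(res.pearson_r, abs=1e-12)
    res2 = lin_ccc(x, x + 1.0)
    assert abs(res2.ccc) < abs(res2.pearson_r)


def test_ccc_degenerate_constant_series():
    res = lin_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert res.degenerate_ci
    with pytest.raises(ValueError):
        lin_ccc([1, 2], [1, 2])


@pytest.mark.parametrize("value,band", [
    (0.92, "moderate"), (0.89, "poor"), (0.995, "almost_perfect"),
    (0.90, "moderate"), (0.95, "substantial"), (0.99, "substantial"),
    (-0.5, "poor"),
])
def test_classify_ccc(value, band):
    assert classify_ccc(value) == band


def test_classify_ccc_out_of_range():
    with pytest.raises(ValueError):
        classify_ccc(1.5)


# -------------------------------------------------------- Bland-Altman

def test_bland_altman_worked_example():
    res = bland_altman([10, 20, 30], [12, 18, 33])
    assert res.mean_diff == pytest.approx(-1.0)
    assert res.sd_diff == pytest.approx(math.sqrt(7), rel=1e-12)
    assert res.loa[0] == pytest.approx(-1 - 1.96 * math.sqrt(7), rel=1e-12)
    assert res.loa[1] == pytest.approx(-1 + 1.96 * math.sqrt(7), rel=1e-12)
    assert res.slope == pytest.approx(-17 / 213.5, rel=1e-10)
    slope, intercept = ols_from_definition((np.array([10, 20, 30]) + [12, 18, 33]) / 2,
                                           np.array([10, 20, 30]) - np.array([12, 18, 33]))
    assert res.slope == pytest.approx(slope, abs=1e-12)
    assert res.intercept == pytest.approx(intercept, abs=1e-12)


def test_bland_altman_constant_differences():
    res = bland_altman([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
    assert res.mean_diff == 0.5
    assert res.sd_diff == 0.0
    assert res.loa == (0.5, 0.5)
    assert res.slope == 0.0 and res.slope_p == 1.0


def test_bland_altman_degenerate_means():
    res = bland_altman([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])  # all means equal 2
    assert res.slope_undefined
    assert math.isnan(res.slope)


def test_bland_altman_points_and_ci_ordering():
    rng = np.random.default_rng(5)
    y = rng.normal(10, 2, size=40)
    x = y + rng.normal(0.5, 1.0, size=40)
    res = bland_altman(x, y)
    assert len(res.points) == 40
    assert res.loa[0] < res.mean_diff < res.loa[1]
    assert res.mean_diff_ci[0] < res.mean_diff < res.mean_diff_ci[1]
    assert res.loa_ci_low[0] < res.loa[0] < res.loa_ci_low[1]
    assert res.loa_ci_high[0] < res.loa[1] < res.loa_ci_high[1]
    np.testing.assert_allclose(res.points["diff"], x - y)


# -------------------------------------------------------- CI overlap rule

@pytest.mark.parametrize("a,b,expected", [
    ((0.1, 0.3), (0.4, 0.6), True),
    ((0.1, 0.5), (0.4, 0.6), False),
    ((0.1, 0.4), (0.4, 0.6), False),  # shared endpoint counts as overlap
    ((0.4, 0.6), (0.1, 0.3), True),
])
def test_ci_overlap(a, b, expected):
    assert ci_overlap_significant(a, b) is expected


def test_ci_overlap_malformed():
    with pytest.raises(ValueError):
        ci_overlap_significant((0.5, 0.1), (0.2, 0.3))


# -------------------------------------------------------- run_agreement

def test_run_agreement_self_agreement(exact_measurements):
    """Every variant computed from exact geometry agrees perfectly with the
    reference: zero bias, CCC 1, flat regression."""
    vols = compute_all_variants(exact_measurements)
    summary, points = run_agreement(vols)
    assert (summary["median_diff"].abs() < 1e-12).all()
    assert (summary["ccc"] > 1 - 1e-12).all()
    assert not summary["systematic_bias"].any()
    assert not summary["proportional_bias"].any()
    assert set(points["method"]) == set(summary["method"])


def test_run_agreement_requires_reference(exact_measurements):
    vols = compute_all_variants(exact_measurements)
    vols = vols[vols["method"] != REFERENCE_LABEL]
    with pytest.raises(ValueError, match="reference"):
        run_agreement(vols)


def test_run_agreement_skips_underpowered_methods(exact_measurements, caplog):
    vols = compute_all_variants(exact_measurements)
    keep = (vols["method"] != "AEM_RPL-A2C") | (vols["dog_id"] == "dog001")
    with caplog.at_level("WARNING"):
        summary, _ = run_agreement(vols[keep])
    assert "AEM_RPL-A2C" not in set(summary["method"])
    assert "skipping" in caplog.text
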