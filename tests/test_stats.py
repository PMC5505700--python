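"""Correlation, factorial simple effects, percent change, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest

from tsc2sig.io import ValidationError
from tsc2sig.stats import (
    km_estimate,
    logrank,
    partial_correlation,
    pearson,
    percent_change,
    two_way_simple_effects,
)


# ---------------------------------------------------------------------------
# Pearson and partial correlation

def test_pearson_perfect_linearity():
    res = pearson([1, 2, 3], [2, 4, 6])
    assert res.r == pytest.approx(1.0)
    assert res.p_value < 1e-6


def test_pearson_orthogonal_deviations():
    res = pearson([-1.0, 0.0, 1.0], [1.0, -2.0, 1.0])
    assert res.r == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_pearson_matches_bruteforce_formula():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=20), rng.normal(size=20)
    res = pearson(x, y)
    xc, yc = x - x.mean(), y - y.mean()
    r_hand = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert res.r == pytest.approx(r_hand, abs=1e-12)


def test_pearson_affine_invariance_and_symmetry():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=15), rng.normal(size=15)
    assert pearson(x, y).r == pytest.approx(pearson(y, x).r, abs=1e-12)
    assert pearson(3.0 * x + 7.0, y).r == pytest.approx(pearson(x, y).r, abs=1e-12)


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValidationError, match="variance"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_partial_correlation_formula_value():
    """r_xy = r_xz = r_yz = 0.5 gives r_xy.z = 0.25/0.75 = 1/3 by the formula."""
    r = (0.5 - 0.5 * 0.5) / np.sqrt((1 - 0.25) * (1 - 0.25))
    assert r == pytest.approx(1 / 3)


def test_partial_correlation_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    n = 50
    z = rng.normal(size=n)
    x = 0.5 * z + rng.normal(size=n)
    y = -0.4 * z + rng.normal(size=n)
    res = partial_correlation(x, y, z)
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)
    assert res.n == n


def test_partial_correlation_uncorrelated_covariate_reduces_to_pearson():
    rng = np.random.default_rng(6)
    n = 2000
    x, y = rng.normal(size=n), rng.normal(size=n)
    z = rng.normal(size=n)
    marginal = pearson(x, y).r
    partial = partial_correlation(x, y, z).r
    assert partial == pytest.approx(marginal, abs=0.05)


def test_partial_correlation_degenerate_covariate():
    x = np.arange(10.0)
    with pytest.raises(ValidationError, match="collinear"):
        partial_correlation(x, np.random.default_rng(0).normal(size=10), x)


# ---------------------------------------------------------------------------
# factorial simple effects

def test_simple_effects_closed_form_with_zero_residual():
    # balanced cells with constant values: effect of A at each B level is exact
    value = [10.0, 10.0, 14.0, 14.0, 20.0, 20.0, 21.0, 21.0]
    a = ["no", "no", "yes", "yes", "no", "no", "yes", "yes"]
    b = ["lo", "lo", "lo", "lo", "hi", "hi", "hi", "hi"]
    eff = two_way_simple_effects(value, a, b).set_index("b_level")
    assert eff.loc["lo", "effect"] == pytest.approx(4.0)
    assert eff.loc["hi", "effect"] == pytest.approx(1.0)


def test_simple_effects_match_regression_oracle():
    """Unbalanced design vs normal equations solved directly."""
    rng = np.random.default_rng(7)
    n = 60
    a = rng.choice([0, 1], size=n, p=[0.4, 0.6])
    b = rng.choice([0, 1], size=n, p=[0.7, 0.3])
    y = 2.0 + 1.5 * a - 0.8 * b + 2.2 * a * b + rng.normal(size=n)
    eff = two_way_simple_effects(y, a, b).set_index("b_level")

    # oracle: cell-mean model by least squares, pooled residual variance
    X = np.column_stack([np.ones(n), a, b, a * b])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 4
    mse = (resid**2).sum() / dof
    for lb in (0, 1):
        m0 = y[(a == 0) & (b == lb)]
        m1 = y[(a == 1) & (b == lb)]
        effect = m1.mean() - m0.mean()
        se = np.sqrt(mse * (1 / len(m0) + 1 / len(m1)))
        assert eff.loc[lb, "effect"] == pytest.approx(effect, abs=1e-10)
        assert eff.loc[lb, "se"] == pytest.approx(se, abs=1e-10)
        assert eff.loc[lb, "df"] == dof


def test_simple_effects_empty_cell_named():
    value = [1.0, 2.0, 3.0, 4.0]
    a = ["no", "no", "yes", "yes"]
    b = ["lo", "lo", "lo", "lo"]
    with pytest.raises(ValidationError, match="both factors must be binary|empty cell"):
        two_way_simple_effects(value, a, b)


# ---------------------------------------------------------------------------
# percent change

@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ([100.0, 100.0], [167.0, 167.0], 67),
        ([100.0, 100.0], [75.0, 75.0], -25),
        ([5.0, 5.0], [5.0, 5.0], 0),
    ],
)
def test_percent_change_values(ref, alt, expected):
    pct, _ = percent_change(ref, alt)
    assert pct == expected


def test_percent_change_zero_reference_rejected():
    with pytest.raises(ValidationError, match="zero"):
        percent_change([0.0, 0.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# survival

def test_km_no_censoring_equals_empirical_survival():
    curve = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
    steps = dict(zip(curve.times, curve.survival))
    for t, s in [(1, 0.8), (2, 0.6), (3, 0.4), (4, 0.2), (5, 0.0)]:
        assert steps[t] == pytest.approx(s)
    assert curve.median == 3 and curve.median_defined


def test_km_all_censored_median_undefined():
    curve = km_estimate([2, 4, 6], [0, 0, 0])
    assert (curve.survival == 1.0).all()
    assert not curve.median_defined and np.isnan(curve.median)


def test_km_mixed_censoring_hand_table():
    # times 1,2+,3,4+,5,6 with events at 1,3,5,6:
    # S(1)=5/6, S(3)=5/6*3/4=0.625, S(5)=0.625*1/2=0.3125, S(6)=0
    curve = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1])
    steps = dict(zip(curve.times, curve.survival))
    assert steps[1.0] == pytest.approx(5 / 6)
    assert steps[3.0] == pytest.approx(0.625)
    assert steps[5.0] == pytest.approx(0.3125)
    assert steps[6.0] == pytest.approx(0.0)
    assert curve.median == 5  # smallest t with S <= 0.5


def test_km_survival_nonincreasing_property():
    rng = np.random.default_rng(8)
    times = rng.exponential(10.0, size=40)
    events = rng.random(40) < 0.7
    curve = km_estimate(times, events)
    assert (np.diff(curve.survival) <= 1e-12).all()
    assert curve.survival[0] <= 1.0


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValidationError, match="positive"):
        km_estimate([0.0, 1.0], [1, 1])


def test_logrank_identical_groups():
    times = [1, 2, 3, 4, 1, 2, 3, 4]
    events = [1, 1, 1, 0, 1, 1, 1, 0]
    groups = ["a"] * 4 + ["b"] * 4
    chi2, p = logrank(times, events, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_label_swap_invariant():
    rng = np.random.default_rng(9)
    times = rng.exponential(5.0, size=30)
    events = rng.random(30) < 0.8
    groups = np.array(["a", "b"] * 15)
    chi2_ab, _ = logrank(times, events, groups)
    swapped = np.where(groups == "a", "b", "a")
    chi2_ba, _ = logrank(times, events, swapped)
    assert chi2_ab == pytest.approx(chi2_ba, abs=1e-10)


def test_logrank_detects_strong_separation():
    rng = np.random.default_rng(10)
    t1 = rng.exponential(1.0, size=50)   # hazard ratio 5
    t2 = rng.exponential(5.0, size=50)
    times = np.concatenate([t1, t2])
    events = np.ones(100, dtype=bool)
    groups = np.array(["fast"] * 50 + ["slow"] * 50)
    _, p = logrank(times, events, groups)
    assert p < 0.001


def test_logrank_single_group_rejected():
    with pytest.raises(ValidationError, match="2 groups"):
        logrank([1, 2], [1, 1], ["a", "a"])
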