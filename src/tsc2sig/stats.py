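"""Clinical and phenotype association statistics used around the signature.

Pearson and first-order partial correlation, simple main effects of a 2x2
factorial, group percent change, Kaplan-Meier estimation and the two-group
log-rank test.  The survival machinery delegates to lifelines and the
factorial omnibus fit to statsmodels; the correlation formulas are small
closed forms implemented directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    kind: str = "pearson"  # "pearson" or "partial"

    def summary(self) -> str:
        return f"{self.kind} r = {self.r:.4g}, p = {self.p_value:.4g} (n = {self.n})"


def _t_pvalue(r: float, df: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def pearson(x, y) -> CorrelationResult:
    """Two-sided Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need n >= 3 for a correlation p-value")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=n)


def partial_correlation(x, y, z) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the p-value
    uses a t distribution with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not len(x) == len(y) == len(z):
        raise ValidationError("x, y, z must have equal length")
    n = len(x)
    if n < 4:
        raise ValidationError("need n >= 4 for a partial correlation")
    r_xy = pearson(x, y).r
    r_xz = pearson(x, z).r
    r_yz = pearson(y, z).r
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValidationError("covariate is collinear with x or y (|r| = 1)")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    return CorrelationResult(r=float(r), p_value=_t_pvalue(float(r), n - 3), n=n, kind="partial")


def two_way_simple_effects(value, factor_a, factor_b) -> pd.DataFrame:
    """Simple main effects of factor A at each level of factor B (2x2 factorial).

    Fits the full interaction model by OLS, then tests the contrast of cell
    means A(level2) - A(level1) within each level of B using the pooled
    residual variance of the interaction model.  Returns one row per level of
    B with the effect estimate, standard error, t, df and two-sided p, plus
    the Type III omnibus p-values attached in ``DataFrame.attrs['omnibus']``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"value": np.asarray(value, dtype=float), "a": np.asarray(factor_a), "b": np.asarray(factor_b)}
    )
    levels_a = sorted(df["a"].unique())
    levels_b = sorted(df["b"].unique())
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValidationError("both factors must be binary")
    counts = df.groupby(["a", "b"], observed=True).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise ValidationError(f"empty cell: a={la!r}, b={lb!r}")

    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    omnibus = sm.stats.anova_lm(model, typ=3)
    mse = model.mse_resid
    dof = int(model.df_resid)

    rows = []
    for lb in levels_b:
        sub = df[df["b"] == lb]
        m1 = sub.loc[sub["a"] == levels_a[0], "value"]
        m2 = sub.loc[sub["a"] == levels_a[1], "value"]
        effect = m2.mean() - m1.mean()
        se = np.sqrt(mse * (1.0 / len(m1) + 1.0 / len(m2)))
        if se == 0:
            t, p = np.inf * np.sign(effect) if effect else 0.0, 0.0 if effect else 1.0
        else:
            t = effect / se
            p = float(2.0 * sps.t.sf(abs(t), dof))
        rows.append(
            {
                "b_level": lb,
                "effect": float(effect),
                "se": float(se),
                "t": float(t),
                "df": dof,
                "p_value": p,
                "n": len(sub),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["omnibus"] = omnibus
    return out


def percent_change(group_ref, group_alt) -> tuple[int, float]:
    """Signed percent change of the alternative group mean vs the reference mean.

    Returns (rounded percentage, Welch-t two-sided p-value).
    """
    ref = np.asarray(group_ref, dtype=float)
    alt = np.asarray(group_alt, dtype=float)
    if ref.mean() == 0:
        raise ValidationError("reference group mean is zero; percent change undefined")
    pct = 100.0 * (alt.mean() - ref.mean()) / ref.mean()
    p = float(sps.ttest_ind(ref, alt, equal_var=False).pvalue)
    # round half up toward the reporting convention
    return int(np.floor(pct + 0.5)) if pct >= 0 else -int(np.floor(-pct + 0.5)), p


@dataclass
class SurvivalCurve:
    """Product-limit survival curve with the smallest-t-with-S<=0.5 median."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # NaN when S never reaches 0.5
    median_defined: bool

    def summary(self) -> str:
        med = f"{self.median:g}" if self.median_defined else "undefined (S stays > 0.5)"
        return f"Kaplan-Meier curve over {len(self.times)} event times; median = {med}"


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` is True/1 for an observed event and False/0 for censoring.  The
    median is the smallest observed time with S(t) <= 0.5 and is flagged
    undefined when the curve never drops that far.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValidationError("need at least one record")
    if (times <= 0).any():
        raise ValidationError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    ev = kmf.event_table
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    below = np.where(surv <= 0.5)[0]
    if len(below):
        median, defined = float(grid[below[0]]), True
    else:
        median, defined = float("nan"), False
    return SurvivalCurve(times=grid, survival=surv, at_risk=at_risk, median=median, median_defined=defined)


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p-value)."""
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    m1 = groups == labels[0]
    res = logrank_test(times[m1], times[~m1], event_observed_A=events[m1], event_observed_B=events[~m1])
    return float(res.test_statistic), float(res.p_value)


def plot_km(times, events, groups=None, ax=None):
    """Kaplan-Meier plot, optionally stratified by a group label."""
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    if ax is None:
        _, ax = plt.subplots()
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if groups is None:
        KaplanMeierFitter().fit(times, events).plot_survival_function(ax=ax)
    else:
        groups = np.asarray(groups)
        for label in pd.unique(groups):
            m = groups == label
            KaplanMeierFitter().fit(times[m], events[m], label=str(label)).plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    return ax
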