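"""Stage-wise association statistics.

Simple linear regressions among uPA expression, miR-23 expression and
promoter methylation rate within each disease-stage group; one-way ANOVA
with Bonferroni-corrected pairwise Welch t-tests for group comparisons;
and the two-sample normal-approximation sample-size formula used to check
enrollment power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import MM_GROUPS

__all__ = [
    "RegressionFit",
    "GroupComparison",
    "PowerSpec",
    "fit_linear",
    "stage_association_report",
    "compare_groups",
    "required_sample_size",
    "STAGE_ASSOCIATIONS",
]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of Y on X with a two-sided slope test."""

    slope: float
    intercept: float
    n: int
    r2: float
    p_slope: float
    stderr: float = math.nan  # standard error of the slope

    @property
    def equation(self) -> str:
        """Equation string with coefficients at 4 significant digits."""
        a = f"{self.slope:.4g}"
        b = f"{abs(self.intercept):.4g}"
        op = "-" if self.intercept < 0 else "+"
        return f"Y = {a}*X {op} {b}"


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS of y on x; p from the slope t-statistic with n-2 df, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x is constant")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=n,
        r2=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        stderr=float(res.stderr),
    )


# (report label, x column, y column, expected slope sign)
STAGE_ASSOCIATIONS = (
    ("uPA with miR-23", "upa", "mir23", -1),
    ("miR-23 with methylation", "meth_rate", "mir23", -1),
    ("uPA with methylation", "meth_rate", "upa", +1),
)


def stage_association_report(cohort: pd.DataFrame, groups: Sequence[str] = MM_GROUPS) -> pd.DataFrame:
    """Per-stage regression table among uPA, miR-23 and methylation.

    For each stage group, three fits with the conventional axes: miR-23 on
    uPA (uPA as abscissa), miR-23 on methylation, and uPA on methylation.
    Returns one row per (group, association) with slope, intercept, n, r²,
    two-sided slope P, the rendered equation, and whether the slope sign
    matches the expected direction (negative, negative, positive).
    """
    required = {"group", "meth_rate", "mir23", "upa"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    rows = []
    for g in groups:
        sub = cohort[cohort["group"] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} absent from cohort")
        for label, xcol, ycol, expect in STAGE_ASSOCIATIONS:
            fit = fit_linear(sub[xcol].to_numpy(), sub[ycol].to_numpy())
            rows.append(
                {
                    "group": g,
                    "association": label,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "n": fit.n,
                    "r2": fit.r2,
                    "p_slope": fit.p_slope,
                    "equation": fit.equation,
                    "expected_sign": expect,
                    "sign_ok": math.copysign(1, fit.slope) == expect,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA plus Bonferroni-corrected pairwise Welch t-tests."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, t, p_raw, p_adj, significant
    n_comparisons: int
    mean_order: tuple[str, ...]  # groups sorted by ascending mean
    alpha: float = 0.05


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: both groups constant
        return (0.0, 1.0) if a[0] == b[0] else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_groups(values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupComparison:
    """Compare >= 2 groups: omnibus one-way ANOVA, all pairwise Welch
    t-tests, Bonferroni adjustment over the pairwise family."""
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    arrays = list(groups.values())
    means = {g: float(v.mean()) for g, v in groups.items()}
    if len({round(x, 15) for v in arrays for x in v}) == 1:
        f_stat, f_p = 0.0, 1.0  # all observations identical
    else:
        f_stat, f_p = (float(s) for s in stats.f_oneway(*arrays))
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        t, p = _welch(groups[a], groups[b])
        p_adj = min(1.0, m * p)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": t,
                "p_raw": p,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    order = tuple(sorted(names, key=means.get))
    return GroupComparison(
        anova_f=f_stat,
        anova_p=f_p,
        pairwise=pd.DataFrame(rows),
        n_comparisons=m,
        mean_order=order,
        alpha=alpha,
    )


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample power specification (two-sided alpha, 1-beta power,
    standardized effect size delta in SD units)."""

    alpha: float = 0.05
    power: float = 0.8
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must be in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")


def required_sample_size(spec: PowerSpec) -> int:
    """Per-group n for a two-sample comparison, normal approximation:
    n = 2 (z_{1-alpha/2} + z_{1-beta})^2 / delta^2, rounded up."""
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    return math.ceil(2 * (z_a + z_b) ** 2 / spec.effect_size**2)
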