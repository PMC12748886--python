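"""Temporal trend fits and factual-vs-counterfactual comparisons.

Annual series (warm-season temperatures, AF, AF_CC, P_CC) get an OLS linear
trend, reported per decade with a t-based 95% CI, alongside Gaussian AICs of
natural-cubic-spline alternatives with 2, 3 and 4 degrees of freedom.
Differences between city-specific trends under factual versus counterfactual
conditions are tested with a two-sided Wilcoxon rank-sum test (exact for
small untied samples, normal approximation with tie correction otherwise),
pooling the 9 counterfactual ensemble members into the counterfactual group
as in the study design (15 factual vs 15 x 9 counterfactual trends).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import natural_cubic_basis, ns_knots_from_df

__all__ = ["TrendFit", "TrendComparison", "fit_trend", "compare_trends"]


@dataclass(frozen=True)
class TrendFit:
    slope_per_decade: float
    ci_lower: float
    ci_upper: float
    slope_se_per_decade: float
    aic_linear: float
    aic_spline: dict[int, float] = field(default_factory=dict)

    @property
    def best_family(self) -> str:
        best_df = min(self.aic_spline, key=self.aic_spline.get, default=None)
        if best_df is not None and self.aic_spline[best_df] < self.aic_linear:
            return f"spline_df{best_df}"
        return "linear"


def _gaussian_aic(resid: np.ndarray, n_par: int) -> float:
    n = resid.size
    sigma2 = max(float(np.mean(resid**2)), 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return -2.0 * ll + 2.0 * (n_par + 1)  # + residual variance parameter


def fit_trend(years: np.ndarray, values: np.ndarray) -> TrendFit:
    """OLS trend of an annual series, per decade, plus spline AICs."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    years, values = years[keep], values[keep]
    n = years.size
    if n < 5:
        raise ValueError(f"need >= 5 annual values, got {n}")
    res = stats.linregress(years, values)
    tcrit = stats.t.ppf(0.975, n - 2)
    resid_lin = values - (res.intercept + res.slope * years)
    aic_spline = {}
    for df in (2, 3, 4):
        inner, bounds = ns_knots_from_df(years, df)
        B = natural_cubic_basis(years, inner, (years.min(), years.max()))
        X = np.column_stack([np.ones(n), B])
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        aic_spline[df] = _gaussian_aic(values - X @ beta, X.shape[1])
    return TrendFit(
        slope_per_decade=float(res.slope * 10.0),
        ci_lower=float((res.slope - tcrit * res.stderr) * 10.0),
        ci_upper=float((res.slope + tcrit * res.stderr) * 10.0),
        slope_se_per_decade=float(res.stderr * 10.0),
        aic_linear=_gaussian_aic(resid_lin, 2),
        aic_spline=aic_spline,
    )


@dataclass(frozen=True)
class TrendComparison:
    grouping: str
    n_a: int
    n_b: int
    statistic: float
    p: float


def compare_trends(
    group_a: np.ndarray,
    group_b: np.ndarray,
    grouping: str = "withCC vs w/oCC",
) -> TrendComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two trend samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TrendComparison(
        grouping=grouping, n_a=a.size, n_b=b.size,
        statistic=float(res.statistic), p=float(res.pvalue),
    )
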