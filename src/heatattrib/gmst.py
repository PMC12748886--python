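"""Counterfactual temperature construction.

A no-climate-change daily temperature series for a city is built by removing
the locally scaled global warming signal from the observed series:

    cf(d) = t(d) - beta_city * G(year(d), month(d))

where ``G`` is the smoothed monthly global mean surface temperature (GMST)
anomaly relative to a pre-industrial reference period (default 1850-1900) and
``beta_city`` is the slope of an OLS regression of the city's annual warm
season (Jun-Sep) mean temperature on the annual mean smoothed GMST anomaly
over a long fitting window (default 1950-2022).  Smoothing uses singular
spectrum analysis (SSA) with a 120-month window; a 5-year moving average of
annual anomalies is available as a sensitivity variant.

Uncertainty is propagated through a 9-member ensemble crossing the lower,
central and upper GMST series with the lower, central and upper bounds of the
scaling slope's 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BOUNDS = ("lower", "central", "upper")
WARM_SEASON_MONTHS = (6, 7, 8, 9)
#: first day of the pre-season lag buffer (10 days before Jun 1)
BUFFER_START = (5, 22)

__all__ = [
    "ScalingFit",
    "ssa_smooth",
    "rebaseline",
    "smooth_gmst",
    "annual_warm_season_mean",
    "annual_gmst_mean",
    "fit_city_scaling",
    "build_counterfactual",
    "build_ensemble",
    "attributable_temperature",
    "moving_average_smooth",
]


# ---------------------------------------------------------------------------
# smoothing

def ssa_smooth(
    series: np.ndarray,
    window: int = 120,
    low_freq_fraction: float = 0.5,
) -> np.ndarray:
    """Extract the trend of a series by singular spectrum analysis.

    The series is embedded into a Hankel trajectory matrix with window length
    ``window``, decomposed by SVD, and reconstructed (diagonal averaging) from
    the trend group of components: those whose left singular vector is
    quasi-monotone, identified by its periodogram concentrating at periods of
    the window length or longer.  A component is kept when the fraction of
    its eigenvector's spectral power at frequencies <= 1/window is at least
    ``low_freq_fraction``.  Oscillatory (e.g. seasonal) and noise components
    fail this criterion and are discarded.

    Parameters
    ----------
    series : 1-d array, length >= 2 * window.
    window : embedding window length (months for monthly GMST), >= 2.
    low_freq_fraction : trend-group threshold on the low-frequency share of
        eigenvector power, in (0, 1].
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if window < 2:
        raise ValueError("window must be >= 2")
    if n < 2 * window:
        raise ValueError(f"series length {n} < 2 * window ({2 * window})")

    L = window
    K = n - L + 1
    idx = np.arange(L)[:, None] + np.arange(K)[None, :]
    X = y[idx]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)

    freqs = np.fft.rfftfreq(L)
    low = freqs <= 1.0 / L + 1e-12
    keep = []
    for i in range(s.size):
        if s[i] <= s[0] * 1e-12:
            break
        p = np.abs(np.fft.rfft(U[:, i])) ** 2
        if p.sum() > 0 and p[low].sum() / p.sum() >= low_freq_fraction:
            keep.append(i)
    if not keep:
        keep = [0]
    keep = np.asarray(keep)

    M = (U[:, keep] * s[keep]) @ Vt[keep]
    # diagonal (anti-diagonal) averaging back to a series
    anti = idx.ravel()
    sums = np.bincount(anti, weights=M.ravel(), minlength=n)
    counts = np.bincount(anti, minlength=n)
    return sums / counts


def moving_average_smooth(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with symmetric window shrinkage at the edges."""
    y = np.asarray(series, dtype=float)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if y.size < window:
        raise ValueError(f"series length {y.size} < window {window}")
    h = window // 2
    out = np.empty_like(y)
    for i in range(y.size):
        k = min(h, i, y.size - 1 - i)
        out[i] = y[i - k : i + k + 1].mean()
    return out


def rebaseline(
    series: pd.Series | np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Shift a series so its mean over ``mask`` (reference window) is zero."""
    y = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != y.shape:
        raise ValueError("mask must match series shape")
    if not mask.any():
        raise ValueError("reference window is empty / outside the series")
    return y - y[mask].mean()


def smooth_gmst(
    gmst: pd.DataFrame,
    window: int = 120,
    reference: tuple[int, int] = (1850, 1900),
    method: str = "ssa",
) -> pd.DataFrame:
    """Smooth monthly GMST anomalies and re-baseline to a reference period.

    ``gmst`` needs columns ``year, month, anomaly, anomaly_lower,
    anomaly_upper`` with contiguous months.  Each bound is smoothed
    independently.  Returns the input plus ``smoothed``, ``smoothed_lower``,
    ``smoothed_upper`` columns, all re-baselined so the mean over the
    reference years is zero (the raw anomaly columns are re-baselined too).

    ``method='annual-ma-5'`` replaces SSA by a 5-year moving average of
    annual mean anomalies, assigned back to every month of the year
    (sensitivity variant).
    """
    df = gmst.sort_values(["year", "month"]).reset_index(drop=True).copy()
    _check_contiguous_months(df)
    lo, hi = reference
    ref = (df["year"] >= lo) & (df["year"] <= hi)
    if not ref.any():
        raise ValueError(f"reference period {reference} outside GMST series")
    colmap = {
        "anomaly": "smoothed",
        "anomaly_lower": "smoothed_lower",
        "anomaly_upper": "smoothed_upper",
    }
    for raw, sm in colmap.items():
        y = df[raw].to_numpy(dtype=float)
        if method == "ssa":
            s = ssa_smooth(y, window=window)
        elif method == "annual-ma-5":
            annual = df.assign(_v=y).groupby("year")["_v"].mean()
            sm_annual = pd.Series(
                moving_average_smooth(annual.to_numpy(), 5), index=annual.index
            )
            s = df["year"].map(sm_annual).to_numpy()
        else:
            raise ValueError(f"unknown smoothing method {method!r}")
        df[raw] = rebaseline(y, ref.to_numpy())
        df[sm] = rebaseline(s, ref.to_numpy())
    return df


def _check_contiguous_months(df: pd.DataFrame) -> None:
    m = df["year"].to_numpy() * 12 + (df["month"].to_numpy() - 1)
    if len(m) and np.any(np.diff(m) != 1):
        raise ValueError("GMST months are not contiguous")


# ---------------------------------------------------------------------------
# annual means and scaling regression

def ensure_datetime(col: pd.Series) -> pd.Series:
    """Parse a date column unless it is already datetime64."""
    if pd.api.types.is_datetime64_any_dtype(col):
        return col
    return pd.to_datetime(col)


def annual_warm_season_mean(
    daily: pd.DataFrame,
    months: tuple[int, ...] = WARM_SEASON_MONTHS,
    value_col: str = "tmean",
) -> pd.Series:
    """Per-year mean of a daily series over the warm-season months.

    Years with missing warm-season days are excluded with a logged warning.
    """
    import calendar

    dts = ensure_datetime(daily["date"])
    mask = dts.dt.month.isin(months).to_numpy()
    years = dts.dt.year.to_numpy()[mask]
    vals = daily[value_col].to_numpy(dtype=float)[mask]
    out = {}
    for year in np.unique(years):
        sel = years == year
        expected = sum(calendar.monthrange(int(year), m)[1] for m in months)
        v = vals[sel]
        if v.size != expected or np.isnan(v).any():
            logger.warning(
                "year %d excluded from warm-season mean: %d/%d days present",
                year, int(np.isfinite(v).sum()), expected,
            )
            continue
        out[int(year)] = float(v.mean())
    return pd.Series(out, name=value_col).rename_axis("year")


def annual_gmst_mean(smoothed_gmst: pd.DataFrame, col: str = "smoothed") -> pd.Series:
    """Calendar-year mean of a smoothed monthly GMST column."""
    return smoothed_gmst.groupby("year")[col].mean()


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of a city's annual warm-season mean on annual smoothed GMST."""

    city: str
    slope: float
    slope_se: float
    slope_lower: float
    slope_upper: float
    intercept: float
    n_years: int

    def slope_bound(self, bound: str) -> float:
        return {
            "lower": self.slope_lower,
            "central": self.slope,
            "upper": self.slope_upper,
        }[bound]


def fit_city_scaling(
    annual_city_means: pd.Series,
    annual_smoothed_gmst: pd.Series,
    years: tuple[int, int] = (1950, 2022),
    city: str = "",
) -> ScalingFit:
    """Regress annual city warm-season means on annual smoothed GMST (OLS).

    The 95% CI of the slope uses the t distribution with n - 2 df.
    """
    joined = pd.concat(
        [annual_city_means.rename("t"), annual_smoothed_gmst.rename("g")],
        axis=1,
    ).dropna()
    joined = joined[(joined.index >= years[0]) & (joined.index <= years[1])]
    n = len(joined)
    if n < 10:
        raise ValueError(f"only {n} overlapping years in {years}; need >= 10")
    g = joined["g"].to_numpy()
    t = joined["t"].to_numpy()
    if np.ptp(g) == 0:
        raise ValueError("GMST predictor has zero variance")
    res = stats.linregress(g, t)
    tcrit = stats.t.ppf(0.975, n - 2)
    return ScalingFit(
        city=city,
        slope=float(res.slope),
        slope_se=float(res.stderr),
        slope_lower=float(res.slope - tcrit * res.stderr),
        slope_upper=float(res.slope + tcrit * res.stderr),
        intercept=float(res.intercept),
        n_years=n,
    )


# ---------------------------------------------------------------------------
# counterfactual series

def _season_mask(dates: pd.Series) -> np.ndarray:
    """Warm-season months plus the 10-day pre-season buffer (May 22-31)."""
    month = dates.dt.month.to_numpy()
    day = dates.dt.day.to_numpy()
    in_season = np.isin(month, WARM_SEASON_MONTHS)
    in_buffer = (month == BUFFER_START[0]) & (day >= BUFFER_START[1])
    return in_season | in_buffer


def build_counterfactual(
    daily: pd.DataFrame,
    slope: float,
    smoothed_gmst: pd.DataFrame,
    gmst_col: str = "smoothed",
    variant: str = "cf_central_central",
    season_only: bool = True,
) -> pd.DataFrame:
    """Subtract ``slope * G(year, month)`` from a daily temperature series.

    With ``season_only`` (default) the subtraction is applied to warm-season
    days plus the 10-day pre-season buffer; other days pass through unchanged.
    Every adjusted day's (year, month) must be present in the GMST table.
    """
    df = daily.copy()
    df["date"] = ensure_datetime(df["date"])
    mask = _season_mask(df["date"]) if season_only else np.ones(len(df), bool)
    # flat (year, month) -> anomaly lookup table
    gy = smoothed_gmst["year"].to_numpy()
    gmo = smoothed_gmst["month"].to_numpy()
    gidx = gy * 12 + (gmo - 1)
    table = np.full(gidx.max() - gidx.min() + 1, np.nan)
    table[gidx - gidx.min()] = smoothed_gmst[gmst_col].to_numpy()
    didx = (
        df["date"].dt.year.to_numpy() * 12 + (df["date"].dt.month.to_numpy() - 1)
    ) - gidx.min()
    if didx[mask].min() < 0 or didx[mask].max() >= table.size:
        raise ValueError("months missing from GMST series")
    g = np.zeros(len(df))
    g[mask] = table[didx[mask]]
    if np.isnan(g).any():
        raise ValueError("months missing from GMST series")
    df["tmean"] = df["tmean"].to_numpy() - slope * g
    df["variant"] = variant
    return df


def build_ensemble(
    daily: pd.DataFrame,
    scaling: ScalingFit,
    smoothed_gmst: pd.DataFrame,
    season_only: bool = True,
) -> dict[str, pd.DataFrame]:
    """The 9 counterfactual variants: GMST bound x scaling-slope bound.

    Keys are ``cf_<gmstbound>_<slopebound>``; ``cf_central_central`` is the
    best-estimate counterfactual used in the main analysis.
    """
    out = {}
    for g in BOUNDS:
        col = "smoothed" if g == "central" else f"smoothed_{g}"
        for b in BOUNDS:
            name = f"cf_{g}_{b}"
            out[name] = build_counterfactual(
                daily,
                scaling.slope_bound(b),
                smoothed_gmst,
                gmst_col=col,
                variant=name,
                season_only=season_only,
            )
    return out


def attributable_temperature(
    factual: pd.DataFrame,
    counterfactuals: dict[str, pd.DataFrame],
    period: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Warm-season warming attributable to climate change, per year.

    Delta T(year) = warm-season mean(factual) - warm-season mean(cf) for each
    ensemble member; returns the central estimate plus the (min, max) range
    across variants, and a ``period`` row with the across-years mean.
    """
    fmean = annual_warm_season_mean(factual)
    deltas = {}
    for name, cf in counterfactuals.items():
        cmean = annual_warm_season_mean(cf)
        if not fmean.index.equals(cmean.index):
            raise ValueError("factual and counterfactual years are misaligned")
        deltas[name] = fmean - cmean
    d = pd.DataFrame(deltas)
    if period is not None:
        d = d[(d.index >= period[0]) & (d.index <= period[1])]
    out = pd.DataFrame(
        {
            "delta_t": d.get("cf_central_central", d.mean(axis=1)),
            "delta_t_min": d.min(axis=1),
            "delta_t_max": d.max(axis=1),
        }
    )
    out.loc["period_mean"] = out.mean(axis=0)
    return out
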