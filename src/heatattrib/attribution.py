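"""Heat-attributable mortality accounting.

For a given association (a cumulative exposure-response coefficient vector
theta on the city's spline basis) and a daily temperature series, the
minimum mortality temperature (MMT) is the grid minimum of the cumulative
log-RR over the 25th-99th percentiles of the city's daily means.  Daily
attributable deaths use the forward perspective: a day t hotter than the MMT
contributes

    AN(t) = (1 - exp(-Delta(t))) * mean(D_t, ..., D_{t+L})

where Delta(t) is the cumulative log-RR at x_t versus the MMT and the
forward moving average of observed deaths runs over the lag window
(truncated at the season end).  Summation over days and cities gives
seasonal AN; division by total warm-season deaths gives AF (%).

Climate-change-attributable quantities are differences between factual and
counterfactual temperature runs (AN_CC, AF_CC) and the relative proportion
P_CC = 100 * AF_CC / AF_factual.  Uncertainty comes from Monte Carlo
resampling of the association coefficients (normal, 1000 draws), with eCIs
taken as the 2.5th/97.5th percentiles of each quantity across draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dlnm import ExposureBasisSpec
from .gmst import ensure_datetime

__all__ = [
    "MMT",
    "find_mmt",
    "attributable_deaths",
    "aggregate",
    "climate_attribution",
    "monte_carlo_eci",
    "baseline_mortality_variant",
    "scenario_attribution",
]


@dataclass(frozen=True)
class MMT:
    city: str
    subperiod: str
    variant: str
    temperature: float
    percentile: float


def find_mmt(
    theta: np.ndarray,
    exposure: ExposureBasisSpec,
    temperatures: np.ndarray,
    city: str = "",
    subperiod: str = "",
    variant: str = "factual",
    lo_pct: float = 25.0,
    hi_pct: float = 99.0,
    step: float = 0.1,
) -> MMT:
    """Grid-search the minimum of the cumulative log-RR curve.

    The grid is the ``lo_pct``..``hi_pct`` percentiles of the supplied daily
    means in ``step``-percentile increments; ties break to the lowest
    temperature.
    """
    probs = np.round(np.arange(lo_pct, hi_pct + step / 2, step), 6)
    grid = np.percentile(np.asarray(temperatures, dtype=float), probs)
    logrr = exposure.transform(grid) @ np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(logrr)):
        raise ValueError("non-finite predictions on the MMT search grid")
    i = int(np.argmin(logrr))  # argmin returns the first (lowest-T) minimum
    return MMT(
        city=city, subperiod=subperiod, variant=variant,
        temperature=float(grid[i]), percentile=float(probs[i]),
    )


def _forward_mean(deaths: np.ndarray, L: int) -> np.ndarray:
    """Mean of deaths over t..t+L, truncated at the end of the series."""
    n = deaths.size
    c = np.concatenate([[0.0], np.cumsum(deaths)])
    hi = np.minimum(np.arange(n) + L + 1, n)
    lo = np.arange(n)
    return (c[hi] - c[lo]) / (hi - lo)


def _attributable_core(
    years: np.ndarray,
    x: np.ndarray,
    deaths: np.ndarray,
    theta: np.ndarray,
    exposure: ExposureBasisSpec,
    mmt: float,
    max_lag: int,
) -> pd.DataFrame:
    """Vectorised per-year AN/AF; inputs are warm-season day arrays sorted by
    date within year."""
    if np.isnan(deaths).any():
        bad = int(years[np.isnan(deaths)][0])
        raise ValueError(f"missing death counts in {bad}")
    theta = np.asarray(theta, dtype=float)
    b_mmt = exposure.transform(np.array([mmt]))[0]
    delta = (exposure.transform(x) - b_mmt) @ theta
    hot = x > mmt
    uy = np.unique(years)
    rows = []
    for y in uy:
        m = years == y
        fm = _forward_mean(deaths[m], max_lag)
        an = float(np.sum((1.0 - np.exp(-delta[m][hot[m]])) * fm[hot[m]]))
        tot = float(deaths[m].sum())
        rows.append({
            "year": int(y), "an": an, "deaths": tot,
            "af": 100.0 * an / tot if tot > 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("year")


def attributable_deaths(
    daily: pd.DataFrame,
    theta: np.ndarray,
    exposure: ExposureBasisSpec,
    mmt: float,
    max_lag: int = 10,
) -> pd.DataFrame:
    """Daily and per-year attributable deaths for one city.

    ``daily`` needs columns date, tmean, deaths covering whole warm seasons
    (Jun-Sep); the forward window is truncated at each season's end.  Returns
    per-year AN, total warm-season deaths and AF (%).
    """
    df = daily.copy()
    df["date"] = ensure_datetime(df["date"])
    df = df[df["date"].dt.month.isin((6, 7, 8, 9))].sort_values("date")
    return _attributable_core(
        df["date"].dt.year.to_numpy(),
        df["tmean"].to_numpy(dtype=float),
        df["deaths"].to_numpy(dtype=float),
        theta, exposure, mmt, max_lag,
    )


def aggregate(per_city: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sum city AN and deaths to all-cities AN and AF per year."""
    cities = list(per_city)
    years = per_city[cities[0]].index
    for c in cities[1:]:
        if not per_city[c].index.equals(years):
            raise ValueError(f"year coverage mismatch for city {c!r}")
    an = sum(per_city[c]["an"] for c in cities)
    deaths = sum(per_city[c]["deaths"] for c in cities)
    return pd.DataFrame({"an": an, "deaths": deaths, "af": 100.0 * an / deaths})


def climate_attribution(
    factual: pd.DataFrame, counterfactual: pd.DataFrame
) -> pd.DataFrame:
    """AN_CC / AF_CC / P_CC per year plus a period-total row.

    Period P_CC uses summed AN: 100 * sum(AN_CC) / sum(AN_factual).  Years
    with zero factual AF get a missing P_CC.
    """
    if not factual.index.equals(counterfactual.index):
        raise ValueError("factual and counterfactual years differ")
    an_cc = factual["an"] - counterfactual["an"]
    af_cc = factual["af"] - counterfactual["af"]
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cc = np.where(
            factual["af"].to_numpy() != 0.0,
            100.0 * af_cc.to_numpy() / factual["af"].to_numpy(),
            np.nan,
        )
    out = pd.DataFrame({"an_cc": an_cc, "af_cc": af_cc, "p_cc": p_cc})
    tot_an_f = factual["an"].sum()
    tot_deaths = factual["deaths"].sum()
    period = {
        "an_cc": an_cc.sum(),
        "af_cc": 100.0 * an_cc.sum() / tot_deaths if tot_deaths else np.nan,
        "p_cc": 100.0 * an_cc.sum() / tot_an_f if tot_an_f else np.nan,
    }
    out.loc["period"] = period
    return out


def baseline_mortality_variant(daily: pd.DataFrame) -> pd.DataFrame:
    """Replace observed deaths by their day-of-year mean over all years
    (sensitivity variant for the attribution stage)."""
    df = daily.copy()
    df["date"] = ensure_datetime(df["date"])
    doy = df["date"].dt.strftime("%m-%d")
    means = df.groupby(doy)["deaths"].transform("mean")
    counts = df.groupby(doy)["deaths"].transform("size")
    nyears = df["date"].dt.year.nunique()
    if (counts < nyears).any():
        missing = doy[counts < nyears].unique()
        raise ValueError(f"incomplete day-of-year coverage: {list(missing)[:5]}")
    df["deaths"] = means
    return df


# ---------------------------------------------------------------------------
# Monte Carlo empirical confidence intervals

def monte_carlo_eci(
    theta: np.ndarray,
    cov: np.ndarray,
    quantity,
    n: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
):
    """eCI for ``quantity(theta_draw)`` under theta_draw ~ N(theta, cov).

    ``quantity`` maps a coefficient vector to a scalar or 1-d array; the
    point estimate is evaluated at ``theta`` and the eCI is the empirical
    (alpha/2, 1-alpha/2) interval across ``n`` draws.  Deterministic given
    the seed.
    """
    theta = np.asarray(theta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    eig = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError("covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(theta, cov, size=n, method="svd")
    vals = np.asarray([np.asarray(quantity(t), dtype=float) for t in draws])
    point = np.asarray(quantity(theta), dtype=float)
    lo = np.percentile(vals, 100 * alpha / 2, axis=0)
    hi = np.percentile(vals, 100 * (1 - alpha / 2), axis=0)
    return point, lo, hi


def scenario_attribution(
    blup_theta: dict[tuple[str, str], np.ndarray],
    temps: dict[str, pd.DataFrame],
    deaths: dict[str, pd.DataFrame],
    exposures: dict[str, ExposureBasisSpec],
    scheme,
    max_lag: int = 10,
    variant: str = "factual",
) -> dict[str, pd.DataFrame]:
    """Per-city yearly AN/AF for one (temperature, association) scenario.

    ``blup_theta`` maps (city, subperiod) to a coefficient vector; the MMT is
    recomputed per city x subperiod from the scenario's own temperature
    percentiles with the scenario's coefficients.
    """
    out = {}
    for city, tdf in temps.items():
        tdf = tdf.copy()
        tdf["date"] = ensure_datetime(tdf["date"])
        warm_all = tdf[tdf["date"].dt.month.isin((6, 7, 8, 9))].sort_values("date")
        ddf = deaths[city].copy()
        ddf["date"] = ensure_datetime(ddf["date"])
        merged_all = warm_all.merge(ddf[["date", "deaths"]], on="date", how="left")
        yrs_all = merged_all["date"].dt.year.to_numpy()
        x_all = merged_all["tmean"].to_numpy(dtype=float)
        d_all = merged_all["deaths"].to_numpy(dtype=float)
        rows = []
        for label, s, e in scheme.blocks:
            key = (city, label)
            if key not in blup_theta:
                continue
            theta = blup_theta[key]
            m = (yrs_all >= s) & (yrs_all <= e)
            mmt = find_mmt(
                theta, exposures[city], x_all[m],
                city=city, subperiod=label, variant=variant,
            )
            rows.append(_attributable_core(
                yrs_all[m], x_all[m], d_all[m], theta, exposures[city],
                mmt.temperature, max_lag,
            ))
        out[city] = pd.concat(rows).sort_index()
    return out
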