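"""First-stage distributed-lag non-linear models (DLNM).

For each city and subperiod, daily warm-season death counts are modelled by a
quasi-Poisson regression whose temperature term is a cross-basis: a tensor
combination of a natural cubic spline in temperature (2 inner knots at the
50th and 90th percentiles of the city's pooled daily means, boundary knots at
the pooled min/max, fixed across subperiods) and a basis in lag 0..10 days
(natural cubic spline with an intercept and 2 inner knots log-spaced in lag).
Day-of-week indicators and year-stratified seasonal splines control for
confounding by calendar time.

Each fit is then reduced to the cumulative (over lags) exposure-response:
a 3-vector of coefficients with covariance, the unit of analysis for the
second-stage meta-regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr as scipy_qr

from .basis import natural_cubic_basis

logger = logging.getLogger(__name__)

__all__ = [
    "SubperiodScheme",
    "ExposureBasisSpec",
    "LagBasisSpec",
    "FirstStageFit",
    "ReducedAssociation",
    "build_cross_basis",
    "fit_quasipoisson",
    "reduce_to_cumulative",
    "predict_rr",
    "fit_city_subperiods",
    "city_percentiles",
]


# ---------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class SubperiodScheme:
    """Ordered, contiguous, non-overlapping year blocks covering the study."""

    blocks: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        prev_end = None
        for label, start, end in self.blocks:
            if end < start:
                raise ValueError(f"subperiod {label}: end before start")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError("subperiods must be contiguous and ordered")
            prev_end = end

    @classmethod
    def from_range(cls, start: int, end: int, block_years: int) -> "SubperiodScheme":
        if (end - start + 1) % block_years:
            raise ValueError("block length does not divide the study period")
        blocks = []
        for s in range(start, end + 1, block_years):
            e = s + block_years - 1
            blocks.append((f"{s}-{e}", s, e))
        return cls(tuple(blocks))

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.blocks]

    def label_for_year(self, year: int) -> str | None:
        for label, s, e in self.blocks:
            if s <= year <= e:
                return label
        return None

    def midpoint(self, label: str) -> float:
        for lab, s, e in self.blocks:
            if lab == label:
                return (s + e) / 2.0
        raise KeyError(label)


DEFAULT_SCHEME = SubperiodScheme.from_range(1993, 2022, 5)


@dataclass(frozen=True)
class ExposureBasisSpec:
    """Natural cubic spline in temperature; 2 inner knots -> 3 columns."""

    inner_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    @classmethod
    def from_temperatures(
        cls,
        tmean: np.ndarray,
        percentiles: tuple[float, ...] = (50.0, 90.0),
    ) -> "ExposureBasisSpec":
        t = np.asarray(tmean, dtype=float)
        inner = tuple(float(np.percentile(t, p)) for p in percentiles)
        return cls(inner, (float(t.min()), float(t.max())))

    @property
    def ncol(self) -> int:
        return len(self.inner_knots) + 1

    def transform(self, x: np.ndarray) -> np.ndarray:
        return natural_cubic_basis(x, self.inner_knots, self.boundary_knots)


@dataclass(frozen=True)
class LagBasisSpec:
    """Basis over lags 0..max_lag: intercept + ns with log-spaced inner knots."""

    max_lag: int = 10
    n_inner_knots: int = 2

    @property
    def lag_knots(self) -> tuple[float, ...]:
        # equally spaced on the log(lag + 1) scale, mapped back to lag units
        L = self.max_lag
        pos = np.linspace(0.0, np.log(L + 1.0), self.n_inner_knots + 2)[1:-1]
        return tuple(float(np.exp(p) - 1.0) for p in pos)

    @property
    def ncol(self) -> int:
        if self.max_lag == 0:
            return 1  # intercept only
        return self.n_inner_knots + 2  # intercept + ns columns

    def matrix(self) -> np.ndarray:
        """(max_lag + 1) x ncol basis matrix evaluated at lags 0..max_lag."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        if self.max_lag == 0:
            return np.ones((1, 1))
        ns = natural_cubic_basis(lags, self.lag_knots, (0.0, float(self.max_lag)))
        return np.column_stack([np.ones(len(lags)), ns])


# ---------------------------------------------------------------------------
# cross-basis

def build_cross_basis(
    tmean: np.ndarray,
    out_index: np.ndarray,
    exposure: ExposureBasisSpec,
    lag: LagBasisSpec,
) -> np.ndarray:
    """Cross-basis rows for the days in ``out_index``.

    ``tmean`` is a contiguous daily series (e.g. May 22 - Sep 30 of one
    year); row ``t`` of the output is sum_l C[l, :] (x) B[t - l, :] where
    ``B`` is the exposure basis and ``C`` the lag basis.  Every output day
    must have ``lag.max_lag`` days of history within the series.
    """
    x = np.asarray(tmean, dtype=float)
    out_index = np.asarray(out_index, dtype=int)
    if out_index.size and out_index.min() < lag.max_lag:
        raise ValueError(
            f"day at position {out_index.min()} lacks {lag.max_lag}-day lag history"
        )
    B = exposure.transform(x)  # (n, ke)
    C = lag.matrix()  # (L+1, kl)
    ke, kl = B.shape[1], C.shape[1]
    out = np.zeros((out_index.size, ke * kl))
    for l in range(lag.max_lag + 1):
        Bl = B[out_index - l]  # (nout, ke)
        # column order: exposure-major (j, m) -> j * kl + m
        out += np.einsum("ij,m->ijm", Bl, C[l]).reshape(out_index.size, ke * kl)
    return out


def lag_sum_contrast(exposure: ExposureBasisSpec, lag: LagBasisSpec) -> np.ndarray:
    """Contrast matrix M with theta = M @ eta summing effects over lags."""
    csum = lag.matrix().sum(axis=0)  # (kl,)
    ke, kl = exposure.ncol, lag.ncol
    M = np.zeros((ke, ke * kl))
    for j in range(ke):
        M[j, j * kl : (j + 1) * kl] = csum
    return M


# ---------------------------------------------------------------------------
# quasi-Poisson fit

@dataclass
class FirstStageFit:
    city: str
    subperiod: str
    params: np.ndarray
    cov: np.ndarray
    dispersion: float
    n_days: int
    converged: bool
    crossbasis_cols: slice
    kept_columns: np.ndarray = field(default=None)  # type: ignore[assignment]


def _drop_aliased(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a full-rank column subset (QR with column pivoting)."""
    _, R, piv = scipy_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    keep = np.sort(piv[:rank])
    return keep


def fit_quasipoisson(
    deaths: np.ndarray,
    cross_basis: np.ndarray,
    controls: np.ndarray,
    city: str = "",
    subperiod: str = "",
    max_iter: int = 100,
) -> FirstStageFit:
    """Quasi-Poisson GLM: log-link Poisson IRLS, Pearson-scaled covariance.

    Design = [controls | cross_basis]; aliased columns are dropped with a
    warning.  Dispersion is the Pearson chi-square over residual df and
    multiplies the usual Fisher-information covariance.
    """
    y = np.asarray(deaths)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("deaths must be non-negative integers")
    if not np.any(y > 0):
        raise ValueError("all-zero outcome series")
    y = y.astype(float)
    ncb = cross_basis.shape[1]
    X = np.column_stack([controls, cross_basis])
    keep = _drop_aliased(X)
    if keep.size < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(keep.tolist()))
        logger.warning(
            "%s %s: dropping %d aliased design column(s): %s",
            city, subperiod, len(dropped), dropped,
        )
    Xk = X[:, keep]
    model = sm.GLM(y, Xk, family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=max_iter)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("%s %s: IRLS did not converge", city, subperiod)
    # re-embed into the full column space (aliased columns get 0 / 0 rows)
    p = X.shape[1]
    params = np.zeros(p)
    cov = np.zeros((p, p))
    params[keep] = res.params
    cov[np.ix_(keep, keep)] = np.asarray(res.cov_params())
    return FirstStageFit(
        city=city,
        subperiod=subperiod,
        params=params,
        cov=cov,
        dispersion=float(res.scale),
        n_days=len(y),
        converged=converged,
        crossbasis_cols=slice(p - ncb, p),
        kept_columns=keep,
    )


# ---------------------------------------------------------------------------
# reduction and prediction

@dataclass
class ReducedAssociation:
    """Cumulative exposure-response: theta (3,) with covariance S (3x3)."""

    city: str
    subperiod: str
    theta: np.ndarray
    S: np.ndarray
    center: float

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


def reduce_to_cumulative(
    fit: FirstStageFit,
    exposure: ExposureBasisSpec,
    lag: LagBasisSpec,
    center: float,
) -> ReducedAssociation:
    """Sum the cross-basis effects over lags: theta = M eta, S = M V M'."""
    eta = fit.params[fit.crossbasis_cols]
    V = fit.cov[fit.crossbasis_cols, fit.crossbasis_cols]
    M = lag_sum_contrast(exposure, lag)
    if M.shape[1] != eta.size:
        raise ValueError(
            f"cross-basis dimension mismatch: contrast {M.shape[1]}, eta {eta.size}"
        )
    theta = M @ eta
    S = M @ V @ M.T
    S = 0.5 * (S + S.T)
    return ReducedAssociation(fit.city, fit.subperiod, theta, S, center)


def predict_rr(
    theta: np.ndarray,
    S: np.ndarray,
    exposure: ExposureBasisSpec,
    temperatures: np.ndarray,
    center: float,
) -> pd.DataFrame:
    """Cumulative RR(x) vs the centering temperature, with delta-method CI."""
    lo, hi = exposure.boundary_knots
    if not (lo <= center <= hi):
        raise ValueError(f"center {center} outside boundary knots ({lo}, {hi})")
    x = np.atleast_1d(np.asarray(temperatures, dtype=float))
    D = exposure.transform(x) - exposure.transform(np.array([center]))
    logrr = D @ theta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, S, D), 0.0))
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "temperature": x,
            "rr": np.exp(logrr),
            "rr_lower": np.exp(logrr - z * se),
            "rr_upper": np.exp(logrr + z * se),
        }
    )


# ---------------------------------------------------------------------------
# seasonal / calendar controls and the per-city driver

def seasonal_controls(dates: pd.Series, seasonal_df: int = 3) -> np.ndarray:
    """Intercept + year indicators + year-stratified day-of-season splines
    + day-of-week contrasts.

    The day-of-season spline (natural cubic, ``seasonal_df`` columns with
    equally spaced inner knots) is interacted with year indicators so each
    year gets its own within-season shape; year indicators control the
    between-year level.
    """
    dates = pd.to_datetime(dates)
    years = dates.dt.year.to_numpy()
    uyears = np.unique(years)
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    lo, hi = doy.min(), doy.max()
    inner = np.linspace(lo, hi, seasonal_df + 1)[1:-1]
    Bseason = natural_cubic_basis(doy, inner, (lo, hi))  # (n, seasonal_df)

    cols = [np.ones(len(dates))]
    for y in uyears[1:]:
        cols.append((years == y).astype(float))
    for y in uyears:
        ind = (years == y).astype(float)
        for j in range(Bseason.shape[1]):
            cols.append(ind * Bseason[:, j])
    dow = dates.dt.dayofweek.to_numpy()
    for d in range(1, 7):
        cols.append((dow == d).astype(float))
    return np.column_stack(cols)


def city_percentiles(
    tmean: np.ndarray, probs: np.ndarray | None = None
) -> pd.Series:
    """Empirical percentiles (linear interpolation) of daily means."""
    if probs is None:
        probs = np.round(np.arange(0.0, 100.01, 0.1), 1)
    vals = np.percentile(np.asarray(tmean, dtype=float), probs)
    return pd.Series(vals, index=probs)


def _season_segments(
    df: pd.DataFrame, lag: LagBasisSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-year (tmean array incl. buffer, output positions) pairs.

    Requires temperatures from May 22 (10-day buffer) through Sep 30; the
    modelled days are Jun 1 - Sep 30.
    """
    segs = []
    for year, grp in df.groupby(df["date"].dt.year):
        grp = grp.sort_values("date")
        season = grp[
            (grp["date"] >= pd.Timestamp(year, 5, 22))
            & (grp["date"] <= pd.Timestamp(year, 9, 30))
        ]
        dates = season["date"].to_numpy()
        expected = pd.date_range(f"{year}-05-22", f"{year}-09-30")
        if len(season) != len(expected) or not (dates == expected.to_numpy()).all():
            first_bad = expected.difference(pd.DatetimeIndex(dates))
            raise ValueError(
                f"incomplete daily series in {year}: first missing day "
                f"{first_bad[0].date() if len(first_bad) else 'unknown'}"
            )
        x = season["tmean"].to_numpy(dtype=float)
        out_mask = season["date"] >= pd.Timestamp(year, 6, 1)
        out_index = np.flatnonzero(out_mask.to_numpy())
        if out_index.min() < lag.max_lag:
            raise ValueError(f"buffer shorter than max lag in {year}")
        segs.append((x, out_index))
    return segs


def fit_city_subperiods(
    temps: pd.DataFrame,
    deaths: pd.DataFrame,
    scheme: SubperiodScheme = DEFAULT_SCHEME,
    exposure_percentiles: tuple[float, float] = (50.0, 90.0),
    lag: LagBasisSpec | None = None,
    seasonal_df: int = 3,
    exposure: ExposureBasisSpec | None = None,
    center_percentile: float = 50.0,
    exclude_years: tuple[int, ...] = (),
) -> tuple[list[ReducedAssociation], ExposureBasisSpec]:
    """First stage for one city: a ReducedAssociation per subperiod.

    ``temps`` must include the pre-season buffer days; knots are placed on
    the pooled warm-season distribution across the whole study period unless
    an ``exposure`` spec is supplied (counterfactual runs reuse the factual
    knots so coefficients stay comparable across variants).
    """
    lag = lag or LagBasisSpec()
    temps = temps.copy()
    temps["date"] = pd.to_datetime(temps["date"])
    deaths = deaths.copy()
    deaths["date"] = pd.to_datetime(deaths["date"])
    city = str(temps["city"].iloc[0]) if "city" in temps else ""

    study = temps[
        temps["date"].dt.year.between(scheme.blocks[0][1], scheme.blocks[-1][2])
    ]
    warm = study[study["date"].dt.month.isin((6, 7, 8, 9))]
    if exposure is None:
        exposure = ExposureBasisSpec.from_temperatures(
            warm["tmean"].to_numpy(), exposure_percentiles
        )
    center = float(np.percentile(warm["tmean"].to_numpy(), center_percentile))

    merged = study.merge(deaths[["date", "deaths"]], on="date", how="left")
    reduced = []
    for label, s, e in scheme.blocks:
        sub = merged[merged["date"].dt.year.between(s, e)]
        sub = sub[~sub["date"].dt.year.isin(exclude_years)]
        if sub.empty:
            continue
        segs = _season_segments(sub, lag)
        xb_parts, rows = [], []
        for x, out_index in segs:
            xb_parts.append(build_cross_basis(x, out_index, exposure, lag))
        xb = np.vstack(xb_parts)
        season_days = sub[sub["date"].dt.month.isin((6, 7, 8, 9))].sort_values("date")
        controls = seasonal_controls(season_days["date"], seasonal_df)
        y = season_days["deaths"].to_numpy()
        if np.isnan(y).any():
            raise ValueError(f"{city} {label}: missing death counts")
        fit = fit_quasipoisson(y, xb, controls, city=city, subperiod=label)
        if not fit.converged:
            logger.warning("%s %s excluded: non-convergence", city, label)
            continue
        reduced.append(reduce_to_cumulative(fit, exposure, lag, center))
    return reduced, exposure
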