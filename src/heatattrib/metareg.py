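"""Longitudinal multivariate mixed-effects meta-regression.

The city x subperiod cumulative exposure-response coefficients (3-vectors
with known within-unit covariances S_ik) are pooled in a second stage:

    theta_ik ~ N(B' x_ik + b_i,  S_ik),      b_i ~ N(0, Psi)

with a shared random effect b_i per city across its subperiods (optionally
with random slopes for time, or nested grouping levels).  Estimation is by
maximum likelihood: the between-city covariance Psi is parameterised by its
Cholesky factor and optimised numerically, with the fixed effects profiled
out by generalised least squares at each step.  ML (not REML) keeps
likelihood-ratio tests of fixed effects valid and AIC/BIC comparable across
fixed-effect specifications.

Meta-predictors are centred and scaled internally; predictions and
counterfactual constructions transparently use the original units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .basis import natural_cubic_basis
from .dlnm import ReducedAssociation, SubperiodScheme

logger = logging.getLogger(__name__)

__all__ = [
    "MetaData",
    "MetaModel",
    "HeterogeneityStats",
    "BLUPSet",
    "build_meta_design",
    "fit_mvmeta",
    "lr_test",
    "select_model",
    "heterogeneity",
    "predict_pooled",
    "compute_blups",
    "counterfactual_blups",
]


# ---------------------------------------------------------------------------
# data container

@dataclass
class MetaData:
    """Stacked second-stage data: estimates, covariances, design, grouping."""

    y: np.ndarray          # (n, d)
    S: np.ndarray          # (n, d, d)
    X: np.ndarray          # (n, q) fixed-effect design (standardised scale)
    columns: list[str]
    groups: np.ndarray     # (n,) city labels
    z: np.ndarray          # (n, r) random-effect design within city
    city: np.ndarray       # alias of groups (kept for nested structures)
    subperiod: np.ndarray  # (n,) labels
    scaler: dict = field(default_factory=dict)  # col -> (mean, sd)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.y.shape[1]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    def design_row(self, values: dict[str, float]) -> np.ndarray:
        """Standardised design row from raw-unit predictor values."""
        row = np.zeros(self.q)
        for j, c in enumerate(self.columns):
            if c == "intercept":
                row[j] = 1.0
            elif c in values:
                v = float(values[c])
                if c in self.scaler:
                    m, s = self.scaler[c]
                    v = (v - m) / s
                row[j] = v
            else:
                raise KeyError(f"missing predictor value for column {c!r}")
        return row


def build_meta_design(
    reduced: list[ReducedAssociation],
    meta_table: pd.DataFrame | None,
    scheme: SubperiodScheme,
    predictors: tuple[str, ...] = (),
    year_spline: bool = True,
    random_time: bool = False,
) -> MetaData:
    """Assemble stacked y, S, X from reduced associations + meta-predictors.

    The base trend term is a natural cubic spline of the subperiod midpoint
    with one inner knot at the study midpoint and boundary knots at the
    first/last midpoints.  Meta-predictors are standardised (mean 0, sd 1
    across rows).
    """
    y = np.stack([r.theta for r in reduced])
    S = np.stack([r.S for r in reduced])
    groups = np.asarray([r.city for r in reduced])
    subs = np.asarray([r.subperiod for r in reduced])
    mids = np.asarray([scheme.midpoint(s) for s in subs])

    cols: list[str] = ["intercept"]
    parts = [np.ones((len(reduced), 1))]
    if year_spline:
        lo, hi = mids.min(), mids.max()
        knot = (lo + hi) / 2.0
        B = natural_cubic_basis(mids, [knot], (lo, hi))
        parts.append(B)
        cols += [f"year_ns{j + 1}" for j in range(B.shape[1])]
    scaler = {}
    if predictors:
        if meta_table is None:
            raise ValueError("meta_table required when predictors are given")
        mt = meta_table.set_index(["city", "subperiod"])
        for p in predictors:
            vals = np.asarray(
                [
                    _predictor_value(mt, c, s, p, scheme.midpoint(s))
                    for c, s in zip(groups, subs)
                ],
                dtype=float,
            )
            if np.isnan(vals).any():
                raise ValueError(f"missing values in meta-predictor {p!r}")
            m, sd = vals.mean(), vals.std(ddof=0)
            sd = sd if sd > 0 else 1.0
            scaler[p] = (float(m), float(sd))
            parts.append(((vals - m) / sd)[:, None])
            cols.append(p)
    X = np.hstack(parts)

    if random_time:
        tm = (mids - mids.mean()) / max(mids.std(ddof=0), 1e-12)
        z = np.column_stack([np.ones(len(reduced)), tm])
    else:
        z = np.ones((len(reduced), 1))
    return MetaData(
        y=y, S=S, X=X, columns=cols, groups=groups, z=z,
        city=groups, subperiod=subs, scaler=scaler,
    )


def _label_midpoint(label: str) -> float:
    start, end = label.split("-")
    return (int(start) + int(end)) / 2.0


def _predictor_value(mt, city, sub, pred, mid: float) -> float:
    """Meta-predictor for a city x subperiod, interpolating at the subperiod
    midpoint when the table was tabulated under a different scheme (the
    predictors are subperiod means of smooth annual indicators)."""
    try:
        return float(mt.loc[(city, sub), pred])
    except KeyError:
        rows = mt.loc[city]
        mids = np.array([_label_midpoint(s) for s in rows.index])
        order = np.argsort(mids)
        return float(np.interp(mid, mids[order], rows[pred].to_numpy()[order]))


# ---------------------------------------------------------------------------
# likelihood machinery

def _chol_from_params(params: np.ndarray, m: int) -> np.ndarray:
    L = np.zeros((m, m))
    tril = np.tril_indices(m)
    L[tril] = params
    diag = np.arange(m)
    L[diag, diag] = np.exp(np.clip(np.diag(L), -30.0, 30.0))
    return L


def _params_from_psi(psi: np.ndarray) -> np.ndarray:
    m = psi.shape[0]
    jitter = 1e-10 * max(np.trace(psi) / m, 1e-10)
    L = np.linalg.cholesky(psi + jitter * np.eye(m))
    p = L[np.tril_indices(m)]
    diag_pos = np.cumsum(np.arange(1, m + 1)) - 1
    p[diag_pos] = np.log(np.maximum(L[np.arange(m), np.arange(m)], 1e-12))
    return p


def _unit_blocks(data: MetaData) -> list[np.ndarray]:
    order = {}
    for i, g in enumerate(data.groups):
        order.setdefault(g, []).append(i)
    return [np.asarray(v) for v in order.values()]


class _LikelihoodWork:
    """Precomputed block tensors for fast repeated likelihood evaluation.

    When every city contributes the same number of subperiods the per-city
    operations (cholesky, whitening) run as a single batched call; otherwise
    a plain loop over cities is used.
    """

    def __init__(self, data: MetaData, blocks: list[np.ndarray]):
        self.data = data
        self.blocks = blocks
        d = data.d
        self.balanced = len({len(b) for b in blocks}) == 1
        if self.balanced:
            k = len(blocks[0])
            idxm = np.stack(blocks)                      # (nb, k)
            eye = np.eye(d)
            nb = idxm.shape[0]
            self.Sb = np.zeros((nb, k * d, k * d))
            for a in range(k):
                self.Sb[:, a * d:(a + 1) * d, a * d:(a + 1) * d] = data.S[idxm[:, a]]
            zb = data.z[idxm]                            # (nb, k, r)
            self.Zb = np.einsum("bac,ij->baicj", zb, eye).reshape(
                nb, k * d, zb.shape[2] * d
            )
            xb = data.X[idxm]                            # (nb, k, q)
            self.Xb = np.einsum("bac,ij->baicj", xb, eye).reshape(
                nb, k * d, data.q * d
            )
            self.yb = data.y[idxm].reshape(nb, k * d)
            self.N = nb * k * d

    def nll(self, psi: np.ndarray):
        data, blocks = self.data, self.blocks
        d, q = data.d, data.q
        p = q * d
        if self.balanced:
            V = self.Sb + self.Zb @ psi @ np.swapaxes(self.Zb, 1, 2)
            try:
                C = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
            logdet = 2.0 * np.sum(np.log(np.diagonal(C, axis1=1, axis2=2)))
            Xw = np.linalg.solve(C, self.Xb)             # batched triangular
            yw = np.linalg.solve(C, self.yb[:, :, None])[:, :, 0]
            XtVX = np.einsum("bki,bkj->ij", Xw, Xw)
            XtVy = np.einsum("bki,bk->i", Xw, yw)
            try:
                beta = np.linalg.solve(XtVX, XtVy)
            except np.linalg.LinAlgError:
                return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
            r = yw - Xw @ beta
            quad = float(np.sum(r * r))
            nll = 0.5 * (self.N * np.log(2.0 * np.pi) + logdet + quad)
            return nll, beta, XtVX

        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        cache = []
        logdet = 0.0
        for idx in blocks:
            k = len(idx)
            Z = np.kron(data.z[idx], np.eye(d))          # (kd, m)
            V = np.zeros((k * d, k * d))
            for a, i in enumerate(idx):
                V[a * d : (a + 1) * d, a * d : (a + 1) * d] = data.S[i]
            V += Z @ psi @ Z.T
            try:
                C = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
            logdet += 2.0 * np.sum(np.log(np.diag(C)))
            Xi = np.kron(data.X[idx], np.eye(d))         # (kd, p)
            yi = data.y[idx].reshape(-1)
            Xw = solve_triangular(C, Xi, lower=True)
            yw = solve_triangular(C, yi, lower=True)
            XtVX += Xw.T @ Xw
            XtVy += Xw.T @ yw
            cache.append((Xw, yw))
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
        quad = 0.0
        N = 0
        for Xw, yw in cache:
            r = yw - Xw @ beta
            quad += float(r @ r)
            N += yw.size
        nll = 0.5 * (N * np.log(2.0 * np.pi) + logdet + quad)
        return nll, beta, XtVX


def _profile_negloglik(
    params: np.ndarray, data: MetaData, blocks: list[np.ndarray],
    work: _LikelihoodWork | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative ML log-likelihood with beta profiled out by GLS."""
    m = data.z.shape[1] * data.d
    L = _chol_from_params(params, m)
    work = work or _LikelihoodWork(data, blocks)
    return work.nll(L @ L.T)


def fit_mvmeta(
    reduced_or_data,
    meta_table: pd.DataFrame | None = None,
    scheme: SubperiodScheme | None = None,
    predictors: tuple[str, ...] = (),
    year_spline: bool = True,
    random_time: bool = False,
    psi_fixed: np.ndarray | None = None,
    maxiter: int = 500,
) -> "MetaModel":
    """ML fit of the multivariate mixed-effects meta-regression.

    Accepts either a prepared :class:`MetaData` or a list of
    :class:`ReducedAssociation` plus a meta-predictor table and subperiod
    scheme.  ``psi_fixed`` skips the Psi optimisation (e.g. 0 for the
    fixed-effects / inverse-variance limit).
    """
    if isinstance(reduced_or_data, MetaData):
        data = reduced_or_data
    else:
        if scheme is None:
            raise ValueError("scheme required when passing reduced associations")
        data = build_meta_design(
            reduced_or_data, meta_table, scheme, predictors,
            year_spline=year_spline, random_time=random_time,
        )
    if data.n < 2:
        raise ValueError("need at least 2 units")
    blocks = _unit_blocks(data)
    d = data.d
    m = data.z.shape[1] * d

    if psi_fixed is not None:
        psi = np.asarray(psi_fixed, dtype=float)
        nll, beta, XtVX = _negloglik_at_psi(psi, data, blocks)
        n_psi_par = 0
        converged = True
    else:
        work = _LikelihoodWork(data, blocks)
        s0 = np.mean([np.trace(S) / d for S in data.S])
        starts = [
            _params_from_psi(_moment_psi_start(data, blocks, m, s0)),
            _params_from_psi(0.1 * s0 * np.eye(m)),
        ]
        best = None
        for start in starts:
            res = optimize.minimize(
                lambda p: _profile_negloglik(p, data, blocks, work)[0],
                start,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
            )
            if best is None or res.fun < best.fun:
                best = res
        res = best
        converged = bool(res.success)
        if not converged:
            logger.warning("mvmeta optimizer: %s", res.message)
        Lc = _chol_from_params(res.x, m)
        psi = Lc @ Lc.T
        nll, beta, XtVX = _profile_negloglik(res.x, data, blocks, work)
        n_psi_par = m * (m + 1) // 2
    if not np.isfinite(nll):
        raise RuntimeError("mvmeta likelihood is not finite at the optimum")
    cov_beta = np.linalg.inv(XtVX)
    loglik = -nll
    n_par = data.q * d + n_psi_par
    aic = -2.0 * loglik + 2.0 * n_par
    bic = -2.0 * loglik + np.log(data.n * d) * n_par
    return MetaModel(
        data=data, beta=beta, cov_beta=cov_beta, psi=psi,
        loglik=float(loglik), n_par=n_par, aic=float(aic), bic=float(bic),
        converged=converged,
    )


def _moment_psi_start(data: MetaData, blocks, m: int, s0: float) -> np.ndarray:
    """Method-of-moments starting value for Psi.

    Covariance of per-city mean residuals from the S-weighted GLS fit, minus
    the attenuation from within-unit error, eigen-clipped to be positive
    definite.  For random-slope structures the extra dimensions start at a
    small multiple of the within-unit scale.
    """
    d = data.d
    try:
        _, beta, _ = _negloglik_at_psi(np.zeros((m, m)), data, blocks)
        resid = np.empty_like(data.y)
        for i in range(data.n):
            A = np.kron(data.X[i][None, :], np.eye(d)).reshape(d, -1)
            resid[i] = data.y[i] - A @ beta
        bbar = np.stack([resid[idx].mean(axis=0) for idx in blocks])
        within = np.mean(
            [data.S[idx].mean(axis=0) / len(idx) for idx in blocks], axis=0
        )
        cov_b = np.cov(bbar.T, ddof=1).reshape(d, d) - within
        vals, vecs = np.linalg.eigh(0.5 * (cov_b + cov_b.T))
        cov_b = (vecs * np.maximum(vals, 1e-3 * s0)) @ vecs.T
    except np.linalg.LinAlgError:
        cov_b = 0.1 * s0 * np.eye(d)
    psi0 = 0.01 * s0 * np.eye(m)
    psi0[:d, :d] = cov_b
    return psi0


def _negloglik_at_psi(psi, data, blocks):
    """Likelihood at a fixed Psi (no Cholesky parameterisation)."""
    m = psi.shape[0]
    if np.allclose(psi, 0.0):
        # bypass the log-parameterisation, evaluate directly
        d, q = data.d, data.q
        p = q * d
        XtVX = np.zeros((p, p)); XtVy = np.zeros(p)
        cache = []; logdet = 0.0; N = 0
        for idx in blocks:
            k = len(idx)
            V = np.zeros((k * d, k * d))
            for a, i in enumerate(idx):
                V[a * d:(a + 1) * d, a * d:(a + 1) * d] = data.S[i]
            C = np.linalg.cholesky(V)
            logdet += 2.0 * np.sum(np.log(np.diag(C)))
            Xi = np.kron(data.X[idx], np.eye(d))
            yi = data.y[idx].reshape(-1)
            Xw = solve_triangular(C, Xi, lower=True)
            yw = solve_triangular(C, yi, lower=True)
            XtVX += Xw.T @ Xw; XtVy += Xw.T @ yw
            cache.append((Xw, yw)); N += yw.size
        beta = np.linalg.solve(XtVX, XtVy)
        quad = sum(float((yw - Xw @ beta) @ (yw - Xw @ beta)) for Xw, yw in cache)
        nll = 0.5 * (N * np.log(2 * np.pi) + logdet + quad)
        return nll, beta, XtVX
    return _profile_negloglik(_params_from_psi(psi), data, blocks)


# ---------------------------------------------------------------------------
# model object, tests, selection

@dataclass
class MetaModel:
    data: MetaData
    beta: np.ndarray       # (q*d,) with beta.reshape(q, d) = B
    cov_beta: np.ndarray   # (q*d, q*d)
    psi: np.ndarray        # (m, m)
    loglik: float
    n_par: int
    aic: float
    bic: float
    converged: bool

    @property
    def B(self) -> np.ndarray:
        return self.beta.reshape(self.data.q, self.data.d)

    def fitted_row(self, i: int) -> np.ndarray:
        return self.B.T @ self.data.X[i]

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.B, index=self.data.columns,
            columns=[f"dim{j + 1}" for j in range(self.data.d)],
        )


def lr_test(nested: MetaModel, full: MetaModel, tol: float = 1e-6):
    """Likelihood-ratio test of nested vs full fixed-effect specifications."""
    if nested.data.n != full.data.n or nested.data.d != full.data.d:
        raise ValueError("models fit to different data")
    if not set(nested.data.columns) <= set(full.data.columns):
        raise ValueError("models are not nested")
    df = full.n_par - nested.n_par
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'nested'")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -tol * max(1.0, abs(full.loglik)):
        raise RuntimeError(
            f"nested log-likelihood exceeds full ({nested.loglik:.6f} > "
            f"{full.loglik:.6f}): optimizer failure"
        )
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p


def select_model(
    reduced: list[ReducedAssociation],
    meta_table: pd.DataFrame,
    scheme: SubperiodScheme,
    candidates: tuple[str, ...],
    year_spline: bool = True,
    random_time: bool = False,
) -> tuple[MetaModel, pd.DataFrame]:
    """Stepwise AIC search (forward then backward) over meta-predictors.

    Returns the selected model and a trace with every tested model's
    AIC/BIC and the LR p-value against its parent.  LR p-values are
    reported, not used as gates; selection is by AIC alone.  After the
    predictor search, the base year-spline trend itself is subjected to the
    same AIC comparison: once meta-predictors explain the temporal drift,
    keeping a nearly collinear year term only destabilises the fixed-effect
    split, so the more parsimonious model wins.
    """
    if not candidates:
        raise ValueError("need at least one candidate predictor")

    def fit(preds: tuple[str, ...], ys: bool = year_spline) -> MetaModel:
        return fit_mvmeta(
            reduced, meta_table, scheme, predictors=preds,
            year_spline=ys, random_time=random_time,
        )

    current_preds: tuple[str, ...] = ()
    current = fit(current_preds)
    trace = [{
        "predictors": "(base)", "action": "base",
        "aic": current.aic, "bic": current.bic, "lr_p": np.nan,
    }]
    improved = True
    while improved:
        improved = False
        # forward pass
        best_add, best_model = None, None
        for c in candidates:
            if c in current_preds:
                continue
            cand = fit(current_preds + (c,))
            try:
                _, _, p = lr_test(current, cand)
            except RuntimeError:
                # candidate fit found a worse optimum than its parent; it
                # cannot be an AIC improvement either
                p = np.nan
            trace.append({
                "predictors": ",".join(current_preds + (c,)),
                "action": f"+{c}", "aic": cand.aic, "bic": cand.bic, "lr_p": p,
            })
            if cand.aic < current.aic - 1e-9 and (
                best_model is None or cand.aic < best_model.aic
            ):
                best_add, best_model = c, cand
        if best_add is not None:
            current_preds += (best_add,)
            current = best_model
            improved = True
        # backward pass
        for c in list(current_preds):
            rest = tuple(p for p in current_preds if p != c)
            cand = fit(rest)
            try:
                _, _, p = lr_test(cand, current)
            except RuntimeError:
                p = np.nan
            trace.append({
                "predictors": ",".join(rest) or "(base)",
                "action": f"-{c}", "aic": cand.aic, "bic": cand.bic, "lr_p": p,
            })
            if cand.aic < current.aic - 1e-9:
                current_preds = rest
                current = cand
                improved = True
    if year_spline and current_preds:
        cand = fit(current_preds, ys=False)
        trace.append({
            "predictors": ",".join(current_preds), "action": "-year_spline",
            "aic": cand.aic, "bic": cand.bic, "lr_p": np.nan,
        })
        if cand.aic < current.aic - 1e-9:
            current = cand
    return current, pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# heterogeneity

@dataclass(frozen=True)
class HeterogeneityStats:
    Q: float
    df: int
    p: float
    I2: float


def heterogeneity(model: MetaModel) -> HeterogeneityStats:
    """Cochran's Q from residuals weighted by the within-unit covariances
    alone, and I2 = max(0, (Q - df) / Q) * 100."""
    data = model.data
    d, q = data.d, data.q
    p = q * d
    df = data.n * d - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    # GLS with S-only weights
    XtX = np.zeros((p, p)); Xty = np.zeros(p)
    Sinv = np.linalg.inv(data.S)
    for i in range(data.n):
        Xi = np.kron(data.X[i][None, :], np.eye(d)).reshape(d, p)
        XtX += Xi.T @ Sinv[i] @ Xi
        Xty += Xi.T @ Sinv[i] @ data.y[i]
    beta = np.linalg.solve(XtX, Xty)
    Q = 0.0
    for i in range(data.n):
        Xi = np.kron(data.X[i][None, :], np.eye(d)).reshape(d, p)
        r = data.y[i] - Xi @ beta
        Q += float(r @ Sinv[i] @ r)
    pval = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HeterogeneityStats(Q=float(Q), df=int(df), p=pval, I2=float(I2))


# ---------------------------------------------------------------------------
# predictions and BLUPs

def predict_pooled(model: MetaModel, values: dict[str, float]):
    """Fixed-effect prediction (theta, covariance) at raw-unit predictor
    values; the year term is supplied as ``year_ns1``/``year_ns2`` or via
    ``subperiod_mid`` handled by the caller."""
    x = model.data.design_row(values)
    d = model.data.d
    A = np.kron(x[None, :], np.eye(d)).reshape(d, model.data.q * d)
    theta = A @ model.beta
    cov = A @ model.cov_beta @ A.T
    return theta, 0.5 * (cov + cov.T)


@dataclass
class BLUPSet:
    """Per city x subperiod coefficient vectors with covariances."""

    city: np.ndarray
    subperiod: np.ndarray
    theta: np.ndarray  # (n, d)
    cov: np.ndarray    # (n, d, d)
    variant: str

    def lookup(self, city: str, subperiod: str) -> tuple[np.ndarray, np.ndarray]:
        mask = (self.city == city) & (self.subperiod == subperiod)
        (i,) = np.flatnonzero(mask)
        return self.theta[i], self.cov[i]

    def to_frame(self) -> pd.DataFrame:
        d = self.theta.shape[1]
        out = pd.DataFrame({"city": self.city, "subperiod": self.subperiod})
        for j in range(d):
            out[f"theta_{j + 1}"] = self.theta[:, j]
        iu = np.triu_indices(d)
        for a, b in zip(*iu):
            out[f"S_{a + 1}{b + 1}"] = self.cov[:, a, b]
        out["variant"] = self.variant
        return out


def compute_blups(model: MetaModel) -> BLUPSet:
    """Factual BLUPs: fixed-effect prediction plus the predicted city random
    effect u_i = Psi Z_i' V_i^{-1} (y_i - X_i beta).

    Covariance per unit: X_ik Sigma_beta X_ik' + conditional variance of the
    random effect, Psi - Psi Z_i' V_i^{-1} Z_i Psi, mapped through the unit's
    random design.
    """

    data = model.data
    d = data.d
    blocks = _unit_blocks(data)
    theta = np.zeros_like(data.y)
    cov = np.zeros_like(data.S)
    for idx in blocks:
        k = len(idx)
        Z = np.kron(data.z[idx], np.eye(d))
        V = np.zeros((k * d, k * d))
        for a, i in enumerate(idx):
            V[a * d : (a + 1) * d, a * d : (a + 1) * d] = data.S[i]
        V += Z @ model.psi @ Z.T
        C = np.linalg.cholesky(V)
        Xi = np.kron(data.X[idx], np.eye(d))
        r = data.y[idx].reshape(-1) - Xi @ model.beta
        Vinv_r = solve_triangular(
            C.T, solve_triangular(C, r, lower=True), lower=False
        )
        u = model.psi @ Z.T @ Vinv_r
        W = solve_triangular(C, Z @ model.psi, lower=True)
        cond_var = model.psi - W.T @ W  # Var(b_i | y_i)
        for a, i in enumerate(idx):
            zk = np.kron(data.z[i][None, :], np.eye(d)).reshape(d, -1)
            A = np.kron(data.X[i][None, :], np.eye(d)).reshape(d, -1)
            theta[i] = A @ model.beta + zk @ u
            ci = A @ model.cov_beta @ A.T + zk @ cond_var @ zk.T
            cov[i] = 0.5 * (ci + ci.T)
    return BLUPSet(
        city=data.city.copy(), subperiod=data.subperiod.copy(),
        theta=theta, cov=cov, variant="factual",
    )


def counterfactual_blups(
    model: MetaModel,
    factual: BLUPSet,
    meta_table: pd.DataFrame,
    predictor: str = "le",
) -> BLUPSet:
    """Counterfactual BLUPs with a meta-predictor frozen at each city's
    first-subperiod value: fixed-effect prediction at the frozen design plus
    the residual from the factual BLUP.  Covariances are carried over
    unchanged from the factual set.
    """
    data = model.data
    if predictor not in data.columns:
        raise ValueError(f"{predictor!r} is not in the fitted model")
    j = data.columns.index(predictor)
    mt = meta_table.set_index(["city", "subperiod"])
    first_sub = {}
    order = list(dict.fromkeys(data.subperiod))
    for c in np.unique(data.city):
        first_sub[c] = _predictor_value(
            mt, c, order[0], predictor, _label_midpoint(order[0])
        )
    m_, s_ = data.scaler.get(predictor, (0.0, 1.0))
    d = data.d
    theta = factual.theta.copy()
    for i in range(data.n):
        x = data.X[i].copy()
        xt = x.copy()
        xt[j] = (first_sub[data.city[i]] - m_) / s_
        A = np.kron((xt - x)[None, :], np.eye(d)).reshape(d, -1)
        theta[i] = factual.theta[i] + A @ model.beta
    return BLUPSet(
        city=factual.city.copy(), subperiod=factual.subperiod.copy(),
        theta=theta, cov=factual.cov.copy(), variant="counterfactual-LE-fixed",
    )
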