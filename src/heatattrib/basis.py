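"""Natural cubic spline bases.

The exposure-response, lag and trend components of the models in this package
all use natural cubic splines: cubic B-splines constrained to zero second
derivative at the boundary knots, hence linear beyond them.  The construction
follows the common statistical convention (as in R's ``splines::ns``): a cubic
B-spline basis on the augmented knot sequence is projected onto the null space
of the boundary second-derivative constraints, and the intercept column is
removed, giving ``len(inner_knots) + 1`` columns.  Evaluation outside the
boundary knots extends each basis function linearly using its boundary value
and first derivative, which is exact for a natural spline.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["natural_cubic_basis", "ns_knots_from_df"]


@lru_cache(maxsize=512)
def _ns_machinery(inner: tuple[float, ...], lo: float, hi: float):
    """Spline evaluators and the natural-constraint projector for one knot
    set (cached: the same bases are evaluated many times per analysis)."""
    t = np.r_[[lo] * 4, list(inner), [hi] * 4]
    ncol = len(inner) + 4
    spl = BSpline(t, np.eye(ncol), 3, extrapolate=False)
    d1 = spl.derivative(1)
    const = spl.derivative(2)(np.array([lo, hi]))[:, 1:]  # (2, ncol-1)
    q, _ = np.linalg.qr(const.T, mode="complete")
    proj = q[:, 2:]
    b_lo, b_hi = spl(np.array([lo]))[0], spl(np.array([hi]))[0]
    s_lo, s_hi = d1(np.array([lo]))[0], d1(np.array([hi]))[0]
    return spl, proj, b_lo, b_hi, s_lo, s_hi


def natural_cubic_basis(
    x: np.ndarray,
    inner_knots,
    boundary_knots,
) -> np.ndarray:
    """Design matrix of a natural cubic spline basis without intercept.

    Parameters
    ----------
    x : array-like of evaluation points (finite).
    inner_knots : strictly increasing interior knots.
    boundary_knots : pair ``(lo, hi)`` with ``lo < hi``; the basis is linear
        outside this interval.

    Returns
    -------
    ndarray of shape ``(len(x), len(inner_knots) + 1)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        x = np.ravel(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    inner = tuple(float(v) for v in np.atleast_1d(inner_knots))
    lo, hi = (float(boundary_knots[0]), float(boundary_knots[1]))
    allk = np.r_[lo, inner, hi]
    if np.any(np.diff(allk) <= 0):
        raise ValueError(
            f"knots must be strictly increasing: boundary={boundary_knots}, inner={inner}"
        )
    spl, proj, b_lo, b_hi, s_lo, s_hi = _ns_machinery(inner, lo, hi)

    # evaluate inside the boundary; Taylor-extend linearly outside (exact
    # for a natural spline, whose tails are linear)
    B = spl(np.clip(x, lo, hi))
    left = x < lo
    right = x > hi
    if left.any():
        B[left] = b_lo + (x[left, None] - lo) * s_lo
    if right.any():
        B[right] = b_hi + (x[right, None] - hi) * s_hi

    # drop the intercept column, then impose the natural boundary
    # constraints by projecting onto the constraint null space
    return B[:, 1:] @ proj


def ns_knots_from_df(x: np.ndarray, df: int) -> tuple[np.ndarray, tuple[float, float]]:
    """Place knots for an ns basis with ``df`` degrees of freedom.

    Boundary knots at the data range, ``df - 1`` inner knots at equally
    spaced quantiles, mirroring the usual default placement.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    probs = np.linspace(0, 1, df + 1)[1:-1]
    inner = np.quantile(x, probs) if len(probs) else np.empty(0)
    return np.atleast_1d(inner), (float(np.min(x)), float(np.max(x)))
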