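"""Intrinsic position and steepness of an input-output response.

Responses are normalized intrinsically: with m(r) and M(r) the infimum
and supremum of r over [0, infinity), the normalization concentration
x0.5 is the smallest positive x at which r is halfway between them, and
q(y) = r(y * x0.5).  Steepness s(r) is the global maximum of |dq/dy|
and position p(r) the smallest y attaining it.  Both are dimensionless
and scale invariant: replacing r(x) by r(c x) changes neither.  The
unnormalized counterparts satisfy s = s_u * x0.5 and p = p_u / x0.5.

For a rational response every extremum and crossing is a real root of a
polynomial (the derivative numerators), so the global optimization over
the half-line reduces to root finding — exact up to root-finder
tolerance, with no grid or local-search failure modes.  A dense-grid
plus local-refinement route is provided separately, both as the
independent oracle for the root-isolation path and as the evaluator for
non-rational responses such as Hill functions with non-integer
coefficient.

The Hill function H_h(x) = x^h / (1 + x^h) is the reference family;
``hill_point`` gives its (p, s) in closed form (the Hill line is this
locus as h varies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .response import RationalResponse

ROOT_IMAG_TOL = 1e-8     # relative imaginary tolerance for real roots
VALUE_REL_TOL = 1e-9     # relative tolerance for maximizer ties
DEGENERATE_TOL = 1e-12   # responses flatter than this are rejected


class DegenerateResponseError(ValueError):
    """Response is (numerically) constant: no half-point exists."""


@dataclass(frozen=True)
class SharpnessPoint:
    """Position-steepness summary of one response."""

    p: float
    s: float
    x_half: float
    m_r: float
    M_r: float
    p_u: float
    s_u: float


def _real_roots(coeffs) -> np.ndarray:
    """Real roots of a constant-first coefficient array (companion
    matrix eigenvalues; quadratics in closed form)."""
    c = np.asarray(coeffs, dtype=float)
    nz = np.nonzero(c)[0]
    if nz.size == 0:
        return np.empty(0)
    c = c[: nz[-1] + 1]
    n = c.size - 1
    if n < 1:
        return np.empty(0)
    if n == 1:
        return np.array([-c[0] / c[1]])
    if n == 2:
        a, b, cc = c[2], c[1], c[0]
        disc = b * b - 4.0 * a * cc
        if disc < 0:
            return np.empty(0)
        sq = math.sqrt(disc)
        return np.sort(np.array([(-b - sq), (-b + sq)]) / (2.0 * a))
    comp = np.zeros((n, n))
    comp[1:, :-1] = np.eye(n - 1)
    comp[:, -1] = -c[:-1] / c[-1]
    r = np.linalg.eigvals(comp)
    real = r[np.abs(r.imag) <= ROOT_IMAG_TOL * (1.0 + np.abs(r.real))].real
    return np.sort(real)


def _polyder(c: np.ndarray) -> np.ndarray:
    return c[1:] * np.arange(1, c.size) if c.size > 1 else np.zeros(1)


def _polymul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.convolve(a, b)


def _newton_polish(c: np.ndarray, x: float, iters: int = 3) -> float:
    """A few Newton steps on a polynomial root from the companion
    matrix, which can carry ~1e-9 relative error when the roots span
    many orders of magnitude."""
    d = _polyder(np.asarray(c, dtype=float))
    for _ in range(iters):
        fp = float(_polyval_many(np.array(x), d))
        if fp == 0.0:
            break
        step = float(_polyval_many(np.array(x), np.asarray(c, dtype=float))) / fp
        nxt = x - step
        if nxt <= 0.0 or not np.isfinite(nxt):
            break
        x = nxt
    return x


def _polyval_many(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    acc = np.full(x.shape, c[-1], dtype=float)
    for k in range(c.size - 2, -1, -1):
        acc = acc * x + c[k]
    return acc


def _positive(vals: np.ndarray, floor: float = 0.0) -> np.ndarray:
    return vals[vals > floor]


def extrema_and_halfpoint(r: RationalResponse):
    """(m(r), M(r), x0.5) for a rational response.

    The extrema are taken over the closed half-line: the value at 0
    (alpha_0/beta_0), the limit at infinity (alpha_l/beta_l), and every
    positive real critical point of r.  x0.5 is the smallest strictly
    positive real root of  A(x) - h B(x)  with h = (m + M)/2; when r(0)
    already equals h, the root at 0 is deflated and the next positive
    crossing is returned.
    """
    A = np.asarray(r.alpha)
    B = np.asarray(r.beta)
    if np.any(B < 0) or B[0] <= 0:
        raise ValueError(
            "denominator must be positive on [0, inf): nonnegative "
            "coefficients with a positive constant term"
        )
    N, _ = _derivative_numerator(A, B)
    crit = _positive(_real_roots(N))
    xs = np.concatenate(([0.0], crit))
    vals = np.concatenate(
        (_polyval_many(xs, A) / _polyval_many(xs, B), [A[-1] / B[-1]])
    )
    m_r, M_r = float(vals.min()), float(vals.max())
    if M_r - m_r <= DEGENERATE_TOL * max(1.0, abs(M_r)):
        raise DegenerateResponseError("response is constant to tolerance")
    h = 0.5 * (m_r + M_r)
    p_half = A - h * B
    scale = np.abs(p_half).max()
    if abs(p_half[0]) <= 1e-12 * scale:
        p_half = p_half[1:]          # r(0) = h: deflate the root at x = 0
    roots = _positive(_real_roots(p_half))
    # guard against spurious near-zero roots from imperfect deflation
    roots = roots[roots > 1e-300]
    if roots.size == 0:
        raise DegenerateResponseError("no positive half-crossing found")
    return m_r, M_r, _newton_polish(p_half, float(roots[0]))


def _derivative_numerator(A: np.ndarray, B: np.ndarray):
    """(N, B) with r' = N / B^2 and N = A'B - AB'."""
    N = _polymul(_polyder(A), B)
    M = _polymul(A, _polyder(B))
    if M.size > N.size:
        N = np.concatenate((N, np.zeros(M.size - N.size)))
    N[: M.size] -= M
    return N, B


def _steepest(r: RationalResponse):
    """(s_u, p_u): max of |r'| over [0, inf) and its smallest argmax.

    Candidates are x = 0 and the positive real roots of the numerator of
    r'' (i.e. N' B - 2 N B' where r' = N / B^2); r' vanishes at
    infinity because the numerator degree is below 2l.
    """
    A = np.asarray(r.alpha)
    B = np.asarray(r.beta)
    N, _ = _derivative_numerator(A, B)
    W1 = _polymul(_polyder(N), B)
    W2 = 2.0 * _polymul(N, _polyder(B))
    if W2.size > W1.size:
        W1 = np.concatenate((W1, np.zeros(W2.size - W1.size)))
    W1[: W2.size] -= W2
    wroots = [_newton_polish(W1, float(w)) for w in _positive(_real_roots(W1))]
    cand = np.concatenate(([0.0], wroots)) if wroots else np.zeros(1)
    num = _polyval_many(cand, N)
    den = _polyval_many(cand, B)
    slope = np.abs(num / (den * den))
    s_u = float(slope.max())
    keep = slope >= s_u * (1.0 - VALUE_REL_TOL)
    p_u = float(cand[keep].min())
    return s_u, p_u


def position_steepness(r) -> SharpnessPoint:
    """Position and steepness of a response.

    Rational responses go through exact polynomial root isolation; any
    other callable is dispatched to the grid-plus-refinement route
    (``position_steepness_numeric``).  Because p and s are scale
    invariant, the rational computation first rebalances the input
    scale so the denominator's end coefficients match (c0 below),
    which keeps the root-finding well conditioned no matter how the
    caller scaled x.
    """
    if not isinstance(r, RationalResponse):
        return position_steepness_numeric(r)
    B = np.asarray(r.beta)
    l = r.l
    c0 = 1.0
    if B[-1] > 0 and B[0] > 0:
        c0 = (B[0] / B[-1]) ** (1.0 / l)
    rs = r.scale_input(c0) if c0 != 1.0 else r
    m_r, M_r, x_half_s = extrema_and_halfpoint(rs)
    s_u_s, p_u_s = _steepest(rs)
    p = p_u_s / x_half_s
    s = s_u_s * x_half_s
    x_half = c0 * x_half_s
    return SharpnessPoint(
        p=p, s=s, x_half=x_half,
        m_r=m_r, M_r=M_r, p_u=p * x_half, s_u=s / x_half,
    )


# ---------------------------------------------------------------------------
# Grid + local-refinement route (oracle; non-rational responses)
# ---------------------------------------------------------------------------

def _grid(n: int, y_cap: float) -> np.ndarray:
    """Search grid on [0, y_cap]: the union of a compactified uniform
    grid (y = t/(1-t), t uniform) and a log-spaced grid reaching down
    to 1e-9, so features at very small y are not missed."""
    t_cap = y_cap / (1.0 + y_cap)
    t = np.linspace(0.0, t_cap, n // 2)
    ys = np.concatenate(
        ([0.0], t[1:] / (1.0 - t[1:]), np.logspace(-9.0, math.log10(y_cap), n - n // 2))
    )
    return np.unique(ys)


def position_steepness_numeric(
    f,
    df=None,
    d2f=None,
    n_grid: int = 4001,
    y_cap: float = 1e9,
) -> SharpnessPoint:
    """Grid search with local refinement on the compactified half-line.

    ``f`` is the response; ``df`` its derivative and ``d2f`` optionally
    the second derivative, used to polish the slope maximizer by root
    finding (both are picked up from ``f.df`` / ``f.d2f`` attributes
    when present, and ``df`` falls back to central differences).
    Raises if the slope maximum sits at the far end of the compactified
    grid, which would mean the supremum is not attained in the searched
    range.
    """
    df = df if df is not None else getattr(f, "df", None)
    d2f = d2f if d2f is not None else getattr(f, "d2f", None)
    ys = _grid(n_grid, y_cap)
    try:
        fv = np.asarray(f(ys), dtype=float)
        if fv.shape != ys.shape:
            raise TypeError
    except (TypeError, ValueError):
        fv = np.asarray([f(y) for y in ys], dtype=float)

    def refine_extremum(sign):
        idx = int(np.argmax(sign * fv))
        lo = ys[max(idx - 1, 0)]
        hi = ys[min(idx + 1, len(ys) - 1)]
        if lo == hi:
            return fv[idx]
        res = minimize_scalar(lambda y: -sign * f(y), bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-13})
        return sign * (-res.fun)

    M_r = max(refine_extremum(+1.0), float(fv[-1]))
    m_r = min(refine_extremum(-1.0), float(fv[-1]))
    if M_r - m_r <= DEGENERATE_TOL * max(1.0, abs(M_r)):
        raise DegenerateResponseError("response is constant to tolerance")
    h = 0.5 * (m_r + M_r)

    g = fv - h
    cross = np.nonzero((g[:-1] * g[1:] <= 0) & (ys[1:] > 0))[0]
    x_half = None
    for i in cross:
        lo, hi = ys[i], ys[i + 1]
        if abs(g[i]) < 1e-15 and lo == 0.0:
            continue  # crossing pinned at 0; take the next one
        if g[i] == g[i + 1] == 0.0:
            continue
        x_half = brentq(lambda y: f(y) - h, lo, hi, xtol=1e-15, rtol=8.9e-16)
        if x_half > 0:
            break
    if not x_half:
        raise DegenerateResponseError("no positive half-crossing found")

    if df is None:
        eps = 1e-6
        df = lambda y: (f(y + eps) - f(max(y - eps, 0.0))) / (eps + min(y, eps))
    try:
        slope = np.abs(np.asarray(df(ys), dtype=float))
        if slope.shape != ys.shape:
            raise TypeError
    except (TypeError, ValueError):
        slope = np.abs([df(y) for y in ys])
    idx = int(np.argmax(slope))
    if idx == len(ys) - 1:
        raise ValueError("slope maximum at the compactification boundary")
    if idx == 0:
        p_u, s_u = 0.0, float(slope[0])
    else:
        lo, hi = ys[idx - 1], ys[idx + 1]
        if d2f is not None and d2f(lo) * d2f(hi) < 0:
            p_u = brentq(d2f, lo, hi, xtol=1e-15, rtol=8.9e-16)
        else:
            res = minimize_scalar(lambda y: -abs(df(y)), bounds=(lo, hi),
                                  method="bounded", options={"xatol": 1e-13})
            p_u = float(res.x)
        s_u = float(abs(df(p_u)))
        if slope[0] >= s_u * (1.0 - VALUE_REL_TOL):
            p_u, s_u = 0.0, max(s_u, float(slope[0]))
    return SharpnessPoint(
        p=p_u / x_half, s=s_u * x_half, x_half=float(x_half),
        m_r=float(m_r), M_r=float(M_r), p_u=float(p_u), s_u=float(s_u),
    )


def position_steepness_grid(r: RationalResponse, **kwargs) -> SharpnessPoint:
    """Grid + refinement evaluation of a rational response, using its
    analytic derivative.  Serves as the independent cross-check of the
    root-isolation route in :func:`position_steepness`."""
    A = np.asarray(r.alpha)
    B = np.asarray(r.beta)
    N, _ = _derivative_numerator(A, B)

    def f(x):
        x = np.asarray(x, dtype=float)
        return _polyval_many(x, A) / _polyval_many(x, B)

    def df(x):
        x = np.asarray(x, dtype=float)
        d = _polyval_many(x, B)
        return _polyval_many(x, N) / (d * d)

    return position_steepness_numeric(f, df=df, **kwargs)


# ---------------------------------------------------------------------------
# Hill functions and the Hill line
# ---------------------------------------------------------------------------

class HillFunction:
    """H_h(x) = x^h / (1 + x^h) with analytic derivatives, for any h > 0."""

    def __init__(self, h: float):
        if h <= 0:
            raise ValueError("Hill coefficient must be > 0")
        self.h = float(h)

    def __call__(self, x):
        xh = np.power(x, self.h)
        return xh / (1.0 + xh)

    def df(self, x):
        h = self.h
        xh = np.power(x, h)
        return h * np.power(x, h - 1.0) / (1.0 + xh) ** 2 if x > 0 else (
            1.0 if h == 1 else (math.inf if h < 1 else 0.0)
        )

    def d2f(self, x):
        h = self.h
        xh = np.power(x, h)
        return h * np.power(x, h - 2.0) * ((h - 1.0) - (h + 1.0) * xh) / (1.0 + xh) ** 3


def hill_response(h):
    """H_h as a RationalResponse when h is a positive integer, else a
    HillFunction callable (handled by the numeric sharpness route)."""
    if float(h).is_integer() and h >= 1:
        h = int(h)
        alpha = (0.0,) * h + (1.0,)
        beta = (1.0,) + (0.0,) * (h - 1) + (1.0,)
        return RationalResponse(alpha, beta)
    return HillFunction(h)


def hill_sharpness(h) -> SharpnessPoint:
    """(p, s) of H_h by direct optimization (independent of the closed
    form in ``hill_point``)."""
    r = hill_response(h)
    if isinstance(r, RationalResponse):
        return position_steepness(r)
    return position_steepness_numeric(r, df=r.df, d2f=r.d2f)


def hill_point(h) -> tuple[float, float]:
    """Closed-form (p, s) of the Hill function H_h.

    For h > 1 the slope of H_h is maximal where y^h = (h-1)/(h+1),
    giving p = ((h-1)/(h+1))^(1/h) and s = h p^(h-1)/(1 + (h-1)/(h+1))^2.
    H_1 has its maximal slope 1 at 0; for h < 1 the slope diverges as
    y -> 0+, so p = 0 with infinite steepness.
    """
    if h <= 0:
        raise ValueError("Hill coefficient must be > 0")
    if h == 1:
        return 0.0, 1.0
    if h < 1:
        return 0.0, math.inf
    yh = (h - 1.0) / (h + 1.0)
    p = yh ** (1.0 / h)
    s = h * p ** (h - 1.0) / (1.0 + yh) ** 2
    return float(p), float(s)


def hill_line(h_values) -> list[tuple[float, float, float]]:
    """(h, p, s) triples along the Hill line."""
    return [(float(h),) + hill_point(h) for h in h_values]
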