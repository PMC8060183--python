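"""Numerically stable likelihood kernels for the bounded integer (BI) model.

The BI model maps a discrete score ``s`` in ``0..S`` onto a latent standard
normal scale through cut-points ``q_s = Phi^{-1}(s/(S+1))``.  The probability
of observing ``s`` for a subject with latent mean ``f`` and latent SD
``sigma`` is the normal mass between adjacent cut-points,

    P(Y = s) = Phi((q_{s+1} - f)/sigma) - Phi((q_s - f)/sigma),

with ``q_0 = -inf`` and ``q_{S+1} = +inf`` so the boundary categories behave
correctly.  Two log-likelihood implementations are provided:

``loglik_naive``
    the literal CDF-subtract-log rendering.  It underflows to ``-inf`` (or
    NaN) when both CDF terms round to equal floating-point values, which
    happens more than ~37 latent SDs into a tail.  This failure mode is the
    point of the comparison and is deliberately not masked.

``loglik_improved``
    works in the log domain throughout: symmetry reflection to avoid
    probabilities near 1, the ``log(a-b) = log a + log1p(-exp(log b - log a))``
    identity, and an asymptotic (Mills-ratio type) approximation of
    ``log(1 - Phi(z))`` beyond ``z = 6``.  Finite wherever the result is
    representable in double precision.

An arbitrary-precision oracle (``loglik_oracle``, mpmath) serves as ground
truth in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "LatentGrid",
    "make_grid",
    "log_norm_cdf",
    "tail_bounds",
    "log_diff_exp",
    "loglik_naive",
    "loglik_improved",
    "loglik_oracle",
    "loglik_grad",
    "pmf",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
#: z-score above which the asymptotic tail formula replaces the direct CDF.
TAIL_SWITCH = 6.0
#: beyond this |z|, z**2/2 overflows double precision; log-probability is -inf.
Z_OVERFLOW = 1.3e154


@dataclass(frozen=True)
class LatentGrid:
    """Cut-point grid ``q_0..q_{S+1}`` for a score bounded by ``S``.

    ``cutpoints[s]`` is the lower boundary of category ``s``; the array has
    length ``S + 2`` with ``-inf`` and ``+inf`` sentinels at the ends.
    Interior cut-points are the ``s/(S+1)`` normal quantiles, hence the grid
    is antisymmetric: ``q_s = -q_{S+1-s}``.
    """

    max_score: int
    cutpoints: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.cutpoints.setflags(write=False)

    def lower(self, score):
        """Lower cut-point ``q_s`` of category ``score`` (array-friendly)."""
        return self.cutpoints[np.asarray(score)]

    def upper(self, score):
        """Upper cut-point ``q_{s+1}`` of category ``score``."""
        return self.cutpoints[np.asarray(score) + 1]


def make_grid(max_score: int) -> LatentGrid:
    """Build the latent cut-point grid for scores ``0..max_score``.

    Parameters
    ----------
    max_score : int
        Largest attainable score ``S`` (>= 1).
    """
    if not (isinstance(max_score, (int, np.integer)) and not isinstance(max_score, bool)):
        raise TypeError(f"max_score must be an integer, got {max_score!r}")
    if max_score < 1:
        raise ValueError(f"max_score must be >= 1, got {max_score}")
    S = int(max_score)
    q = np.empty(S + 2)
    q[0], q[-1] = -np.inf, np.inf
    q[1:-1] = special.ndtri(np.arange(1, S + 1) / (S + 1))
    return LatentGrid(max_score=S, cutpoints=q)


def _log_tail(z):
    """Asymptotic ``log(1 - Phi(z))`` for large positive z (upper bound form).

    This is the 4/pi variant of the Abramowitz & Stegun 7.1.13 bracket,
    rearranged for the normal upper tail.  Log-scale error decays like
    ``(1/2 - 1/pi)/x^2`` with ``x = z/sqrt(2)`` (~8.8e-3 at z=6, ~9e-4 at
    z=20).
    """
    z = np.asarray(z, dtype=float)
    x = z / np.sqrt(2.0)
    with np.errstate(over="ignore"):
        xx = x * x
    out = np.where(
        xx < np.inf,
        np.log(np.sqrt(2.0 / np.pi)) - np.log(x + np.sqrt(xx + 4.0 / np.pi)) - xx - 0.5 * np.log(2.0),
        -np.inf,
    )
    return out


def log_norm_cdf(z):
    """``log Phi(z)``, stable over the whole extended real line.

    For ``z >= -6`` the value comes from the complementary error function
    (with ``log1p`` on the upper side); for ``z < -6`` the asymptotic tail
    formula is used.  Total function: ``log Phi(-inf) = -inf``,
    ``log Phi(+inf) = 0``; beyond ``|z| ~ 1.3e154`` (where ``z^2/2``
    overflows) the result is ``-inf``.
    """
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    out = np.empty_like(z)

    lo = z < -TAIL_SWITCH
    mid = ~lo & (z <= 0)
    hi = z > 0

    out[lo] = _log_tail(-z[lo])
    with np.errstate(divide="ignore"):
        out[mid] = np.log(0.5 * special.erfc(-z[mid] / np.sqrt(2.0)))
    out[hi] = np.log1p(-0.5 * special.erfc(z[hi] / np.sqrt(2.0)))
    out[np.isposinf(z)] = 0.0
    out[np.isnan(z)] = np.nan
    return out[0] if scalar else out


def tail_bounds(z):
    """Lower/upper bracket of ``log(1 - Phi(z))`` for ``z > 0``.

    Returns the two sides of the Mills-ratio-type inequality (constants 2 and
    4/pi inside the square root); ``lower < log(1-Phi(z)) <= upper`` with the
    gap shrinking like ``(1 - 2/pi)/z^2``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("tail bounds are derived for the upper tail: z must be > 0")
    x = z / np.sqrt(2.0)
    const = np.log(np.sqrt(2.0 / np.pi)) - 0.5 * np.log(2.0)
    lower = const - np.log(x + np.sqrt(x * x + 2.0)) - x * x
    upper = const - np.log(x + np.sqrt(x * x + 4.0 / np.pi)) - x * x
    return lower, upper


def log_diff_exp(log_a, log_b):
    """``log(a - b)`` from ``log a >= log b`` without leaving the log domain.

    Uses ``log a + log1p(-exp(log b - log a))``; the exponential argument is
    never positive.  ``log_b = -inf`` returns ``log_a``; an exact tie returns
    ``-inf`` (a log-domain zero).
    """
    log_a = np.asarray(log_a, dtype=float)
    log_b = np.asarray(log_b, dtype=float)
    if np.any(log_a < log_b):
        raise ValueError("log_diff_exp requires log_a >= log_b elementwise")
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = log_b - log_a
        # -inf - -inf gives NaN; both operands -inf means 0 - 0 -> log 0
        diff = np.where(np.isneginf(log_a) & np.isneginf(log_b), -np.inf, diff)
        out = log_a + np.log1p(-np.exp(diff))
        out = np.where(np.isneginf(log_b), log_a, out)
        out = np.where(diff == 0.0, -np.inf, out)
    return out[()] if out.ndim == 0 else out


def _zscores(score, grid: LatentGrid, eta, sigma):
    score = np.asarray(score)
    if np.any(score < 0) or np.any(score > grid.max_score):
        raise ValueError(f"score must lie in 0..{grid.max_score}")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")
    z_lo = (grid.lower(score) - eta) / sigma
    z_hi = (grid.upper(score) - eta) / sigma
    return z_lo, z_hi


def loglik_naive(score, grid: LatentGrid, eta, sigma):
    """Literal ``log(Phi(z_hi) - Phi(z_lo))``: CDF first, subtract, then log.

    Deliberately unhardened — returns ``-inf`` (or NaN) whenever the two CDF
    values round to the same double, which is the failure mode this kernel
    exists to exhibit.
    """
    z_lo, z_hi = _zscores(score, grid, eta, sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = special.ndtr(z_hi) - special.ndtr(z_lo)
        return np.log(p)


def loglik_improved(score, grid: LatentGrid, eta, sigma):
    """Numerically stable BI log-likelihood of one observed score.

    Boundary categories reduce to a single log-CDF; interior categories with
    both z-scores positive are reflected (``Phi(b)-Phi(a) = Phi(-a)-Phi(-b)``)
    so the dominant term is always a lower-tail probability, then combined
    with :func:`log_diff_exp`.
    """
    z_lo, z_hi = _zscores(score, grid, eta, sigma)
    score = np.asarray(score)
    scalar = score.ndim == 0 and np.ndim(eta) == 0 and np.ndim(sigma) == 0
    z_lo, z_hi, score = np.atleast_1d(z_lo, z_hi, np.broadcast_to(score, np.shape(z_lo)))

    reflect = (z_lo > 0) & (z_hi > 0)
    a = np.where(reflect, -z_hi, z_lo)
    b = np.where(reflect, -z_lo, z_hi)
    la = log_norm_cdf(a)
    lb = log_norm_cdf(b)
    # max/min ordering: robust even where the z > 6 tail approximation makes
    # log Phi very slightly non-monotone across the branch switch
    out = log_diff_exp(np.maximum(la, lb), np.minimum(la, lb))
    # boundary categories: one CDF term is exactly 0 or 1
    lo_edge = score == 0
    hi_edge = score == np.asarray(grid.max_score)
    out = np.where(lo_edge, log_norm_cdf(z_hi), out)
    out = np.where(hi_edge, log_norm_cdf(-z_lo), out)
    return out[0] if scalar else out


def loglik_grad(score, grid: LatentGrid, eta, sigma, impl="improved"):
    """Gradient ``(d/d eta, d/d sigma)`` of the BI log-likelihood.

    The improved route evaluates the normal-hazard ratios
    ``phi(z)/P = exp(log phi(z) - loglik)`` in the log domain; the naive
    route mirrors the naive kernel's linear-domain arithmetic (and inherits
    its breakdowns).
    """
    z_lo, z_hi = _zscores(score, grid, eta, sigma)
    if impl == "naive":
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            p = special.ndtr(z_hi) - special.ndtr(z_lo)
            pdf_lo = np.exp(-0.5 * z_lo**2) / np.sqrt(2 * np.pi)
            pdf_hi = np.exp(-0.5 * z_hi**2) / np.sqrt(2 * np.pi)
            pdf_lo = np.where(np.isinf(z_lo), 0.0, pdf_lo)
            pdf_hi = np.where(np.isinf(z_hi), 0.0, pdf_hi)
            d_eta = (pdf_lo - pdf_hi) / (sigma * p)
            zp_lo = np.where(np.isinf(z_lo), 0.0, z_lo * pdf_lo)
            zp_hi = np.where(np.isinf(z_hi), 0.0, z_hi * pdf_hi)
            d_sigma = (zp_lo - zp_hi) / (sigma * p)
        return d_eta, d_sigma
    if impl != "improved":
        raise ValueError(f"impl must be 'naive' or 'improved', got {impl!r}")
    ll = loglik_improved(score, grid, eta, sigma)
    with np.errstate(over="ignore", invalid="ignore"):
        lpdf_lo = -0.5 * z_lo**2 - _LOG_SQRT_2PI
        lpdf_hi = -0.5 * z_hi**2 - _LOG_SQRT_2PI
        r_lo = np.where(np.isinf(z_lo), 0.0, np.exp(lpdf_lo - ll))
        r_hi = np.where(np.isinf(z_hi), 0.0, np.exp(lpdf_hi - ll))
        d_eta = (r_lo - r_hi) / sigma
        d_sigma = (np.where(np.isinf(z_lo), 0.0, z_lo * r_lo)
                   - np.where(np.isinf(z_hi), 0.0, z_hi * r_hi)) / sigma
    return d_eta, d_sigma


def loglik_oracle(score, grid: LatentGrid, eta, sigma, digits: int = 50):
    """Arbitrary-precision evaluation of the naive expression (ground truth).

    CDF, subtraction and logarithm are all carried out at ``digits`` decimal
    digits (mpmath) and rounded to a double only at the end.
    """
    import mpmath as mp

    if digits < 30:
        raise ValueError("digits must be >= 30")
    score = int(score)
    if not 0 <= score <= grid.max_score:
        raise ValueError(f"score must lie in 0..{grid.max_score}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    with mp.workdps(digits):
        q_lo = grid.cutpoints[score]
        q_hi = grid.cutpoints[score + 1]
        eta_, sigma_ = mp.mpf(eta), mp.mpf(sigma)
        lo = mp.ninf if np.isneginf(q_lo) else (mp.mpf(q_lo) - eta_) / sigma_
        hi = mp.inf if np.isposinf(q_hi) else (mp.mpf(q_hi) - eta_) / sigma_
        if lo > 0 and hi > 0:
            # exact symmetry Phi(hi)-Phi(lo) = Phi(-lo)-Phi(-hi): keeps the
            # subtraction in the lower tail, where finite precision does not
            # round the CDF values to 1
            lo, hi = -hi, -lo
        p_hi = mp.mpf(1) if hi == mp.inf else mp.ncdf(hi)
        p_lo = mp.mpf(0) if lo == mp.ninf else mp.ncdf(lo)
        diff = p_hi - p_lo
        if diff <= 0:
            return -np.inf
        return float(mp.log(diff))


def pmf(grid: LatentGrid, eta, sigma):
    """Probability vector over scores ``0..S`` at latent mean/SD (eta, sigma)."""
    scores = np.arange(grid.max_score + 1)
    with np.errstate(under="ignore"):
        return np.exp(loglik_improved(scores, grid, eta, sigma))
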