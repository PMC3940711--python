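"""First-passage quantities for a drifted Wiener process between two absorbing boundaries.

This is the decision core of the diffusion model: a particle starts at
``z`` between an upper boundary at ``a`` (target-color decision) and a lower
boundary at 0 (distractor-color decision), drifts at rate ``v`` with
within-trial noise ``s``, and is absorbed at whichever boundary it reaches
first.  Everything here is exact (series) mathematics for a single trial
with no between-trial parameter variability; the mixture over trial-to-trial
variability lives in :mod:`popddm.rdm`.

Densities are evaluated with the classical pair of series representations —
a trigonometric ("large-time") series and an image-method ("small-time")
series — choosing per evaluation point whichever needs fewer terms for the
requested tolerance.  Defective cumulative probabilities use the term-wise
integral of the large-time series, which converges for every t > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DomainError",
    "WienerParams",
    "absorb_prob_upper",
    "absorb_prob_lower",
    "fpt_density",
    "fpt_cdf",
]


class DomainError(ValueError):
    """A parameter or argument violates a model invariant."""


@dataclass(frozen=True)
class WienerParams:
    """Single-trial diffusion parameters.

    Parameters
    ----------
    v : drift rate (evidence units per second).
    a : boundary separation; upper boundary at ``a``, lower at 0.
    z : starting point, strictly between 0 and ``a``.
    s : within-trial diffusion coefficient (scaling constant).  The default
        1 fixes the natural mathematical scale; study-level code uses the
        Ratcliff convention s = 0.1 (see :mod:`popddm.rdm`).
    """

    v: float
    a: float
    z: float
    s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v", "a", "z", "s"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"WienerParams.{name} must be finite")
        if self.a <= 0:
            raise DomainError("boundary separation a must be > 0")
        if not 0.0 < self.z < self.a:
            raise DomainError("starting point z must satisfy 0 < z < a")
        if self.s <= 0:
            raise DomainError("diffusion coefficient s must be > 0")


# ---------------------------------------------------------------------------
# absorption probabilities
# ---------------------------------------------------------------------------

def _absorb_upper_raw(v, a, z, s):
    """P(hit a before 0), vectorized, numerically stable for any sign of v."""
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    z = np.asarray(z, dtype=float)
    s = np.asarray(s, dtype=float)
    v, a, z, s = np.broadcast_arrays(v, a, z, s)

    # reflect negative drift onto positive drift: P_up(v,z) = 1 - P_up(-v, a-z)
    neg = v < 0
    vp = np.abs(v)
    zp = np.where(neg, a - z, z)
    x = 2.0 * vp * zp / s**2
    y = 2.0 * vp * a / s**2
    tiny = y < 1e-12  # v -> 0 limit: P = z/a
    y_safe = np.where(tiny, 1.0, y)
    x_safe = np.where(tiny, 0.5, x)
    base = np.where(tiny, zp / a, np.expm1(-x_safe) / np.expm1(-y_safe))
    return np.where(neg, 1.0 - base, base)


def absorb_prob_upper(p: WienerParams) -> float:
    """Probability that the process is absorbed at the upper boundary.

    Continuous in ``v`` through 0, where it equals ``z / a``.
    """
    return float(_absorb_upper_raw(p.v, p.a, p.z, p.s))


def absorb_prob_lower(p: WienerParams) -> float:
    """Probability of absorption at the lower boundary (= 1 - upper)."""
    return 1.0 - absorb_prob_upper(p)


# ---------------------------------------------------------------------------
# first-passage densities
# ---------------------------------------------------------------------------

_SERIES_TOL = 1e-10   # tolerance on the unit-scale density
_EXP_CUTOFF = 46.0    # exp(-46) ~ 1e-20: treat mass beyond this as zero


def _nterms_large(u, tol):
    """Terms needed by the trigonometric series at unit-scale time u."""
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.pi * u * tol
        k = np.where(
            arg < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg, 1e-300)), 0.0)
                    / (np.pi**2 * u)),
            0.0,
        )
        k = np.maximum(k, 1.0 / (np.pi * np.sqrt(u)))
    return k


def _nterms_small(u, tol):
    """Terms needed by the image-method series at unit-scale time u."""
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 2.0 * np.sqrt(2.0 * np.pi * u) * tol
        k = np.where(
            arg < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * u * np.log(np.maximum(arg, 1e-300)),
                                     0.0)),
            2.0,
        )
        k = np.maximum(k, np.sqrt(u) + 1.0)
    return k


def _f0_large(u, w, kmax):
    """Large-time unit density: pi * sum k exp(-k^2 pi^2 u / 2) sin(k pi w)."""
    k = np.arange(1, kmax + 1, dtype=float)
    shape = u.shape + (1,)
    uu = u.reshape(shape)
    ww = w.reshape(shape) if w.shape == u.shape else np.broadcast_to(w, u.shape).reshape(shape)
    terms = k * np.exp(-0.5 * k**2 * np.pi**2 * uu) * np.sin(k * np.pi * ww)
    return np.pi * terms.sum(axis=-1)


def _f0_small(u, w, kmax):
    """Small-time unit density: image-method sum over reflections."""
    khalf = int(math.ceil(kmax / 2.0)) + 1
    k = np.arange(-khalf, khalf + 1, dtype=float)
    shape = u.shape + (1,)
    uu = u.reshape(shape)
    ww = w.reshape(shape) if w.shape == u.shape else np.broadcast_to(w, u.shape).reshape(shape)
    x = ww + 2.0 * k
    terms = x * np.exp(-np.minimum(x**2 / (2.0 * uu), 700.0))
    return terms.sum(axis=-1) / np.sqrt(2.0 * np.pi * u**3)


def _fpt_density_lower(t, v, a, z, s, tol=_SERIES_TOL):
    """Defective FPT density at the lower boundary, vectorized over all args."""
    t = np.asarray(t, dtype=float)
    v, a, z, s, t = np.broadcast_arrays(v, a, z, s, t)
    out = np.zeros(t.shape, dtype=float)

    u = t * s**2 / a**2          # unit-scale time
    w = z / a                    # relative start
    vp = v * a / s**2            # unit-scale drift

    pos = u > 0
    # no reachable mass: the start is too many diffusion lengths from 0
    reach = np.zeros_like(u)
    with np.errstate(divide="ignore"):
        reach[pos] = w[pos] ** 2 / (2.0 * u[pos]) - np.abs(vp[pos]) * w[pos]
    live = pos & (reach < _EXP_CUTOFF)
    if not np.any(live):
        return out

    ul, wl, vl = u[live], w[live], vp[live]
    ks = _nterms_small(ul, tol)
    kl = _nterms_large(ul, tol)
    use_small = ks < kl
    f0 = np.empty(ul.shape)
    if np.any(use_small):
        f0[use_small] = _f0_small(ul[use_small], wl[use_small],
                                  int(np.ceil(ks[use_small].max())))
    if np.any(~use_small):
        f0[~use_small] = _f0_large(ul[~use_small], wl[~use_small],
                                   int(np.ceil(kl[~use_small].max())))
    dens = (s[live] ** 2 / a[live] ** 2) * np.exp(
        -vl * wl - 0.5 * vl**2 * ul) * f0
    out[live] = np.maximum(dens, 0.0)
    return out


def fpt_density(t, p: WienerParams, boundary: str = "upper"):
    """Defective first-passage density at the named boundary.

    Integrates over t in (0, inf) to the corresponding absorption
    probability.  ``t`` may be a scalar or array; negative values raise.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("first-passage time t must be >= 0")
    if boundary == "lower":
        out = _fpt_density_lower(t_arr, p.v, p.a, p.z, p.s)
    elif boundary == "upper":
        out = _fpt_density_lower(t_arr, -p.v, p.a, p.a - p.z, p.s)
    else:
        raise DomainError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# first-passage CDFs
# ---------------------------------------------------------------------------

try:  # optional acceleration; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _cdf_unit(ui, wi, vi, tol):   # pragma: no cover - exercised via wrappers
        """Unit-scale lower-boundary defective CDF at time ui, start wi, drift vi."""
        pi2 = np.pi * np.pi
        if ui <= 0.0:
            return 0.0
        if wi * wi / (2.0 * ui) - abs(vi) * wi > 46.0:
            return 0.0
        if abs(vi) < 1e-12:
            p_low = 1.0 - wi
        else:
            vv = abs(vi)
            ww = wi if vi >= 0.0 else 1.0 - wi
            pu = math.expm1(-2.0 * vv * ww) / math.expm1(-2.0 * vv)
            p_low = 1.0 - (pu if vi >= 0.0 else 1.0 - pu)
        kmax = int(math.sqrt(-2.0 * math.log(tol) / (pi2 * ui))) + 2
        kmin = 1.0 / (np.pi * math.sqrt(ui))
        amp = np.pi * math.exp(-vi * wi)
        tail = 0.0
        for k in range(1, kmax + 1):
            lam = 0.5 * (vi * vi + k * k * pi2)
            term = k * math.exp(-lam * ui) / lam
            tail += term * math.sin(k * np.pi * wi)
            if k >= kmin and amp * term < tol * 0.1:
                break
        F = p_low - amp * tail
        return min(max(F, 0.0), 1.0)

    @_njit(cache=False, fastmath=False)
    def _cdf_kernel(u, w, vp, tol):   # pragma: no cover
        n = u.shape[0]
        out = np.zeros(n)
        for i in range(n):
            out[i] = _cdf_unit(u[i], w[i], vp[i], tol)
        return out

    @_njit(cache=False, fastmath=False)
    def _rt_cdf_nodes(ts, ters, wt, vs, wv, zs, wz, a, s, upper, tol):   # pragma: no cover
        """Latency CDF at times ts, marginalized over quadrature nodes.

        ters/wt: non-decision-time nodes and weights; vs/wv: drift nodes;
        zs/wz: starting-point nodes (evidence units).  ``upper`` selects
        the correct-response (upper-boundary) distribution.
        """
        scale = s * s / (a * a)
        out = np.zeros(ts.shape[0])
        for i in range(ts.shape[0]):
            acc = 0.0
            for j in range(ters.shape[0]):
                td = ts[i] - ters[j]
                if td <= 0.0:
                    continue
                u = td * scale
                inner = 0.0
                for e in range(vs.shape[0]):
                    vp = vs[e] * a / (s * s)
                    row = 0.0
                    for q in range(zs.shape[0]):
                        w = zs[q] / a
                        if upper:
                            row += wz[q] * _cdf_unit(u, 1.0 - w, -vp, tol)
                        else:
                            row += wz[q] * _cdf_unit(u, w, vp, tol)
                    inner += wv[e] * row
                acc += wt[j] * inner
            out[i] = acc
        return out

    _HAVE_NUMBA = True
except ImportError:   # pragma: no cover
    _HAVE_NUMBA = False
    _rt_cdf_nodes = None


def _fpt_cdf_lower(t, v, a, z, s, tol=1e-10):
    """Defective CDF at the lower boundary via the integrated large-time series."""
    t = np.asarray(t, dtype=float)
    v, a, z, s, t = np.broadcast_arrays(v, a, z, s, t)

    u = (t * s**2 / a**2).ravel()
    w = (z / a).ravel()
    vp = (v * a / s**2).ravel()

    if _HAVE_NUMBA:
        return _cdf_kernel(np.ascontiguousarray(u), np.ascontiguousarray(w),
                           np.ascontiguousarray(vp), tol).reshape(t.shape)

    out = np.zeros(u.shape, dtype=float)
    pos = u > 0
    reach = np.zeros_like(u)
    with np.errstate(divide="ignore"):
        reach[pos] = w[pos] ** 2 / (2.0 * u[pos]) - np.abs(vp[pos]) * w[pos]
    live = pos & (reach < _EXP_CUTOFF)
    if not np.any(live):
        return out.reshape(t.shape)

    ul, wl, vl = u[live], w[live], vp[live]
    p_lower = 1.0 - _absorb_upper_raw(vl, 1.0, wl, 1.0)

    # tail(u) = pi e^{-vp w} sum_k k sin(k pi w) e^{-lam_k u} / lam_k,
    # lam_k = (vp^2 + k^2 pi^2) / 2;  F(u) = P_lower - tail(u)
    kmax = int(np.ceil(np.sqrt(
        2.0 * max(-math.log(tol), 1.0) / (np.pi**2 * ul.min())))) + 2
    kmax = min(max(kmax, 3), 100_000)
    k = np.arange(1, kmax + 1, dtype=float)
    lam = 0.5 * (vl[:, None] ** 2 + (k * np.pi) ** 2)
    terms = (k * np.sin(k * np.pi * wl[:, None])
             * np.exp(-lam * ul[:, None]) / lam)
    tail = np.pi * np.exp(-vl * wl) * terms.sum(axis=-1)
    out[live] = np.clip(p_lower - tail, 0.0, 1.0)
    return out.reshape(t.shape)


def fpt_cdf(t, p: WienerParams, boundary: str = "upper"):
    """Defective first-passage CDF: P(absorbed at `boundary` and T <= t)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("first-passage time t must be >= 0")
    if boundary == "lower":
        out = _fpt_cdf_lower(t_arr, p.v, p.a, p.z, p.s)
    elif boundary == "upper":
        out = _fpt_cdf_lower(t_arr, -p.v, p.a, p.a - p.z, p.s)
    else:
        raise DomainError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
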