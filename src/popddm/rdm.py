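"""The full Ratcliff diffusion model for one experimental condition.

Extends the single-trial Wiener process (:mod:`popddm.wiener`) with the
three standard sources of trial-to-trial variability:

* Gaussian variability in drift rate with standard deviation ``eta``,
* uniform variability in the starting point over a range ``Sz``,
* uniform variability in non-decision time over a range ``St``.

Predicted response probabilities and latency distributions are obtained by
quadrature over these mixing distributions: Gauss-Hermite for the Gaussian
drift (the full, untruncated normal) and Gauss-Legendre for the two uniform
ranges.  When a variability parameter is exactly zero its quadrature
collapses to a single node, so the degenerate model reduces exactly to the
Wiener layer.

The model is parameterized by the relative bias ``B = z / a`` rather than
the raw starting point: B = 0.5 is unbiased, B > 0.5 favors the
target-color boundary.  The scaling constant defaults to the Ratcliff
convention s = 0.1, the scale on which the study-level parameter values in
:mod:`popddm.presets` are expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .wiener import DomainError, _absorb_upper_raw, _fpt_cdf_lower

__all__ = [
    "RDMConditionParams",
    "response_prob",
    "rt_cdf",
    "bin_probabilities",
    "rt_quantile",
]

#: Ratcliff-convention within-trial diffusion coefficient.
DEFAULT_S = 0.1

#: default quadrature resolution (drift, start point, non-decision time)
N_ETA, N_SZ, N_ST = 20, 10, 10


@dataclass(frozen=True)
class RDMConditionParams:
    """Diffusion parameters for a single inter-trial condition.

    ``v`` mean drift rate, ``a`` boundary separation, ``B`` relative bias
    z/a in (0, 1), ``Ter`` non-decision time (s), ``eta`` SD of Gaussian
    drift variability, ``Sz`` full range of uniform starting-point
    variability (evidence units), ``St`` full range of uniform non-decision
    time variability (s), ``s`` scaling constant.
    """

    v: float
    a: float
    B: float
    Ter: float
    eta: float = 0.0
    Sz: float = 0.0
    St: float = 0.0
    s: float = DEFAULT_S

    def __post_init__(self) -> None:
        for name in ("v", "a", "B", "Ter", "eta", "Sz", "St", "s"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"RDMConditionParams.{name} must be finite")
        if self.a <= 0:
            raise DomainError("boundary separation a must be > 0")
        if not 0.0 < self.B < 1.0:
            raise DomainError("relative bias B must satisfy 0 < B < 1")
        if self.eta < 0:
            raise DomainError("drift variability eta must be >= 0")
        if self.Sz < 0:
            raise DomainError("starting-point range Sz must be >= 0")
        if self.Sz > 2.0 * min(self.B, 1.0 - self.B) * self.a + 1e-12:
            raise DomainError(
                "Sz too large: starting point would leave the boundaries "
                f"(Sz={self.Sz:.4g}, limit={2 * min(self.B, 1 - self.B) * self.a:.4g})")
        if self.St < 0:
            raise DomainError("non-decision-time range St must be >= 0")
        if self.Ter - self.St / 2.0 < 0:
            raise DomainError("Ter - St/2 must be >= 0")
        if self.s <= 0:
            raise DomainError("scaling constant s must be > 0")

    @property
    def z(self) -> float:
        """Mean starting point in evidence units."""
        return self.B * self.a


# ---------------------------------------------------------------------------
# quadrature nodes
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _gauss_hermite(n: int):
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


@lru_cache(maxsize=32)
def _gauss_legendre_unit(n: int):
    """Nodes/weights for averaging over a centered unit-width interval."""
    x, w = np.polynomial.legendre.leggauss(n)
    return x / 2.0, w / 2.0


def _drift_nodes(p: RDMConditionParams, n_eta: int):
    if p.eta == 0.0:
        return np.array([p.v]), np.array([1.0])
    x, w = _gauss_hermite(n_eta)
    return p.v + p.eta * x, w


def _start_nodes(p: RDMConditionParams, n_sz: int):
    if p.Sz == 0.0:
        return np.array([p.z]), np.array([1.0])
    x, w = _gauss_legendre_unit(n_sz)
    return p.z + p.Sz * x, w


def _ter_nodes(p: RDMConditionParams, n_st: int):
    if p.St == 0.0:
        return np.array([p.Ter]), np.array([1.0])
    x, w = _gauss_legendre_unit(n_st)
    return p.Ter + p.St * x, w


# ---------------------------------------------------------------------------
# predicted quantities
# ---------------------------------------------------------------------------

def response_prob(p: RDMConditionParams, n_eta: int = N_ETA,
                  n_sz: int = N_SZ) -> float:
    """Probability of a correct response (upper-boundary absorption).

    Marginalizes the Wiener absorption probability over the drift and
    starting-point mixing distributions; St does not affect which boundary
    is reached.
    """
    v, wv = _drift_nodes(p, n_eta)
    z, wz = _start_nodes(p, n_sz)
    grid = _absorb_upper_raw(v[:, None], p.a, z[None, :], p.s)
    return float(wv @ grid @ wz)


def rt_cdf(t, p: RDMConditionParams, outcome: str = "correct",
           n_eta: int = N_ETA, n_sz: int = N_SZ, n_st: int = N_ST):
    """Defective latency CDF: P(outcome and latency <= t).

    Includes the non-decision time shift and its uniform variability
    (exact for CDFs: the shifted CDFs are averaged over the St range).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DomainError("latency t must be >= 0")
    if outcome not in ("correct", "error"):
        raise DomainError(f"outcome must be 'correct' or 'error', got {outcome!r}")

    v, wv = _drift_nodes(p, n_eta)
    z, wz = _start_nodes(p, n_sz)
    ter, wt = _ter_nodes(p, n_st)

    from .wiener import _HAVE_NUMBA, _rt_cdf_nodes
    if _HAVE_NUMBA:
        out = _rt_cdf_nodes(np.ascontiguousarray(t_arr), ter, wt, v, wv,
                            z, wz, p.a, p.s, outcome == "correct", 1e-10)
    else:
        t_dec = np.maximum(t_arr[:, None] - ter[None, :], 0.0)   # (T, S)
        # broadcast to (T, S, E, Z)
        td = t_dec[:, :, None, None]
        vv = v[None, None, :, None]
        zz = z[None, None, None, :]
        if outcome == "correct":
            grid = _fpt_cdf_lower(td, -vv, p.a, p.a - zz, p.s)
        else:
            grid = _fpt_cdf_lower(td, vv, p.a, zz, p.s)
        out = np.einsum("tsez,s,e,z->t", grid, wt, wv, wz)
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def bin_probabilities(p: RDMConditionParams, correct_edges,
                      n_eta: int = N_ETA, n_sz: int = N_SZ,
                      n_st: int = N_ST) -> np.ndarray:
    """Model probabilities for the six correct-latency bins plus one error bin.

    ``correct_edges`` are the five latency values (seconds) delimiting the
    six correct-response bins (in the fit these are the observed 10/30/50/
    70/90% quantiles).  Returns seven probabilities summing to 1: six
    correct-bin masses followed by the total error mass.
    """
    edges = np.asarray(correct_edges, dtype=float)
    if edges.shape != (5,) or np.any(np.diff(edges) <= 0):
        raise DomainError("correct_edges must be 5 strictly increasing latencies")
    F = rt_cdf(edges, p, "correct", n_eta=n_eta, n_sz=n_sz, n_st=n_st)
    p_correct = response_prob(p, n_eta=n_eta, n_sz=n_sz)
    cum = np.concatenate(([0.0], F, [p_correct]))
    masses = np.maximum(np.diff(cum), 0.0)
    return np.concatenate((masses, [1.0 - p_correct]))


def rt_quantile(p: RDMConditionParams, q: float, outcome: str = "correct",
                n_eta: int = N_ETA, n_sz: int = N_SZ,
                n_st: int = N_ST) -> float:
    """Latency at conditional (within-outcome) cumulative fraction ``q``."""
    from scipy.optimize import brentq

    if not 0.0 < q < 1.0:
        raise DomainError("quantile fraction q must be in (0, 1)")
    if outcome == "correct":
        total = response_prob(p, n_eta=n_eta, n_sz=n_sz)
    else:
        total = 1.0 - response_prob(p, n_eta=n_eta, n_sz=n_sz)
    if total <= 0:
        raise DomainError(f"outcome {outcome!r} has zero probability")

    def g(t):
        return rt_cdf(t, p, outcome, n_eta=n_eta, n_sz=n_sz, n_st=n_st) / total - q

    lo = max(p.Ter - p.St / 2.0, 0.0)
    hi = lo + 10.0 * p.a**2 / p.s**2 + p.St + 0.1
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket latency quantile")
    return float(brentq(g, lo, hi, xtol=1e-8))
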