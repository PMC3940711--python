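"""Quantile-based chi-square fitting of the diffusion model.

The fitting method follows the Ratcliff-Tuerlinckx quantile chi-square
approach, modified for high-accuracy data: per condition, correct-response
latencies are summarized by their 10/30/50/70/90% quantiles, which cut the
correct-response probability mass into six bins with observed proportions
(.1, .2, .2, .2, .2, .1) x accuracy; because error trials are scarce, all
errors form a single seventh bin.  The statistic is

    chi2 = sum_conditions sum_bins N (p_obs - p_exp)^2 / p_exp

where N is the condition's trial count and p_exp the model's bin mass
(:func:`popddm.rdm.bin_probabilities` evaluated at the observed quantile
edges).  With four conditions this gives 28 components; a condition with
zero observed errors contributes no error component (27, 26, ... instead).

Before summarizing, latencies more than five standard deviations from the
subject's mean (computed over all of that subject's target-present trials,
all conditions pooled) are discarded as outliers.

Minimization is derivative-free Nelder-Mead on a transformed unconstrained
parameter space (log for scale parameters, a tanh map for the bias deltas,
and non-decision times parameterized as St/2 plus a positive gap), with
multistart from a jittered method-of-moments initialization.  Remaining
cross-parameter constraints (the starting-point range must keep the start
inside the boundaries) are enforced by a large finite penalty so the
optimizer always sees a finite objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import selection
from .conditions import (Condition, FullModelParams, SubModelSpec, expand,
                         free_fields, free_parameter_count, get_submodel)
from .rdm import DEFAULT_S, N_ETA, N_ST, N_SZ, bin_probabilities
from .wiener import DomainError

__all__ = [
    "QUANTILE_FRACTIONS",
    "BIN_FRACTIONS",
    "ConditionSummary",
    "FitOptions",
    "FitResult",
    "filter_outliers",
    "summarize",
    "condition_summaries",
    "chisq_condition",
    "objective",
    "fit",
]

QUANTILE_FRACTIONS = np.array([0.10, 0.30, 0.50, 0.70, 0.90])
BIN_FRACTIONS = np.array([0.10, 0.20, 0.20, 0.20, 0.20, 0.10])

_P_FLOOR = 1e-5       # floor on expected bin proportions
_PENALTY = 1e8        # base penalty for out-of-domain parameter vectors


@dataclass(frozen=True)
class ConditionSummary:
    """Observed per-condition data entering the chi-square."""

    condition: str
    n_trials: int
    n_correct: int
    n_error: int
    quantiles: np.ndarray    # 10/30/50/70/90% correct-latency quantiles (s)

    def __post_init__(self) -> None:
        if self.n_correct + self.n_error != self.n_trials:
            raise DomainError("n_correct + n_error must equal n_trials")
        q = np.asarray(self.quantiles, dtype=float)
        if q.shape != (5,) or np.any(np.diff(q) < 0):
            raise DomainError("quantiles must be 5 nondecreasing latencies")
        object.__setattr__(self, "quantiles", q)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


@dataclass
class FitOptions:
    """Optimizer and quadrature settings for :func:`fit`."""

    seed: int = 0
    n_restarts: int = 5
    maxiter: int = 3000
    polish_maxiter: int = 40
    fatol: float = 1e-6
    xatol: float = 1e-5
    jitter: float = 0.25
    n_eta: int = N_ETA
    n_sz: int = N_SZ
    n_st: int = N_ST
    s: float = DEFAULT_S


@dataclass
class FitResult:
    """Best fit of one sub-model to one subject's data."""

    submodel: str
    params: FullModelParams
    chi_square: float
    n_components: int
    df: int
    critical_value: float
    log_likelihood: float
    aic: float
    bic: float
    n_trials: int
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def filter_outliers(latencies) -> np.ndarray:
    """Drop latencies more than 5 SD from the mean (single pass).

    Mean and SD (n-1 denominator) are computed from the full input; the
    survivors are returned in their original order.
    """
    x = np.asarray(latencies, dtype=float)
    if x.size < 2:
        return x.copy()
    sd = x.std(ddof=1)
    return x[np.abs(x - x.mean()) <= 5.0 * sd]


def _present_trials(records: pd.DataFrame) -> pd.DataFrame:
    df = records
    df = df[(df["target_present"] == 1) & df["latency_ms"].notna()]
    return df


def condition_summaries(records: pd.DataFrame,
                        min_correct: int = 6) -> dict[str, ConditionSummary]:
    """Per-condition summaries for one subject's trial table.

    Outlier filtering uses the subject's pooled target-present latencies
    (all conditions together), then each of the four searchable conditions
    is summarized separately.
    """
    df = _present_trials(records)
    lat_all = df["latency_ms"].to_numpy(dtype=float) / 1000.0
    keep = np.ones(len(df), dtype=bool)
    if len(df) >= 2:
        sd = lat_all.std(ddof=1)
        keep = np.abs(lat_all - lat_all.mean()) <= 5.0 * sd
    df = df.iloc[keep]

    out: dict[str, ConditionSummary] = {}
    for cond in Condition:
        sub = df[df["condition"] == cond.value]
        n = len(sub)
        correct = sub["correct"].to_numpy(dtype=float)
        lat = sub["latency_ms"].to_numpy(dtype=float) / 1000.0
        n_correct = int(correct.sum())
        if n_correct < min_correct:
            raise DomainError(
                f"condition {cond.value}: only {n_correct} correct trials "
                f"(need >= {min_correct}) — cannot form latency quantiles")
        q = np.quantile(lat[correct == 1], QUANTILE_FRACTIONS, method="linear")
        out[cond.value] = ConditionSummary(cond.value, n, n_correct,
                                           n - n_correct, q)
    return out


def summarize(records: pd.DataFrame, condition: Condition | str,
              min_correct: int = 6) -> ConditionSummary:
    """Summary for a single condition (pooled-subject outlier filter)."""
    return condition_summaries(records, min_correct)[Condition(condition).value]


def observed_proportions(s: ConditionSummary) -> np.ndarray:
    """Observed bin proportions: six correct bins (+ error bin if any errors)."""
    correct = BIN_FRACTIONS * s.accuracy
    if s.n_error == 0:
        return correct
    return np.concatenate((correct, [s.n_error / s.n_trials]))


# ---------------------------------------------------------------------------
# the chi-square objective
# ---------------------------------------------------------------------------

def chisq_condition(s: ConditionSummary, p, n_eta: int = N_ETA,
                    n_sz: int = N_SZ, n_st: int = N_ST) -> np.ndarray:
    """Chi-square components for one condition.

    Six correct-bin components, plus one error component unless the
    condition had no errors at all (100% accuracy), in which case the
    error cell is omitted entirely.
    """
    edges = s.quantiles
    if np.any(np.diff(edges) <= 0):   # tied quantiles: nudge apart
        edges = edges + np.arange(5) * 1e-9
    p_exp = bin_probabilities(p, edges, n_eta=n_eta, n_sz=n_sz, n_st=n_st)
    p_obs = observed_proportions(s)
    if s.n_error == 0:
        p_exp = p_exp[:6]
    p_exp = np.maximum(p_exp, _P_FLOOR)
    return s.n_trials * (p_obs - p_exp) ** 2 / p_exp


# -- free-vector transform ---------------------------------------------------

_LOG_FLOOR = 1e-4   # floor when packing a zero-valued scale parameter


def pack(m: FullModelParams, spec: SubModelSpec) -> np.ndarray:
    """Map a parameter struct to the sub-model's unconstrained free vector."""
    theta = []
    for name in free_fields(spec):
        val = getattr(m, name)
        if name in ("dB_DPE", "dB_POP"):
            theta.append(math.atanh(np.clip(2.0 * val, -0.999, 0.999)))
        elif name in ("a_DPE", "a_POP", "Sz", "St", "eta"):
            theta.append(math.log(max(val, _LOG_FLOOR)))
        elif name in ("T_DPE", "T_POP"):
            theta.append(math.log(max(val - m.St / 2.0, _LOG_FLOOR)))
        else:   # v0, dv_*
            theta.append(val)
    return np.asarray(theta)


def unpack(theta: np.ndarray, spec: SubModelSpec,
           s: float = DEFAULT_S) -> FullModelParams:
    """Inverse of :func:`pack`; shared/zeroed fields are filled in."""
    vals = dict(zip(free_fields(spec), np.asarray(theta, dtype=float)))
    St = math.exp(np.clip(vals["St"], -50, 50)) if "St" in vals else 0.0

    def get(name, default=0.0):
        if name not in vals:
            return default
        raw = vals[name]
        if name in ("dB_DPE", "dB_POP"):
            return 0.5 * math.tanh(raw)
        if name in ("a_DPE", "a_POP", "Sz", "St", "eta"):
            return math.exp(np.clip(raw, -50, 50))
        if name in ("T_DPE", "T_POP"):
            return St / 2.0 + math.exp(np.clip(raw, -50, 50))
        return raw

    kw = {name: get(name) for name in vals}
    kw["St"] = St
    if "a_POP" not in kw:
        kw["a_POP"] = kw["a_DPE"]
    if "T_POP" not in kw:
        kw["T_POP"] = kw["T_DPE"]
    kw.setdefault("dB_DPE", 0.0)
    kw.setdefault("dB_POP", 0.0)
    kw.setdefault("dv_DPE", 0.0)
    kw.setdefault("dv_POP", 0.0)
    return FullModelParams(s=s, **kw)


def objective(summaries: Mapping[str, ConditionSummary] | pd.DataFrame,
              spec: SubModelSpec, theta: np.ndarray,
              options: Optional[FitOptions] = None) -> float:
    """Total chi-square at free vector ``theta`` (finite-penalty on breach)."""
    opt = options or FitOptions()
    if isinstance(summaries, pd.DataFrame):
        summaries = condition_summaries(summaries)
    try:
        m = unpack(theta, spec, s=opt.s)
    except (DomainError, OverflowError) as _:
        return _PENALTY
    total = 0.0
    for cond in Condition:
        try:
            p = expand(m, cond)
        except DomainError:
            # e.g. Sz exceeding the start-to-boundary margin: penalize in
            # proportion to the violation so the simplex can retreat
            limit = 2.0 * min(0.5, 1.0) * min(m.a_DPE, m.a_POP)
            return _PENALTY * (1.0 + max(m.Sz - limit, 0.0))
        total += float(chisq_condition(summaries[cond.value], p,
                                       n_eta=opt.n_eta, n_sz=opt.n_sz,
                                       n_st=opt.n_st).sum())
    if not math.isfinite(total):
        return _PENALTY
    return total


def n_components(summaries: Mapping[str, ConditionSummary]) -> int:
    """28 chi-square cells minus one per condition with zero errors."""
    return sum(6 if s.n_error == 0 else 7 for s in summaries.values())


# ---------------------------------------------------------------------------
# initialization and optimization
# ---------------------------------------------------------------------------

def heuristic_init(summaries: Mapping[str, ConditionSummary],
                   s: float = DEFAULT_S) -> FullModelParams:
    """Method-of-moments style starting point.

    Ter from the fastest observed quantile; the drift-boundary product
    from overall accuracy (logit link, exact for the unbiased Wiener
    process); the boundary separation from the mean decision time.
    """
    q10 = min(su.quantiles[0] for su in summaries.values())
    med = np.mean([su.quantiles[2] for su in summaries.values()])
    acc = (sum(su.n_correct for su in summaries.values())
           / sum(su.n_trials for su in summaries.values()))
    acc = min(max(acc, 0.55), 0.995)
    ter = 0.9 * q10
    mean_dt = max(med - ter, 0.01)
    q = math.log(acc / (1.0 - acc))                 # = v*a/s^2
    a = math.sqrt(2.0 * q * s**2 * mean_dt / math.tanh(q / 2.0))
    v = q * s**2 / a

    def acc_of(c):
        return summaries[c].n_correct / summaries[c].n_trials

    def dlogit(c1, c2):
        x1 = min(max(acc_of(c1), 0.2), 0.995)
        x2 = min(max(acc_of(c2), 0.2), 0.995)
        return math.log(x1 / (1 - x1)) - math.log(x2 / (1 - x2))

    # a bias delta moves the logit of accuracy by roughly 2*dB*a*v/s^2
    dB_pop = np.clip(dlogit("SRe", "SSw") / (4.0 * q), -0.3, 0.3)
    dB_dpe = np.clip(dlogit("DP", "TP") / (4.0 * q), -0.3, 0.3)
    return FullModelParams(
        dB_DPE=float(dB_dpe), dB_POP=float(dB_pop), v0=v,
        dv_DPE=0.0, dv_POP=0.0, a_DPE=a, a_POP=a,
        T_DPE=ter, T_POP=ter, Sz=0.2 * a, St=min(0.05, ter), eta=0.3 * v,
        s=s)


def fit(records: pd.DataFrame | Mapping[str, ConditionSummary],
        spec: SubModelSpec | str = "full",
        options: Optional[FitOptions] = None) -> FitResult:
    """Minimize the quantile chi-square for one subject under one sub-model.

    Nelder-Mead with ``options.n_restarts`` starts: the first from the
    method-of-moments heuristic, the rest jittered around it.  The best
    restart is polished and returned with adequacy (df, critical value)
    and information-criterion bookkeeping.  Deterministic given
    ``options.seed``.
    """
    if isinstance(spec, str):
        spec = get_submodel(spec)
    opt = options or FitOptions()
    summaries = (condition_summaries(records)
                 if isinstance(records, pd.DataFrame) else dict(records))

    theta0 = pack(heuristic_init(summaries, s=opt.s), spec)
    rng = np.random.default_rng(opt.seed)

    best = None
    traces = []
    nfev = 0
    fun = lambda th: objective(summaries, spec, th, opt)  # noqa: E731
    for r in range(opt.n_restarts):
        start = theta0 if r == 0 else theta0 + opt.jitter * rng.standard_normal(theta0.size)
        res = minimize(
            fun, start, method="Nelder-Mead",
            options=dict(maxiter=opt.maxiter, fatol=opt.fatol,
                         xatol=opt.xatol, adaptive=True))
        nfev += res.nfev
        if opt.polish_maxiter > 0:   # directional polish of the simplex optimum
            pol = minimize(fun, res.x, method="Powell",
                           options=dict(maxiter=opt.polish_maxiter,
                                        ftol=opt.fatol))
            nfev += pol.nfev
            if pol.fun < res.fun:
                res = pol
        traces.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= _PENALTY:
        raise RuntimeError("optimization failed: no in-domain optimum found")

    params = unpack(best.x, spec, s=opt.s)
    # the optimizer may run on reduced quadrature for speed; the reported
    # statistic is always evaluated at full default resolution
    full = FitOptions(s=opt.s)
    chi2 = float(objective(summaries, spec, best.x, full))
    M = free_parameter_count(spec)
    n_dropped = sum(1 for s_ in summaries.values() if s_.n_error == 0)
    df_val = selection.dof(J=4, K=7, M=M, n_dropped=n_dropped)
    crit = selection.critical_chisq(0.05, df_val)
    lnL = selection.multinomial_loglik(summaries, params, spec)
    n_obs = sum(s_.n_trials for s_ in summaries.values())
    return FitResult(
        submodel=spec.name, params=params, chi_square=chi2,
        n_components=n_components(summaries), df=df_val,
        critical_value=crit, log_likelihood=lnL,
        aic=-2.0 * lnL + 2.0 * M, bic=-2.0 * lnL + M * math.log(n_obs),
        n_trials=n_obs,
        diagnostics=dict(nfev=nfev, restarts=opt.n_restarts,
                         restart_chi2=traces,
                         converged=bool(best.success),
                         iterations=int(best.nit)))
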