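"""Fit adequacy and information-criterion comparison of the nine sub-models.

A fitted chi-square is judged against the upper 5% point of the
chi-square distribution with J(K-1) - M degrees of freedom, where J is the
number of conditions (4), K the number of chi-square cells per condition
(7: six correct bins plus the error bin) and M the number of free
parameters; each condition whose error cell was dropped (100% accuracy)
removes one further degree of freedom.

For model comparison the likelihood is the multinomial likelihood of the
observed bin counts over the same quantile bins used by the chi-square
objective, and

    AIC = -2 ln L + 2 M          BIC = -2 ln L + M ln n

with n the number of trials entering the fit.  Across-subject comparison
sums the per-subject criteria, which (for independent subjects) is the
criterion of the joint likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import Condition, FullModelParams, SubModelSpec, expand
from .rdm import N_ETA, N_ST, N_SZ, bin_probabilities
from .wiener import DomainError

if TYPE_CHECKING:   # pragma: no cover
    from .fitting import ConditionSummary, FitResult

__all__ = ["DofSpec", "dof", "critical_chisq", "multinomial_loglik", "compare"]


@dataclass(frozen=True)
class DofSpec:
    """Degrees-of-freedom bookkeeping for the quantile chi-square."""

    J: int               # number of conditions
    K: int               # chi-square cells per full condition
    M: int               # free model parameters
    n_dropped: int = 0   # dropped error cells (100%-accuracy conditions)

    def __post_init__(self) -> None:
        if self.J < 1 or self.K < 2 or self.M < 1 or self.n_dropped < 0:
            raise DomainError("require J >= 1, K >= 2, M >= 1, n_dropped >= 0")


def dof(spec: DofSpec | None = None, *, J: int = 4, K: int = 7,
        M: int = 12, n_dropped: int = 0) -> int:
    """Degrees of freedom J(K-1) - M - n_dropped (must be >= 1)."""
    if spec is None:
        spec = DofSpec(J=J, K=K, M=M, n_dropped=n_dropped)
    out = spec.J * (spec.K - 1) - spec.M - spec.n_dropped
    if out < 1:
        raise DomainError(f"degrees of freedom {out} < 1")
    return out


def critical_chisq(alpha: float, df: int) -> float:
    """Upper-tail critical value: the (1 - alpha) chi-square quantile."""
    if not 0.0 < alpha < 1.0:
        raise DomainError("significance level alpha must be in (0, 1)")
    if df < 1:
        raise DomainError("df must be >= 1")
    return float(sps.chi2.ppf(1.0 - alpha, df))


def multinomial_loglik(summaries: "Mapping[str, ConditionSummary] | pd.DataFrame",
                       params: FullModelParams, spec: SubModelSpec,
                       n_eta: int = N_ETA, n_sz: int = N_SZ,
                       n_st: int = N_ST) -> float:
    """Multinomial log-likelihood of the binned data under the model.

    Uses the same binning as the chi-square objective: per condition, six
    correct bins holding (.1, .2, .2, .2, .2, .1) of the correct trials
    plus one error bin.  The multinomial coefficient is omitted, so the
    value is always <= 0.  A zero model probability meeting a nonzero
    count yields -inf.
    """
    from .fitting import BIN_FRACTIONS, condition_summaries

    if isinstance(summaries, pd.DataFrame):
        summaries = condition_summaries(summaries)
    total = 0.0
    for cond in Condition:
        s = summaries[cond.value]
        edges = s.quantiles
        if np.any(np.diff(edges) <= 0):
            edges = edges + np.arange(5) * 1e-9
        p = bin_probabilities(expand(params, cond), edges,
                              n_eta=n_eta, n_sz=n_sz, n_st=n_st)
        counts = np.concatenate((BIN_FRACTIONS * s.n_correct, [s.n_error]))
        nonzero = counts > 0
        if np.any(p[nonzero] <= 0):
            return float("-inf")
        total += float(counts[nonzero] @ np.log(p[nonzero]))
    return total


def compare(fits: "Mapping[str, Mapping[str, FitResult]]"
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-subject AIC/BIC and their across-subject sums.

    ``fits`` maps subject -> sub-model name -> FitResult; every subject
    must carry the same set of sub-models.  Returns the long per-subject
    table and a per-model totals table with ``best_aic`` / ``best_bic``
    flags on the minima.
    """
    subjects = list(fits)
    if not subjects:
        raise DomainError("no fits supplied")
    models = list(fits[subjects[0]])
    gaps = [(s, m) for s in subjects for m in models if m not in fits[s]]
    if gaps:
        raise DomainError(f"missing fits for: {gaps}")

    from .conditions import free_parameter_count, get_submodel

    rows = []
    for s in subjects:
        for m in models:
            r = fits[s][m]
            rows.append(dict(subject=s, submodel=m,
                             M=free_parameter_count(get_submodel(m)),
                             lnL=r.log_likelihood, aic=r.aic, bic=r.bic))
    table = pd.DataFrame(rows)

    totals = (table.groupby("submodel", sort=False)[["aic", "bic"]]
              .sum().reset_index())
    totals["best_aic"] = totals["aic"] == totals["aic"].min()
    totals["best_bic"] = totals["bic"] == totals["bic"].min()
    per_subj_best = (table.loc[table.groupby("subject")["aic"].idxmin(),
                               ["subject", "submodel"]]
                     .rename(columns={"submodel": "best_aic_model"}))
    table = table.merge(per_subj_best, on="subject", how="left")
    return table, totals
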