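"""Group-level statistics on fitted parameters and goodness-of-fit exports.

Thin, explicit wrappers over scipy.stats chosen to match the reporting
conventions of the study design this package emulates: one-tailed
one-sample t-tests for directional parameter predictions (bias and drift
deltas greater than zero), paired two-tailed t-tests for family
differences (boundary separation and non-decision time between the
distractor-preview and pop-out families), a 2x2 chi-square test for
accuracy contrasts, and Welch's t for latency contrasts.  Also exports
quantile-probability-plot (QPP) data: observed versus model-predicted
accuracy and latency quantiles per condition.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import Condition, expand
from .rdm import response_prob, rt_quantile
from .wiener import DomainError

__all__ = [
    "one_tailed_t",
    "paired_two_tailed_t",
    "accuracy_chisq",
    "column_summary",
    "latency_t_test",
    "qpp_export",
]


def _as_vector(values, min_n: int = 2) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise DomainError(f"need a 1-d sample of at least {min_n} values")
    return x


def one_tailed_t(values) -> tuple[float, float]:
    """One-sample t-test of H1: mean > 0; returns (t, upper-tail p)."""
    x = _as_vector(values)
    if np.allclose(x, x[0]):
        raise DomainError("zero variance: one-sample t-test undefined")
    res = sps.ttest_1samp(x, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def paired_two_tailed_t(x, y) -> tuple[float, float]:
    """Paired t-test on x - y, two-tailed; returns (t, p)."""
    x = _as_vector(x)
    y = _as_vector(y)
    if x.size != y.size:
        raise DomainError("paired samples must have equal length")
    d = x - y
    if np.allclose(d, d[0]):
        raise DomainError("zero variance of differences: paired t-test undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def accuracy_chisq(correct1: int, n1: int, correct2: int, n2: int,
                   correction: bool = False) -> float:
    """2x2 chi-square test of equal accuracy; returns the p-value.

    No Yates continuity correction by default (set ``correction=True`` to
    apply it).
    """
    for c, n in ((correct1, n1), (correct2, n2)):
        if not 0 <= c <= n or n <= 0:
            raise DomainError("counts must satisfy 0 <= correct <= n, n > 0")
    table = np.array([[correct1, n1 - correct1], [correct2, n2 - correct2]])
    if np.any(table.sum(axis=0) == 0):
        raise DomainError("a margin of the 2x2 table is empty")
    if correct1 == n1 and correct2 == n2 or correct1 == 0 and correct2 == 0:
        return 1.0   # identical degenerate proportions
    _, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(p)


def column_summary(values) -> tuple[float, float]:
    """(mean, SEM) with the n-1 denominator standard deviation."""
    x = _as_vector(values)
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def latency_t_test(latencies_c1, latencies_c2,
                   equal_var: bool = False) -> float:
    """Two-sample two-tailed t-test on latencies (Welch by default)."""
    x = _as_vector(latencies_c1)
    y = _as_vector(latencies_c2)
    if np.allclose(x, x[0]) and np.allclose(y, y[0]) and x[0] == y[0]:
        return 1.0
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)


def qpp_export(records: pd.DataFrame, fit,
               fractions=(0.1, 0.3, 0.5, 0.7, 0.9)) -> pd.DataFrame:
    """Quantile-probability-plot data: one row per condition.

    Observed accuracy, correct-latency quantiles and error count, next to
    the fitted model's predicted accuracy, quantiles (inverse of the
    conditional correct-latency CDF at the same fractions) and expected
    error count.
    """
    from .fitting import condition_summaries

    summaries = condition_summaries(records)
    rows = []
    for cond in Condition:
        s = summaries[cond.value]
        p = expand(fit.params, cond)
        acc_model = response_prob(p)
        row = {
            "condition": cond.value,
            "n_trials": s.n_trials,
            "obs_accuracy": s.accuracy,
            "model_accuracy": acc_model,
            "obs_errors": s.n_error,
            "model_errors": s.n_trials * (1.0 - acc_model),
        }
        for f, q in zip(fractions, s.quantiles):
            row[f"obs_q{int(f * 100)}"] = q
        for f in fractions:
            row[f"model_q{int(f * 100)}"] = rt_quantile(p, f, "correct")
        rows.append(row)
    return pd.DataFrame(rows)
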