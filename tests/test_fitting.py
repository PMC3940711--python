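"""Outlier filtering, summaries, chi-square objective, and the optimizer."""

import numpy as np
import pytest
from scipy.integrate import quad

from popddm.conditions import get_submodel
from popddm.fitting import (BIN_FRACTIONS, ConditionSummary, FitOptions,
                            chisq_condition, condition_summaries, fit,
                            filter_outliers, n_components, objective,
                            observed_proportions, pack, summarize, unpack)
from popddm.presets import SUBJECT_PRESETS
from popddm.rdm import RDMConditionParams
from popddm.wiener import DomainError, WienerParams, absorb_prob_upper, fpt_density

FAST = FitOptions(seed=0, n_restarts=1, maxiter=400, polish_maxiter=20,
                  n_eta=8, n_sz=4, n_st=4)


class TestFilterOutliers:
    def test_constant_sample_unchanged(self):
        x = np.full(50, 0.3)
        np.testing.assert_array_equal(filter_outliers(x), x)

    def test_five_sd_rule(self):
        rng = np.random.default_rng(0)
        x = 0.3 + 0.01 * (2 * rng.random(199) - 1)
        x = np.append(x, 5.0)
        kept = filter_outliers(x)
        # the 5 s value is > 5 SD out; verify against the direct bound
        bound = 5 * x.std(ddof=1)
        assert 5.0 not in kept
        assert np.all(np.abs(kept - x.mean()) <= bound)
        assert len(kept) == 199

    def test_empty_input(self):
        assert filter_outliers([]).size == 0

    def test_preserves_order(self):
        x = np.array([0.3, 0.25, 0.35, 0.28])
        np.testing.assert_array_equal(filter_outliers(x), x)


class TestSummarize:
    def test_median_recovered(self, small_study):
        s = summarize(small_study, "SRe")
        present = small_study[(small_study["target_present"] == 1)
                              & small_study["latency_ms"].notna()]
        pooled = present["latency_ms"].to_numpy() / 1000.0
        keep = np.abs(pooled - pooled.mean()) <= 5 * pooled.std(ddof=1)
        kept = present.iloc[keep]
        lat = kept[(kept["condition"] == "SRe") & (kept["correct"] == 1)]
        assert s.quantiles[2] == pytest.approx(
            np.median(lat["latency_ms"] / 1000.0), abs=1e-9)

    def test_quantiles_match_linear_interpolation_oracle(self):
        lat = np.array([0.21, 0.23, 0.24, 0.26, 0.27, 0.30, 0.31, 0.35, 0.4, 0.5])
        records = _records_from_latencies(lat)
        s = summarize(records, "SRe")
        for frac, q in zip((0.1, 0.3, 0.5, 0.7, 0.9), s.quantiles):
            pos = frac * (len(lat) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expected = lat[lo] + (pos - lo) * (lat[hi] - lat[lo])
            assert q == pytest.approx(expected, abs=1e-12)

    def test_quantiles_nondecreasing(self, small_study):
        for cond in ("SRe", "SSw", "TP", "DP"):
            s = summarize(small_study, cond)
            assert np.all(np.diff(s.quantiles) >= 0)

    def test_too_few_correct_trials_raises(self):
        records = _records_from_latencies(np.array([0.2, 0.3, 0.4]))
        with pytest.raises(DomainError, match="correct"):
            summarize(records, "SRe")

    def test_counts_are_consistent(self, small_study):
        summaries = condition_summaries(small_study)
        for s in summaries.values():
            assert s.n_correct + s.n_error == s.n_trials


def _records_from_latencies(lat_s, condition="SRe"):
    """Minimal single-condition trial table (all four conditions present)."""
    import pandas as pd
    rows = []
    for c in ("SRe", "SSw", "TP", "DP"):
        use = lat_s if c == condition else 0.25 + 0.01 * np.arange(10)
        for x in use:
            rows.append(dict(subject="S", condition=c, target_present=1,
                             latency_ms=1000 * x, correct=1))
    return pd.DataFrame(rows)


class TestChisqCondition:
    P = RDMConditionParams(v=1.0, a=1.0, B=0.5, Ter=0.2, s=1.0)

    def test_zero_when_observed_equals_expected(self):
        # build a summary whose observed proportions equal the model's bins
        from popddm.rdm import response_prob, rt_quantile
        q = np.array([rt_quantile(self.P, f) for f in (0.1, 0.3, 0.5, 0.7, 0.9)])
        pc = response_prob(self.P)
        n = 100_000
        n_correct = int(round(pc * n))
        s = ConditionSummary("SRe", n, n_correct, n - n_correct, q)
        comps = chisq_condition(s, self.P)
        assert comps.shape == (7,)
        assert np.all(comps < 0.05)   # only the accuracy rounding remains

    def test_hand_computed_components(self):
        """Components equal N (p_obs - p_exp)^2 / p_exp with quadrature p_exp."""
        w = WienerParams(v=1.0, a=1.0, z=0.5, s=1.0)
        q = np.array([0.3, 0.4, 0.5, 0.7, 1.0])
        s = ConditionSummary("SRe", 100, 90, 10, q)
        comps = chisq_condition(s, self.P)
        dec = np.concatenate(([0.0], q - 0.2, [np.inf]))
        p_exp = np.array(
            [quad(lambda t: fpt_density(t, w, "upper"), lo, hi, limit=300)[0]
             for lo, hi in zip(dec[:-1], dec[1:])]
            + [1 - absorb_prob_upper(w)])
        p_obs = np.concatenate((BIN_FRACTIONS * 0.9, [0.1]))
        np.testing.assert_allclose(comps, 100 * (p_obs - p_exp) ** 2 / p_exp,
                                   atol=1e-4)

    def test_error_cell_dropped_at_perfect_accuracy(self):
        q = np.array([0.3, 0.4, 0.5, 0.7, 1.0])
        s = ConditionSummary("DP", 100, 100, 0, q)
        assert chisq_condition(s, self.P).shape == (6,)
        assert observed_proportions(s).shape == (6,)


class TestObjective:
    def test_component_count_is_28_without_dropped_cells(self, small_study):
        summaries = condition_summaries(small_study)
        if all(s.n_error > 0 for s in summaries.values()):
            assert n_components(summaries) == 28
        else:
            dropped = sum(s.n_error == 0 for s in summaries.values())
            assert n_components(summaries) == 28 - dropped

    def test_invariant_to_trial_order(self, small_study):
        spec = get_submodel("full")
        theta = pack(SUBJECT_PRESETS["P1"], spec)
        shuffled = small_study.sample(frac=1.0, random_state=4)
        a = objective(condition_summaries(small_study), spec, theta, FAST)
        b = objective(condition_summaries(shuffled), spec, theta, FAST)
        assert a == pytest.approx(b, abs=1e-10)

    def test_out_of_domain_theta_gets_finite_penalty(self, small_study):
        spec = get_submodel("full")
        theta = pack(SUBJECT_PRESETS["P1"], spec)
        bad = theta.copy()
        bad[[5, 6]] = -20.0    # microscopic boundary separations
        bad[9] = 5.0           # enormous Sz: start point escapes
        val = objective(condition_summaries(small_study), spec, bad, FAST)
        assert np.isfinite(val) and val >= 1e8


class TestFit:
    def test_deterministic_given_seed(self, tiny_study):
        r1 = fit(tiny_study, "nov_all", FAST)
        r2 = fit(tiny_study, "nov_all", FAST)
        assert r1.chi_square == r2.chi_square
        assert r1.params == r2.params

    def test_result_bookkeeping(self, tiny_study):
        r = fit(tiny_study, "full", FAST)
        assert r.submodel == "full"
        assert r.chi_square >= 0
        assert r.df == 4 * 6 - 12 - sum(
            1 for s in condition_summaries(tiny_study).values() if s.n_error == 0)
        assert r.aic == pytest.approx(-2 * r.log_likelihood + 2 * 12)
        assert r.bic == pytest.approx(
            -2 * r.log_likelihood + 12 * np.log(r.n_trials))
        assert r.log_likelihood < 0

    def test_full_model_dominates_nested_submodel(self, small_study):
        """The richer model attains at least as small a chi-square."""
        opts = FitOptions(seed=0, n_restarts=1, maxiter=1500,
                          polish_maxiter=30, n_eta=12, n_sz=6, n_st=6)
        r_sub = fit(small_study, "nov_all", opts)
        r_full = fit(small_study, "full", opts)
        assert r_full.chi_square <= r_sub.chi_square + 1e-3
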