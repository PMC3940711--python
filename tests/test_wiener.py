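"""Single-trial Wiener first-passage layer: closed forms, series, symmetry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from popddm.wiener import (DomainError, WienerParams, absorb_prob_lower,
                           absorb_prob_upper, fpt_cdf, fpt_density)


def euler_absorb_oracle(v, a, z, s, n=150_000, dt=5e-4, seed=5):
    """Independent Euler-Maruyama oracle with Brownian-bridge crossing checks."""
    rng = np.random.default_rng(seed)
    x = np.full(n, float(z))
    alive = np.ones(n, dtype=bool)
    up = np.zeros(n, dtype=bool)
    t_abs = np.zeros(n)
    sq = s * math.sqrt(dt)
    t = 0.0
    while alive.any() and t < 50.0:
        t += dt
        idx = np.flatnonzero(alive)
        x0 = x[idx]
        x1 = x0 + v * dt + sq * rng.standard_normal(idx.size)
        hit_up = x1 >= a
        hit_lo = x1 <= 0
        interior = ~(hit_up | hit_lo)
        pu = np.exp(-2.0 * (a - x0[interior]) * (a - x1[interior]) / (s * s * dt))
        pl = np.exp(-2.0 * x0[interior] * x1[interior] / (s * s * dt))
        u = rng.random(interior.sum())
        hit_up[interior] |= u < pu
        hit_lo[interior] |= (~(u < pu)) & (u < pu + pl)
        done = hit_up | hit_lo
        x[idx] = x1
        up[idx[done]] = hit_up[done]
        t_abs[idx[done]] = t
        alive[idx[done]] = False
    return up, t_abs


class TestAbsorptionProbability:
    @pytest.mark.parametrize("params, expected", [
        (WienerParams(v=0, a=0.08, z=0.04), 0.5),
        (WienerParams(v=0, a=1, z=0.7), 0.7),
        (WienerParams(v=1, a=1, z=0.5), (1 - math.exp(-1)) / (1 - math.exp(-2))),
    ])
    def test_closed_form(self, params, expected):
        assert absorb_prob_upper(params) == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_oracle(self):
        p = WienerParams(v=1, a=1, z=0.5)
        up, _ = euler_absorb_oracle(1, 1, 0.5, 1)
        phat = up.mean()
        se = math.sqrt(phat * (1 - phat) / up.size)
        assert abs(absorb_prob_upper(p) - phat) < 3 * se

    def test_continuity_through_zero_drift(self):
        base = absorb_prob_upper(WienerParams(v=0, a=1, z=0.3))
        near = absorb_prob_upper(WienerParams(v=1e-9, a=1, z=0.3))
        assert near == pytest.approx(base, abs=1e-8)

    @given(v=st.floats(-3, 3), a=st.floats(0.05, 2), rel_z=st.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_upper_and_lower_sum_to_one(self, v, a, rel_z):
        p = WienerParams(v=v, a=a, z=rel_z * a)
        assert absorb_prob_upper(p) + absorb_prob_lower(p) == pytest.approx(1, abs=1e-12)

    def test_monotone_in_drift_and_start(self):
        probs_v = [absorb_prob_upper(WienerParams(v=v, a=1, z=0.4))
                   for v in np.linspace(-2, 2, 15)]
        assert np.all(np.diff(probs_v) > 0)
        probs_z = [absorb_prob_upper(WienerParams(v=0.5, a=1, z=z))
                   for z in np.linspace(0.05, 0.95, 15)]
        assert np.all(np.diff(probs_z) > 0)

    @pytest.mark.parametrize("kwargs", [
        dict(v=0, a=-1, z=0.5), dict(v=0, a=1, z=0.0), dict(v=0, a=1, z=1.0),
        dict(v=0, a=1, z=0.5, s=0.0), dict(v=math.nan, a=1, z=0.5),
    ])
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(DomainError):
            WienerParams(**kwargs)


class TestFirstPassageDensity:
    @pytest.mark.parametrize("params", [
        WienerParams(v=1, a=1, z=0.5),
        WienerParams(v=0.6, a=0.09, z=0.045),
        WienerParams(v=0.6785, a=0.0567, z=0.02835, s=0.1),
        WienerParams(v=-0.5, a=1, z=0.3),
    ])
    @pytest.mark.parametrize("boundary", ["upper", "lower"])
    def test_integrates_to_absorption_probability(self, params, boundary):
        total, _ = quad(lambda t: fpt_density(t, params, boundary), 0, np.inf,
                        limit=400)
        expected = (absorb_prob_upper(params) if boundary == "upper"
                    else absorb_prob_lower(params))
        assert total == pytest.approx(expected, abs=1e-6)

    def test_zero_at_time_zero(self):
        assert fpt_density(0.0, WienerParams(v=1, a=1, z=0.5), "upper") == 0.0

    def test_reflection_symmetry(self):
        grid = np.linspace(0.01, 2.0, 50)
        d_up = fpt_density(grid, WienerParams(v=0.7, a=1, z=0.3), "upper")
        d_lo = fpt_density(grid, WienerParams(v=-0.7, a=1, z=0.7), "lower")
        np.testing.assert_allclose(d_up, d_lo, atol=1e-12)

    def test_nonnegative_on_grid(self):
        grid = np.linspace(0.0, 3.0, 200)
        for b in ("upper", "lower"):
            assert np.all(fpt_density(grid, WienerParams(v=0.3, a=0.8, z=0.3), b) >= 0)

    def test_negative_time_raises(self):
        with pytest.raises(DomainError):
            fpt_density(-0.1, WienerParams(v=1, a=1, z=0.5), "upper")


class TestFirstPassageCdf:
    def test_zero_at_time_zero(self):
        assert fpt_cdf(0.0, WienerParams(v=1, a=1, z=0.5), "upper") == 0.0

    def test_limit_is_absorption_probability(self):
        p = WienerParams(v=0, a=1, z=0.5)
        assert fpt_cdf(50.0, p, "upper") == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("params, t", [
        (WienerParams(v=0.6, a=0.09, z=0.045), 0.3),
        (WienerParams(v=1, a=1, z=0.5), 0.4),
        (WienerParams(v=0.6785, a=0.0567, z=0.02835, s=0.1), 0.05),
    ])
    def test_matches_density_quadrature(self, params, t):
        integral, _ = quad(lambda x: fpt_density(x, params, "upper"), 0, t,
                           limit=400)
        assert fpt_cdf(t, params, "upper") == pytest.approx(integral, abs=1e-6)

    def test_monotone(self):
        grid = np.linspace(0, 3, 150)
        F = fpt_cdf(grid, WienerParams(v=0.4, a=1, z=0.6), "lower")
        assert np.all(np.diff(F) >= -1e-12)

    def test_negative_time_raises(self):
        with pytest.raises(DomainError):
            fpt_cdf(-1e-9, WienerParams(v=1, a=1, z=0.5), "lower")


def test_driftless_mean_first_passage_time():
    """Simulated driftless mean absorption time matches z(a-z)/s^2."""
    up, t_abs = euler_absorb_oracle(0, 1, 0.5, 1, n=60_000, dt=5e-4, seed=9)
    mean = t_abs.mean()
    se = t_abs.std() / math.sqrt(t_abs.size)
    assert abs(mean - 0.25) < 4 * se + 5e-4   # allow for the dt/2 timing grid
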