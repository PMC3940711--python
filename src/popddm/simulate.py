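"""Trial-level sampling from the diffusion model and full synthetic studies.

The per-trial sampler is Euler-Maruyama with a 0.1 ms step: each trial
draws its drift from Normal(v, eta), its starting point from
Uniform(z +/- Sz/2), and its non-decision time from Uniform(Ter +/- St/2),
then integrates the diffusion until a boundary is crossed.  All trials of
a batch are stepped in parallel, retiring trials as they absorb.

:func:`generate_study` is the complete synthetic-data stage: it builds a
pseudorandom trial sequence via :mod:`popddm.design`, classifies each
trial's inter-trial condition, and samples a latency and a correctness
flag for every labeled target-present trial from that condition's
expanded parameters.  Target-absent trials receive Bernoulli false alarms
(saccades that should have been withheld) and carry no diffusion latency;
trials without a condition label (first trial of a block) are simulated at
the subject's neutral baseline (B = 0.5, v = v0, pop-out-family a and Ter)
and are excluded from fitting by their label.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .conditions import Condition, FullModelParams, expand
from .design import LABEL_ABSENT, LABEL_UNLABELED, SequenceConfig, build_study
from .rdm import RDMConditionParams

__all__ = ["simulate_trial", "simulate_trials", "generate_study", "DEFAULT_DT"]

#: Euler-Maruyama step in seconds (0.1 ms)
DEFAULT_DT = 1e-4


def simulate_trials(p: RDMConditionParams, n: int, rng: np.random.Generator,
                    dt: float = DEFAULT_DT, max_time: float = 20.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` trials; returns (latencies in seconds, correct flags).

    A correct trial is one absorbed at the upper (target-color) boundary.
    Trials still unabsorbed after ``max_time`` of decision time (an event
    of negligible probability at study-scale parameters) are scored by
    their nearest boundary.
    """
    drift = rng.normal(p.v, p.eta, n) if p.eta > 0 else np.full(n, p.v)
    x = np.full(n, p.z) + (p.Sz * (rng.random(n) - 0.5) if p.Sz > 0 else 0.0)
    ter = np.full(n, p.Ter) + (p.St * (rng.random(n) - 0.5) if p.St > 0 else 0.0)

    latency = np.empty(n)
    correct = np.empty(n, dtype=bool)
    active = np.arange(n)
    x = np.array(x, dtype=float)
    t = 0.0
    sq = p.s * np.sqrt(dt)
    two_over_var = 2.0 / (p.s**2 * dt)
    max_steps = int(np.ceil(max_time / dt))
    for _ in range(max_steps):
        if active.size == 0:
            break
        t += dt
        x0 = x[active]
        x1 = x0 + drift[active] * dt + sq * rng.standard_normal(active.size)
        x[active] = x1
        hit_up = x1 >= p.a
        hit_lo = x1 <= 0.0
        # Brownian-bridge correction: the path may have touched a boundary
        # within the step even though both endpoints are interior; without
        # it the discrete scheme systematically under-detects crossings.
        interior = ~(hit_up | hit_lo)
        if np.any(interior):
            xi0, xi1 = x0[interior], x1[interior]
            p_up = np.exp(-two_over_var * (p.a - xi0) * (p.a - xi1))
            p_lo = np.exp(-two_over_var * xi0 * xi1)
            u = rng.random(xi0.size)
            bridge_up = u < p_up
            bridge_lo = (~bridge_up) & (u < p_up + p_lo)
            hit_up[interior] |= bridge_up
            hit_lo[interior] |= bridge_lo
        done = hit_up | hit_lo
        if np.any(done):
            idx = active[done]
            latency[idx] = ter[idx] + t
            correct[idx] = hit_up[done]
            active = active[~done]
    if active.size:   # force-score stragglers by nearest boundary
        latency[active] = ter[active] + t
        correct[active] = x[active] >= p.a / 2.0
    return latency, correct


def simulate_trial(p: RDMConditionParams, rng: np.random.Generator,
                   dt: float = DEFAULT_DT) -> tuple[float, bool]:
    """Sample a single trial; returns (latency in seconds, correct flag)."""
    lat, cor = simulate_trials(p, 1, rng, dt=dt)
    return float(lat[0]), bool(cor[0])


def _neutral_params(m: FullModelParams) -> RDMConditionParams:
    """Baseline parameters for trials without an inter-trial label."""
    return RDMConditionParams(v=m.v0, a=m.a_POP, B=0.5, Ter=m.T_POP,
                              eta=m.eta, Sz=min(m.Sz, m.a_POP * 0.999),
                              St=m.St, s=m.s)


def generate_study(params_by_subject: Mapping[str, FullModelParams],
                   cfg: Optional[SequenceConfig] = None,
                   false_alarm_rate: float | Mapping[str, float] = 0.02,
                   seed: int = 0,
                   dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Simulate a complete behavioral study as a trial-record table.

    Returns the design columns of :func:`popddm.design.build_study` plus
    ``latency_ms`` (empty for absent trials and withheld saccades),
    ``correct`` (0/1, target-present trials only) and ``false_alarm``
    (0/1, target-absent trials only).  Identical seeds yield identical
    tables.
    """
    subjects = list(params_by_subject)
    if cfg is None:
        cfg = SequenceConfig(n_subjects=len(subjects), subjects=subjects)
    elif cfg.subjects is None:
        cfg = SequenceConfig(cfg.n_subjects, cfg.sessions, cfg.blocks,
                             cfg.trials_per_block, cfg.seed, subjects)

    ss = np.random.SeedSequence(seed)
    design_rng = np.random.default_rng(ss.spawn(1)[0])
    df = build_study(cfg, rng=design_rng)

    df["latency_ms"] = np.nan
    df["correct"] = pd.array([pd.NA] * len(df), dtype="Int8")
    df["false_alarm"] = pd.array([pd.NA] * len(df), dtype="Int8")

    for subject, sub_ss in zip(subjects, ss.spawn(len(subjects))):
        rng = np.random.default_rng(sub_ss)
        m = params_by_subject[subject]
        sub_mask = df["subject"] == subject

        # labeled target-present trials, one vectorized batch per condition
        for cond in Condition:
            mask = sub_mask & (df["condition"] == cond.value)
            n = int(mask.sum())
            if n == 0:
                continue
            lat, cor = simulate_trials(expand(m, cond), n, rng, dt=dt)
            df.loc[mask, "latency_ms"] = lat * 1000.0
            df.loc[mask, "correct"] = cor.astype(int)

        mask = sub_mask & (df["condition"] == LABEL_UNLABELED)
        n = int(mask.sum())
        if n:
            lat, cor = simulate_trials(_neutral_params(m), n, rng, dt=dt)
            df.loc[mask, "latency_ms"] = lat * 1000.0
            df.loc[mask, "correct"] = cor.astype(int)

        mask = sub_mask & (df["condition"] == LABEL_ABSENT)
        n = int(mask.sum())
        if n:
            rate = (false_alarm_rate.get(subject, 0.02)
                    if isinstance(false_alarm_rate, Mapping)
                    else float(false_alarm_rate))
            df.loc[mask, "false_alarm"] = (rng.random(n) < rate).astype(int)
    return df
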