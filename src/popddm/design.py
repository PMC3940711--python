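"""Pseudorandom trial-sequence generation and inter-trial condition labeling.

The emulated design is a saccadic color-oddball search: three diamonds on
an iso-acuity ellipse, either all one color (target absent) or one oddball
among two same-colored distractors (target present, saccade to the
oddball).  Sequences are built from 32-trial sets.  Each set contains
eight designed trial pairs — the four inter-trial conditions crossed with
the two distractor colors — shuffled, with sixteen additional single
trials (half target-absent) inserted at random between the pairs.  The
default study layout is 5 subjects x 5 sessions x 5 blocks x 64 trials
(two sets per block), i.e. 1600 trials per subject.

Each target-present trial is then labeled by its relation to the
immediately preceding trial:

* previous trial target-present with the same color assignment -> ``SRe``
* previous trial target-present with swapped colors -> ``SSw``
* previous trial target-absent in the current *target* color -> ``TP``
* previous trial target-absent in the current *distractor* color -> ``DP``

Target-absent trials are labeled ``absent``; the first trial of a block is
``unlabeled`` (eye-tracker drift correction intervenes between blocks, so
cross-block relations are not meaningful and labeling never crosses a
block boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conditions import Condition
from .wiener import DomainError

__all__ = [
    "COLORS",
    "TrialSpec",
    "SequenceConfig",
    "build_pair",
    "build_set",
    "build_block",
    "build_study",
    "classify",
    "write_trials",
    "read_trials",
]

COLORS = ("red", "green")

#: labels that are not one of the four searchable conditions
LABEL_ABSENT = "absent"
LABEL_UNLABELED = "unlabeled"


def _other(color: str) -> str:
    return COLORS[1] if color == COLORS[0] else COLORS[0]


@dataclass(frozen=True)
class TrialSpec:
    """One display: target presence plus the color assignment."""

    target_present: bool
    target_color: Optional[str]   # None when target absent
    distractor_color: str

    def __post_init__(self) -> None:
        if self.distractor_color not in COLORS:
            raise DomainError(f"distractor_color must be one of {COLORS}")
        if self.target_present:
            if self.target_color not in COLORS:
                raise DomainError(f"target_color must be one of {COLORS}")
            if self.target_color == self.distractor_color:
                raise DomainError("target and distractor colors must differ")
        elif self.target_color is not None:
            raise DomainError("target-absent trials carry no target color")


@dataclass(frozen=True)
class SequenceConfig:
    """Study layout; the defaults reproduce the reference design."""

    n_subjects: int = 5
    sessions: int = 5
    blocks: int = 5
    trials_per_block: int = 64
    seed: Optional[int] = None
    subjects: Optional[Sequence[str]] = field(default=None)

    def __post_init__(self) -> None:
        if self.trials_per_block % 32 != 0:
            raise DomainError("trials_per_block must be a multiple of 32 "
                              "(sequences are built from 32-trial sets)")

    def subject_ids(self) -> list[str]:
        if self.subjects is not None:
            return list(self.subjects)
        return [f"P{i + 1}" for i in range(self.n_subjects)]


def build_pair(c: Condition | str, current_distractor_color: str
               ) -> tuple[TrialSpec, TrialSpec]:
    """The designed two-trial sequence realizing condition ``c``.

    ``current_distractor_color`` is the distractor color of the pair's
    second (always target-present) trial.
    """
    c = Condition(c)
    d = current_distractor_color
    if d not in COLORS:
        raise DomainError(f"distractor color must be one of {COLORS}")
    o = _other(d)
    second = TrialSpec(True, o, d)
    if c is Condition.SRe:
        first = TrialSpec(True, o, d)
    elif c is Condition.SSw:
        first = TrialSpec(True, d, o)
    elif c is Condition.TP:
        first = TrialSpec(False, None, o)   # absent display in current target color
    else:  # DP
        first = TrialSpec(False, None, d)   # absent display in current distractor color
    return first, second


def build_set(rng: np.random.Generator) -> list[TrialSpec]:
    """One 32-trial set: 8 shuffled designed pairs with 16 inserted singles.

    The inserted singles are 8 target-absent (four per color) and 8
    target-present (four per distractor color), placed uniformly at random
    in the gaps between pairs (never splitting a pair).
    """
    pairs = [build_pair(c, d) for c in Condition for d in COLORS]
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    singles: list[TrialSpec] = []
    for color in COLORS:
        singles.extend(TrialSpec(False, None, color) for _ in range(4))
        singles.extend(TrialSpec(True, _other(color), color) for _ in range(4))
    singles = [singles[i] for i in rng.permutation(len(singles))]

    # gap g holds singles placed before pair g; gap len(pairs) is the end
    gaps: list[list[TrialSpec]] = [[] for _ in range(len(pairs) + 1)]
    for trial in singles:
        gaps[int(rng.integers(0, len(pairs) + 1))].append(trial)

    out: list[TrialSpec] = []
    for g, pair in enumerate(pairs):
        out.extend(gaps[g])
        out.extend(pair)
    out.extend(gaps[len(pairs)])
    return out


def build_block(rng: np.random.Generator, n_trials: int = 64) -> list[TrialSpec]:
    if n_trials % 32 != 0:
        raise DomainError("block length must be a multiple of 32")
    out: list[TrialSpec] = []
    for _ in range(n_trials // 32):
        out.extend(build_set(rng))
    return out


def classify(trials: Sequence[TrialSpec]) -> list[str]:
    """Label each trial of one contiguous block by its predecessor relation."""
    labels: list[str] = []
    for i, trial in enumerate(trials):
        if not trial.target_present:
            labels.append(LABEL_ABSENT)
            continue
        if i == 0:
            labels.append(LABEL_UNLABELED)
            continue
        prev = trials[i - 1]
        if prev.target_present:
            labels.append(Condition.SRe.value
                          if prev.target_color == trial.target_color
                          else Condition.SSw.value)
        elif prev.distractor_color == trial.target_color:
            labels.append(Condition.TP.value)
        else:
            labels.append(Condition.DP.value)
    return labels


def build_study(cfg: SequenceConfig = SequenceConfig(),
                rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Full study table with condition labels.

    Columns: subject, session, block, trial (1-based within block),
    target_present (0/1), target_color, distractor_color, condition.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows = []
    for subject in cfg.subject_ids():
        for session in range(1, cfg.sessions + 1):
            for block in range(1, cfg.blocks + 1):
                trials = build_block(rng, cfg.trials_per_block)
                labels = classify(trials)
                for idx, (trial, label) in enumerate(zip(trials, labels), start=1):
                    rows.append({
                        "subject": subject,
                        "session": session,
                        "block": block,
                        "trial": idx,
                        "target_present": int(trial.target_present),
                        "target_color": trial.target_color or "",
                        "distractor_color": trial.distractor_color,
                        "condition": label,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (booleans as 0/1, colors lowercase)."""
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=[""], dtype={"subject": str})
    df["target_color"] = df["target_color"].fillna("")
    return df
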