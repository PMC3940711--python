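"""Parameter-constraint scheme mapping the 12-parameter model onto conditions.

A subject is described by twelve parameters: two bias deltas (``dB_DPE``,
``dB_POP``), a baseline drift ``v0`` with two drift deltas (``dv_DPE``,
``dv_POP``), separate boundary separations and non-decision times for the
distractor-preview and pop-out-priming trial families (``a_DPE``/``a_POP``,
``T_DPE``/``T_POP``), and three variability parameters shared across all
conditions (``Sz``, ``St``, ``eta``).

The four inter-trial conditions expand as

=========  ==============  ============  =======  =======
condition  B               v             a        Ter
=========  ==============  ============  =======  =======
DP         0.5 + dB_DPE    v0 + dv_DPE   a_DPE    T_DPE
TP         0.5 - dB_DPE    v0 - dv_DPE   a_DPE    T_DPE
SRe        0.5 + dB_POP    v0 + dv_POP   a_POP    T_POP
SSw        0.5 - dB_POP    v0 - dv_POP   a_POP    T_POP
=========  ==============  ============  =======  =======

so that positive deltas favor the facilitated condition of each effect
(DP over TP, repeated over switched search).  Deltas may be negative;
signed estimates are preserved.

Sub-models fix one or two of these degrees of freedom (a delta to zero, or
the two boundary separations / non-decision times shared), implemented by
removing the corresponding entries from the free parameter vector so the
optimizer dimension equals the number of free parameters counted by
AIC/BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from .rdm import DEFAULT_S, RDMConditionParams
from .wiener import DomainError

__all__ = [
    "Condition",
    "FullModelParams",
    "SubModelSpec",
    "expand",
    "enumerate_submodels",
    "get_submodel",
    "free_parameter_count",
    "apply_constraints",
    "free_fields",
    "SUBMODEL_NAMES",
]


class Condition(str, Enum):
    """The four inter-trial search conditions."""

    SRe = "SRe"   # search repeated: colors repeat across consecutive trials
    SSw = "SSw"   # search switched: color assignment swapped
    TP = "TP"     # target-color previewed: previous absent display in target color
    DP = "DP"     # distractor-color previewed: previous absent display in distractor color


#: all twelve model parameters, in canonical order
PARAM_FIELDS = (
    "dB_DPE", "dB_POP", "v0", "dv_DPE", "dv_POP",
    "a_DPE", "a_POP", "T_DPE", "T_POP", "Sz", "St", "eta",
)


@dataclass(frozen=True)
class FullModelParams:
    """The twelve-parameter subject-level model (plus the fixed scale s)."""

    dB_DPE: float
    dB_POP: float
    v0: float
    dv_DPE: float
    dv_POP: float
    a_DPE: float
    a_POP: float
    T_DPE: float
    T_POP: float
    Sz: float
    St: float
    eta: float
    s: float = DEFAULT_S

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS + ("s",):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"FullModelParams.{name} must be finite")
        if self.a_DPE <= 0 or self.a_POP <= 0:
            raise DomainError("boundary separations must be > 0")
        if abs(self.dB_DPE) >= 0.5 or abs(self.dB_POP) >= 0.5:
            raise DomainError("bias deltas must keep 0 < 0.5 +/- dB < 1")
        if min(self.Sz, self.St, self.eta) < 0:
            raise DomainError("Sz, St, eta must be >= 0")
        if self.T_DPE < self.St / 2.0 or self.T_POP < self.St / 2.0:
            raise DomainError("non-decision times must be >= St/2")
        if self.s <= 0:
            raise DomainError("scaling constant s must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in PARAM_FIELDS}


# (B sign, v sign, family) per condition; family selects a_*/T_*
_EXPANSION = {
    Condition.DP: (+1, +1, "DPE"),
    Condition.TP: (-1, -1, "DPE"),
    Condition.SRe: (+1, +1, "POP"),
    Condition.SSw: (-1, -1, "POP"),
}


def expand(m: FullModelParams, c: Condition | str) -> RDMConditionParams:
    """Per-condition diffusion parameters implied by the constraint scheme."""
    c = Condition(c)
    b_sign, v_sign, family = _EXPANSION[c]
    if family == "DPE":
        dB, dv, a, ter = m.dB_DPE, m.dv_DPE, m.a_DPE, m.T_DPE
    else:
        dB, dv, a, ter = m.dB_POP, m.dv_POP, m.a_POP, m.T_POP
    try:
        return RDMConditionParams(
            v=m.v0 + v_sign * dv,
            a=a,
            B=0.5 + b_sign * dB,
            Ter=ter,
            eta=m.eta,
            Sz=m.Sz,
            St=m.St,
            s=m.s,
        )
    except DomainError as exc:
        raise DomainError(f"invalid parameters for condition {c.value}: {exc}") from exc


# ---------------------------------------------------------------------------
# sub-models
# ---------------------------------------------------------------------------

#: constraint flag -> (field it removes, field it is tied to or zero)
_CONSTRAINT_EFFECT = {
    "dB_DPE=0": ("dB_DPE", 0.0),
    "dB_POP=0": ("dB_POP", 0.0),
    "dv_DPE=0": ("dv_DPE", 0.0),
    "dv_POP=0": ("dv_POP", 0.0),
    "a_shared": ("a_POP", "a_DPE"),
    "T_shared": ("T_POP", "T_DPE"),
}


@dataclass(frozen=True)
class SubModelSpec:
    """A named constrained variant of the full model."""

    name: str
    constraints: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.constraints - set(_CONSTRAINT_EFFECT)
        if bad:
            raise DomainError(f"unknown constraint flags: {sorted(bad)}")


_SUBMODELS = [
    SubModelSpec("full", frozenset()),
    SubModelSpec("noB_all", frozenset({"dB_DPE=0", "dB_POP=0"})),
    SubModelSpec("noB_dpe", frozenset({"dB_DPE=0"})),
    SubModelSpec("noB_pop", frozenset({"dB_POP=0"})),
    SubModelSpec("nov_all", frozenset({"dv_DPE=0", "dv_POP=0"})),
    SubModelSpec("nov_dpe", frozenset({"dv_DPE=0"})),
    SubModelSpec("nov_pop", frozenset({"dv_POP=0"})),
    SubModelSpec("a_shared", frozenset({"a_shared"})),
    SubModelSpec("t_shared", frozenset({"T_shared"})),
]

SUBMODEL_NAMES = tuple(sm.name for sm in _SUBMODELS)


def enumerate_submodels() -> list[SubModelSpec]:
    """The full model plus the eight constrained sub-models."""
    return list(_SUBMODELS)


def get_submodel(name: str) -> SubModelSpec:
    for sm in _SUBMODELS:
        if sm.name == name:
            return sm
    raise DomainError(
        f"unknown sub-model {name!r}; choose from {', '.join(SUBMODEL_NAMES)}")


def free_parameter_count(spec: SubModelSpec) -> int:
    """Number of free parameters M: 12 minus one per constraint."""
    return len(PARAM_FIELDS) - len(spec.constraints)


def apply_constraints(m: FullModelParams, spec: SubModelSpec) -> FullModelParams:
    """Project ``m`` onto the sub-model: constrained fields zeroed/shared."""
    updates: dict[str, float] = {}
    for flag in spec.constraints:
        field, source = _CONSTRAINT_EFFECT[flag]
        updates[field] = source if isinstance(source, float) else getattr(m, source)
    return replace(m, **updates)


def free_fields(spec: SubModelSpec) -> tuple[str, ...]:
    """Names of the fields the optimizer varies, in canonical order."""
    removed = {_CONSTRAINT_EFFECT[flag][0] for flag in spec.constraints}
    return tuple(f for f in PARAM_FIELDS if f not in removed)
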