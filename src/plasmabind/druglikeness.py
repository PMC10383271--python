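"""Rule-based drug-likeness screening over supplied descriptor sets.

Descriptors (MW, logP, H-bond donors/acceptors, rotatable bonds, TPSA,
WLOGP) are inputs — in the source study they come from an external ADME
prediction server — and are checked against published filters:

* Lipinski rule of five: MW <= 500 g/mol, logP <= 5, HBD <= 5,
  HBA <= 10 (HBA read as the classic N+O count).
* Veber rule: rotatable bonds <= 10 and TPSA <= 140 A^2 (boundary
  values pass).
* BOILED-Egg: passive GI absorption / BBB permeation by membership of
  the (TPSA, WLOGP) point in the "white" and "yolk" ellipses.  The
  default ellipse coefficients are external constants from the original
  BOILED-Egg publication and are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import MissingDescriptorError, ValidationError


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptors for one compound.

    ``mw`` is the conventional average molecular weight (g/mol); counts
    are non-negative integers; ``tpsa`` in A^2.  Optional fields default
    to ``None`` and the rules that need them raise
    :class:`MissingDescriptorError` when absent.
    """

    compound_id: str
    mw: float | None = None
    logp: float | None = None
    hbd: int | None = None
    hba: int | None = None
    rotatable_bonds: int | None = None
    tpsa: float | None = None
    wlogp: float | None = None

    def __post_init__(self):
        if self.mw is not None and self.mw <= 0:
            raise ValidationError("MW must be positive")
        for name in ("hbd", "hba", "rotatable_bonds"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.tpsa is not None and self.tpsa < 0:
            raise ValidationError("TPSA must be >= 0")

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise MissingDescriptorError(name)


@dataclass(frozen=True)
class RuleViolation:
    descriptor: str
    limit: float
    value: float


@dataclass(frozen=True)
class RuleVerdict:
    """Outcome of one rule: the violated limits, empty iff passing."""

    rule: str
    violations: tuple[RuleViolation, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return not self.violations


LIPINSKI_LIMITS = {"mw": 500.0, "logp": 5.0, "hbd": 5.0, "hba": 10.0}
VEBER_LIMITS = {"rotatable_bonds": 10.0, "tpsa": 140.0}


def _check(d: DescriptorSet, rule: str, limits: dict[str, float]) -> RuleVerdict:
    d.require(*limits)
    violations = tuple(
        RuleViolation(name, limit, float(getattr(d, name)))
        for name, limit in limits.items()
        if getattr(d, name) > limit
    )
    return RuleVerdict(rule=rule, violations=violations)


def lipinski(d: DescriptorSet) -> RuleVerdict:
    """Lipinski rule-of-five verdict (all four limits enumerated)."""
    return _check(d, "lipinski_ro5", LIPINSKI_LIMITS)


def veber(d: DescriptorSet) -> RuleVerdict:
    """Veber oral-bioavailability rule verdict (boundary values pass)."""
    return _check(d, "veber", VEBER_LIMITS)


@dataclass(frozen=True)
class Ellipse:
    """Axis-rotated ellipse in the (TPSA, WLOGP) plane.

    ``angle_deg`` rotates the semi-axes counter-clockwise about the
    center; a point is inside when its rotated, normalized coordinates
    satisfy (x/rx)^2 + (y/ry)^2 <= 1.
    """

    cx: float
    cy: float
    rx: float
    ry: float
    angle_deg: float = 0.0

    def contains(self, x: float, y: float) -> bool:
        theta = math.radians(self.angle_deg)
        dx, dy = x - self.cx, y - self.cy
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        return (u / self.rx) ** 2 + (v / self.ry) ** 2 <= 1.0


# External constants: best-fit ellipses of the original BOILED-Egg model
# (white = passive GI absorption, yolk = passive BBB permeation), given
# as center, semi-axes, and rotation in the (TPSA, WLOGP) plane.
BOILED_EGG_WHITE = Ellipse(cx=71.051, cy=2.292, rx=142.081 / 2, ry=8.740 / 2,
                           angle_deg=-1.031)
BOILED_EGG_YOLK = Ellipse(cx=38.117, cy=3.481, rx=82.061 / 2, ry=5.557 / 2,
                          angle_deg=-0.171)


@dataclass(frozen=True)
class BoiledEggResult:
    gi_absorbed: bool
    bbb_permeant: bool


def boiled_egg(
    wlogp: float,
    tpsa: float,
    white: Ellipse = BOILED_EGG_WHITE,
    yolk: Ellipse = BOILED_EGG_YOLK,
) -> BoiledEggResult:
    """Classify passive GI absorption and BBB permeation.

    Both ellipses are tested independently (the yolk lies inside the
    white, so a BBB-permeant compound is normally also GI-absorbed).
    """
    if wlogp is None:
        raise MissingDescriptorError("wlogp")
    if tpsa is None:
        raise MissingDescriptorError("tpsa")
    return BoiledEggResult(
        gi_absorbed=white.contains(tpsa, wlogp),
        bbb_permeant=yolk.contains(tpsa, wlogp),
    )


def evaluate(d: DescriptorSet) -> dict:
    """All applicable verdicts for one descriptor set, JSON-ready.

    BOILED-Egg is skipped with a notice when WLOGP (or TPSA) is absent;
    Lipinski/Veber propagate their missing-descriptor errors.
    """
    out: dict = {
        "compound_id": d.compound_id,
        "lipinski": _verdict_dict(lipinski(d)),
        "veber": _verdict_dict(veber(d)),
    }
    try:
        egg = boiled_egg(d.wlogp, d.tpsa)
        out["boiled_egg"] = {
            "gi_absorbed": egg.gi_absorbed,
            "bbb_permeant": egg.bbb_permeant,
        }
    except MissingDescriptorError as exc:
        out["boiled_egg"] = {"skipped": f"missing descriptor {exc.descriptor}"}
    return out


def _verdict_dict(v: RuleVerdict) -> dict:
    return {
        "pass": v.passed,
        "violations": [
            {"descriptor": x.descriptor, "limit": x.limit, "value": x.value}
            for x in v.violations
        ],
    }
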