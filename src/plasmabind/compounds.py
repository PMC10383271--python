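"""Compound registry, molecular-formula parsing, and monoisotopic masses.

The study compounds are N-acylhydrazone (NAH) derivatives of a
pyrrolo[3,4-d]pyridazinone core, built from C/H/N/O/Cl only.  Identity is
confirmed by high-resolution ESI-MS of the protonated molecule, so the
central computation here is the monoisotopic [M+H]+ mass: the sum of
principal-isotope masses over the formula plus one proton.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from types import MappingProxyType
from typing import Mapping

from .errors import ConfigurationError, FormulaParseError, UnsupportedElementError

#: Principal-isotope (most abundant isotope) masses, Da.
MONOISOTOPIC_MASS: Mapping[str, float] = MappingProxyType(
    {
        "C": 12.000000,
        "H": 1.0078250,
        "N": 14.0030740,
        "O": 15.9949146,
        "Cl": 34.9688527,
    }
)

#: Proton mass, Da — the adduct constant of an [M+H]+ ion.  Using the
#: proton rather than a hydrogen atom (which would ignore the missing
#: electron) matches printed calcd values at 4 decimal places.
PROTON_MASS: float = 1.0072765

#: Standard average atomic weights, g/mol, for conventional (Ro5-style)
#: molecular-weight checks.
AVERAGE_MASS: Mapping[str, float] = MappingProxyType(
    {
        "C": 12.011,
        "H": 1.008,
        "N": 14.007,
        "O": 15.999,
        "Cl": 35.45,
    }
)

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-order molecular formula string into element counts.

    Grammar: a sequence of element tokens, each an uppercase letter with an
    optional lowercase letter, followed by an optional integer count >= 1
    (implicit 1).  No parentheses, charges, or hydrates.

    >>> parse_formula("C22H27N5O3")
    {'C': 22, 'H': 27, 'N': 5, 'O': 3}
    """
    if not formula or not formula.strip():
        raise FormulaParseError("empty formula", position=0)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaParseError(
                f"malformed formula {formula!r} at position {pos} "
                f"({formula[pos:pos + 3]!r})",
                position=pos,
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise UnsupportedElementError(symbol, position=pos)
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaParseError(
                f"count for {symbol} must be >= 1 at position {pos}",
                position=pos,
            )
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts as a canonical Hill-order formula string.

    Hill order: C first, then H, then remaining elements alphabetically.
    Count 1 is implicit.  Round-trips with :func:`parse_formula`.
    """
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)


def _checked(counts: Mapping[str, int]) -> Mapping[str, int]:
    for symbol, count in counts.items():
        if symbol not in MONOISOTOPIC_MASS:
            raise UnsupportedElementError(symbol)
        if count < 1:
            raise FormulaParseError(f"count for {symbol} must be >= 1")
    return counts


def monoisotopic_mass(counts: Mapping[str, int] | str) -> float:
    """Neutral monoisotopic mass in Da of a formula or count map."""
    if isinstance(counts, str):
        counts = parse_formula(counts)
    return sum(MONOISOTOPIC_MASS[e] * k for e, k in _checked(counts).items())


def monoisotopic_mh(counts: Mapping[str, int] | str) -> float:
    """Monoisotopic [M+H]+ mass in Da: neutral mass plus one proton."""
    return monoisotopic_mass(counts) + PROTON_MASS


def average_mass(counts: Mapping[str, int] | str) -> float:
    """Average molecular weight in g/mol (standard atomic weights)."""
    if isinstance(counts, str):
        counts = parse_formula(counts)
    return sum(AVERAGE_MASS[e] * k for e, k in _checked(counts).items())


@dataclass(frozen=True)
class CompoundRecord:
    """One registry compound.

    ``r`` is the pyridazinone N-substituent series tag (n-butyl / phenyl /
    3-chlorophenyl); ``r1`` the benzylidene-ring substituent (H / 2-OH /
    4-CH3); both are ``None`` for synthetic intermediates.  ``reported_mh``
    is the published calcd [M+H]+ value used for validation.
    """

    id: str
    formula: str
    reported_mh: float
    r: str | None = None
    r1: str | None = None
    stage: str = "final"

    @property
    def element_counts(self) -> dict[str, int]:
        return parse_formula(self.formula)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.element_counts)

    @property
    def monoisotopic_mh(self) -> float:
        return monoisotopic_mh(self.element_counts)

    @property
    def average_mass(self) -> float:
        return average_mass(self.element_counts)

    @property
    def mass_error(self) -> float:
        """Signed difference computed − reported [M+H]+, Da."""
        return self.monoisotopic_mh - self.reported_mh


#: Agreement required between computed and reported calcd masses, Da.
MASS_TOLERANCE = 5e-4


@lru_cache(maxsize=1)
def load_registry() -> tuple[CompoundRecord, ...]:
    """Load the bundled compound registry and validate every mass.

    Raises :class:`ConfigurationError` if the registry file is missing or
    malformed, if ids repeat, or if any computed [M+H]+ deviates from its
    reported value by more than ``MASS_TOLERANCE``.
    """
    try:
        raw = (
            resources.files("plasmabind").joinpath("data/registry.json").read_text()
        )
        entries = json.loads(raw)
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"compound registry unreadable: {exc}") from exc

    records = []
    seen: set[str] = set()
    for entry in entries:
        try:
            rec = CompoundRecord(**entry)
        except TypeError as exc:
            raise ConfigurationError(f"bad registry entry {entry!r}: {exc}") from exc
        if rec.id in seen:
            raise ConfigurationError(f"duplicate registry id {rec.id!r}")
        seen.add(rec.id)
        if abs(rec.mass_error) > MASS_TOLERANCE:
            raise ConfigurationError(
                f"registry compound {rec.id}: computed [M+H]+ "
                f"{rec.monoisotopic_mh:.4f} deviates from reported "
                f"{rec.reported_mh:.4f} by more than {MASS_TOLERANCE} Da"
            )
        records.append(rec)
    return tuple(records)


def get_compound(compound_id: str) -> CompoundRecord:
    """Look up one registry compound by id."""
    for rec in load_registry():
        if rec.id == compound_id:
            return rec
    raise KeyError(f"unknown compound id {compound_id!r}")
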