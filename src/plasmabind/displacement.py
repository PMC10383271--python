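"""Site-marker displacement analysis and binding-site assignment.

Fluorescent site markers report which protein pocket a ligand occupies:
dansyl-L-glycine (DanG) marks HSA drug site 1 (subdomain IIA),
dansyl-L-phenylalanine (DanF) marks HSA drug site 2 (subdomain IIIA),
and quinaldine red (QR) marks the single drug site of AAG.  When the
ligand displaces a bound marker its fluorescence drops, and the percent
replacement at each protein:marker:ligand ratio is

    replacement% = 100 * (F0 - F) / F0.

The marker with the larger replacement identifies the preferred site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError

MARKER_SITE = {"DanG": "HSA_site1", "DanF": "HSA_site2", "QR": "AAG_drug_site"}
MARKER_PROTEIN = {"DanG": "HSA", "DanF": "HSA", "QR": "AAG"}

#: Replacement margins (percentage points) below which two markers tie.
DEFAULT_TIE_TOL = 2.0


@dataclass(frozen=True)
class DisplacementSeries:
    """Marker fluorescence vs ligand:protein ratio (protein:marker 1:1).

    Ratios must start at 0 (marker only) and increase strictly.  Marker
    intensities are used as observed; no inner-filter correction is
    applied in this assay.
    """

    marker: str
    ratios: tuple[float, ...]
    f: tuple[float, ...]

    def __post_init__(self):
        if self.marker not in MARKER_SITE:
            raise ValidationError(
                f"unknown marker {self.marker!r}; expected one of {sorted(MARKER_SITE)}"
            )
        object.__setattr__(self, "ratios", tuple(float(r) for r in self.ratios))
        object.__setattr__(self, "f", tuple(float(v) for v in self.f))
        if len(self.ratios) != len(self.f):
            raise ValidationError("ratios and intensities must have equal length")
        if not self.ratios or self.ratios[0] != 0.0:
            raise ValidationError("ratio grid must start at 0")
        if np.any(np.diff(self.ratios) <= 0):
            raise ValidationError("ratios must be strictly increasing")
        if self.f[0] <= 0:
            raise ValidationError("reference intensity F0 must be positive")

    @property
    def f0(self) -> float:
        return self.f[0]

    @property
    def site_label(self) -> str:
        return MARKER_SITE[self.marker]

    @property
    def protein(self) -> str:
        return MARKER_PROTEIN[self.marker]


def percent_replacement(f0, f):
    """Percent marker replacement, 100 (F0 - F)/F0.

    Scalar or element-wise on arrays.  Values below 0 (F > F0) indicate
    fluorescence enhancement rather than displacement and are returned
    as-is so callers can flag them.  Invariant to common rescaling of
    (F0, F).
    """
    f0 = np.asarray(f0, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f0 <= 0):
        raise ValidationError("F0 must be positive")
    if np.any(f < 0):
        raise ValidationError("intensities must be non-negative")
    out = 100.0 * (f0 - f) / f0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ReplacementProfile:
    """Percent replacement at each ratio, with data-quality notes."""

    marker: str
    by_ratio: dict[float, float]
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def protein(self) -> str:
        return MARKER_PROTEIN[self.marker]


def replacement_profile(series: DisplacementSeries) -> ReplacementProfile:
    """Apply the replacement formula pointwise across a marker series.

    A non-monotone profile (replacement decreasing with ratio) is legal
    data but is reported as a quality note, as is any enhancement
    (negative replacement).
    """
    pct = percent_replacement(series.f0, np.asarray(series.f))
    notes: list[str] = []
    if np.any(np.diff(pct) < 0):
        notes.append("replacement profile is not monotonically non-decreasing")
    if np.any(pct < 0):
        notes.append("negative replacement (fluorescence enhancement) observed")
    return ReplacementProfile(
        marker=series.marker,
        by_ratio=dict(zip(series.ratios, pct.tolist())),
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class SiteAssignment:
    """Preferred binding site, the winning marker, and the margin in
    percentage points at the comparison ratio."""

    site: str  # a MARKER_SITE value, or "indeterminate"
    marker: str | None
    margin: float
    at_ratio: float


def assign_site(
    profiles: Mapping[str, ReplacementProfile],
    at_ratio: float | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> SiteAssignment:
    """Assign the preferred binding site from >= 2 marker profiles.

    The comparison is made at ``at_ratio`` (default: the largest ratio
    present in every profile).  All profiles must belong to the same
    protein.  A margin below ``tie_tol`` percentage points yields an
    indeterminate assignment.
    """
    if len(profiles) < 2:
        raise ValidationError("site assignment needs >= 2 marker profiles")
    proteins = {p.protein for p in profiles.values()}
    if len(proteins) > 1:
        raise ValidationError(
            f"markers from different proteins mixed: {sorted(proteins)}"
        )
    if at_ratio is None:
        common = set.intersection(*(set(p.by_ratio) for p in profiles.values()))
        if not common:
            raise ValidationError("profiles share no common ratio")
        at_ratio = max(common)
    try:
        scores = {m: p.by_ratio[at_ratio] for m, p in profiles.items()}
    except KeyError as exc:
        raise ValidationError(f"ratio {at_ratio} missing from profile") from exc
    ranked = sorted(scores.items(), key=lambda kv: kv[1], reverse=True)
    margin = ranked[0][1] - ranked[1][1]
    if margin < tie_tol:
        return SiteAssignment("indeterminate", None, margin, at_ratio)
    best = ranked[0][0]
    return SiteAssignment(MARKER_SITE[best], best, margin, at_ratio)
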