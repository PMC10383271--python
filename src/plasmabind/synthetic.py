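"""Synthetic data generator for every input the pipeline consumes.

The generator reproduces the statistical structure the analysis stages
assume, so the whole pipeline is testable without instrument data:

* quenching titrations drawn from the 1:1 static-complex model
  (F0 - F)/F = Kb [Q]^n, inner-filter attenuation from Beer–Lambert
  absorbances, and the study's titration grid (protein 1e-6 mol/dm3,
  ligand:protein ratios 0 to 2 in 0.4 steps, temperatures 297/303/308 K);
* marker-displacement series as saturating displacement curves on the
  study's ratio ladders;
* CD spectra as convex combinations of the bundled alpha/beta/coil
  component bands on the 205–250 nm grid.

The free ligand concentration is taken as the total added ligand (the
same approximation the analysis equations make; depletion by binding is
ignored).  All randomness is seeded; noiseless output inverts exactly
under the corresponding fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cd import CDSpectrum, structural_basis
from .displacement import MARKER_PROTEIN, DisplacementSeries
from .errors import ConfigurationError, ValidationError
from .quenching import TitrationPoint, TitrationSeries
from .thermodynamics import R_GAS

#: Ligand:protein molar-ratio grid of the titration experiments.
DEFAULT_RATIO_GRID = (0.0, 0.4, 0.8, 1.2, 1.6, 2.0)

#: Measurement temperatures, K.
DEFAULT_TEMPERATURES = (297.0, 303.0, 308.0)

#: Ligand:protein ratio ladders of the marker-displacement experiments.
HSA_MARKER_RATIOS = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 10.0)
AAG_MARKER_RATIOS = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)

#: Protein:ligand ratio ladder of the CD experiments.
CD_RATIOS = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)

#: Default CD wavelength grid, nm.
DEFAULT_CD_WAVELENGTHS = tuple(np.arange(205.0, 250.5, 0.5))


@dataclass(frozen=True)
class TitrationDesign:
    """Experimental design of one fluorescence titration.

    ``eps_ex``/``eps_em`` are effective molar absorptivity x pathlength
    per unit quencher concentration (dm3/mol), so A_ex = eps_ex [Q];
    zero (the default) disables the inner-filter effect.  ``noise_rel``
    is the relative SD of multiplicative Gaussian intensity noise.
    """

    protein_conc: float = 1e-6
    ratio_grid: tuple[float, ...] = DEFAULT_RATIO_GRID
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    f0: float = 1000.0
    eps_ex: float = 0.0
    eps_em: float = 0.0
    noise_rel: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "ratio_grid", tuple(float(r) for r in self.ratio_grid))
        object.__setattr__(
            self, "temperatures", tuple(float(t) for t in self.temperatures)
        )
        if self.protein_conc <= 0:
            raise ValidationError("protein concentration must be positive")
        if not self.ratio_grid or self.ratio_grid[0] != 0.0:
            raise ValidationError("ratio grid must start at 0")
        if np.any(np.diff(self.ratio_grid) <= 0):
            raise ValidationError("ratio grid must be strictly increasing")
        if self.noise_rel < 0:
            raise ValidationError("noise_rel must be >= 0")
        if self.f0 <= 0:
            raise ValidationError("F0 must be positive")
        if self.eps_ex < 0 or self.eps_em < 0:
            raise ValidationError("absorptivities must be >= 0")

    @property
    def quencher_grid(self) -> np.ndarray:
        return np.asarray(self.ratio_grid) * self.protein_conc


@dataclass(frozen=True)
class GroundTruth:
    """True binding parameters behind a generated titration.

    Either a temperature-independent ``kb_ref`` or the van't Hoff pair
    (``dh`` J/mol, ``ds`` J mol-1 K-1) must be supplied; when dh/ds are
    given they define Kb(T) = exp(-dH/(R T) + dS/R) and ``kb_ref`` is
    ignored.
    """

    kb_ref: float | None = None
    n: float = 1.0
    dh: float | None = None
    ds: float | None = None

    def __post_init__(self):
        if (self.dh is None) != (self.ds is None):
            raise ConfigurationError("dh and ds must be supplied together")
        if self.dh is None and self.kb_ref is None:
            raise ConfigurationError("supply kb_ref or the (dh, ds) pair")
        if self.kb_ref is not None and self.kb_ref <= 0:
            raise ValidationError("kb_ref must be positive")
        if self.n <= 0:
            raise ValidationError("stoichiometry n must be positive")

    @classmethod
    def from_kb_and_enthalpy(
        cls, kb_ref: float, dh: float, t_ref: float = 297.0, n: float = 1.0
    ) -> "GroundTruth":
        """Truth with a chosen dH anchored so that Kb(t_ref) = kb_ref."""
        if kb_ref <= 0 or t_ref <= 0:
            raise ValidationError("kb_ref and t_ref must be positive")
        ds = dh / t_ref + R_GAS * math.log(kb_ref)
        return cls(kb_ref=None, n=n, dh=dh, ds=ds)

    def kb_at(self, temperature: float) -> float:
        if self.dh is not None:
            return math.exp(-self.dh / (R_GAS * temperature) + self.ds / R_GAS)
        return self.kb_ref


def _observe(f_corr: np.ndarray, q: np.ndarray, design: TitrationDesign, rng):
    """Apply inner-filter attenuation and multiplicative noise."""
    a_ex = design.eps_ex * q
    a_em = design.eps_em * q
    f_obs = f_corr * 10.0 ** (-(a_ex + a_em) / 2.0)
    if design.noise_rel > 0:
        f_obs = f_obs * (1.0 + rng.normal(0.0, design.noise_rel, size=f_obs.shape))
        f_obs = np.clip(f_obs, 1e-12, None)
    return f_obs, a_ex, a_em


def generate_titration(
    design: TitrationDesign, truth: GroundTruth
) -> list[TitrationSeries]:
    """Generate one static-quenching titration series per temperature.

    The corrected intensity follows F_corr = F0 / (1 + Kb(T) [Q]^n)
    exactly — the data-generating process is the inverse of the
    double-log fit, so noiseless output recovers (Kb, n) to machine
    precision.  The same seed yields bit-identical output.
    """
    rng = np.random.default_rng(design.seed)
    q = design.quencher_grid
    series = []
    for t in design.temperatures:
        kb = truth.kb_at(t)
        f_corr = design.f0 / (1.0 + kb * q**truth.n)
        f_obs, a_ex, a_em = _observe(f_corr, q, design, rng)
        series.append(
            TitrationSeries(
                points=tuple(
                    TitrationPoint(q=qi, f_obs=fi, a_ex=ai, a_em=bi)
                    for qi, fi, ai, bi in zip(q, f_obs, a_ex, a_em)
                ),
                temperature=t,
            )
        )
    return series


def generate_collisional_titration(
    design: TitrationDesign, ksv_by_temperature: Mapping[float, float]
) -> list[TitrationSeries]:
    """Generate purely collisional (dynamic) quenching titrations,
    F0/F = 1 + Ksv [Q], one series per supplied temperature.  Intended
    for exercising the mechanism classifier (Ksv should increase with
    temperature for a genuinely dynamic system)."""
    rng = np.random.default_rng(design.seed)
    q = design.quencher_grid
    series = []
    for t in sorted(ksv_by_temperature):
        ksv = ksv_by_temperature[t]
        if ksv < 0:
            raise ValidationError("Ksv must be >= 0")
        f_corr = design.f0 / (1.0 + ksv * q)
        f_obs, a_ex, a_em = _observe(f_corr, q, design, rng)
        series.append(
            TitrationSeries(
                points=tuple(
                    TitrationPoint(q=qi, f_obs=fi, a_ex=ai, a_em=bi)
                    for qi, fi, ai, bi in zip(q, f_obs, a_ex, a_em)
                ),
                temperature=float(t),
            )
        )
    return series


def generate_displacement(
    marker: str,
    displacement_strength: float,
    ratios: Sequence[float] | None = None,
    k_half: float = 1.0,
    f0: float = 1000.0,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> DisplacementSeries:
    """Generate a marker-displacement series.

    The marker intensity follows the saturating displacement curve
    F = F0 (1 - r * ratio / (k_half + ratio)) with plateau replacement
    r = ``displacement_strength`` (clipped into [0, 1] with a warning).
    Default ratio ladders: 8 points for the HSA markers (DanG, DanF),
    9 points for the AAG marker (QR).
    """
    if marker not in MARKER_PROTEIN:
        raise ValidationError(f"unknown marker {marker!r}")
    if displacement_strength < 0:
        raise ValidationError("displacement strength must be >= 0")
    if displacement_strength > 1:
        warnings.warn(
            f"displacement strength {displacement_strength} > 1 clipped to 1",
            stacklevel=2,
        )
        displacement_strength = 1.0
    if ratios is None:
        ratios = (
            AAG_MARKER_RATIOS if MARKER_PROTEIN[marker] == "AAG" else HSA_MARKER_RATIOS
        )
    r = np.asarray(ratios, dtype=float)
    f = f0 * (1.0 - displacement_strength * r / (k_half + r))
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        f = f * (1.0 + rng.normal(0.0, noise_rel, size=f.shape))
        f = np.clip(f, 1e-12, None)
    return DisplacementSeries(marker=marker, ratios=tuple(r), f=tuple(f))


def generate_cd(
    fractions: Sequence[float],
    wavelengths: Sequence[float] | None = None,
    noise_rel: float = 0.0,
    seed: int = 0,
    pathlength_cm: float = 1.0,
    residue_conc: float | None = None,
) -> CDSpectrum:
    """Generate a CD spectrum as a convex basis combination plus noise.

    ``fractions`` = (f_alpha, f_beta, f_coil) must be non-negative and
    sum to 1 (within 1e-9).  Noise is additive Gaussian with SD equal to
    ``noise_rel`` times the peak magnitude of the noiseless spectrum
    (the spectrum crosses zero, so relative multiplicative noise is not
    well defined).
    """
    f = np.asarray(fractions, dtype=float)
    if f.shape != (3,):
        raise ValidationError("fractions must be (f_alpha, f_beta, f_coil)")
    if np.any(f < 0):
        raise ValidationError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {f.sum()!r}")
    wl = np.asarray(
        DEFAULT_CD_WAVELENGTHS if wavelengths is None else wavelengths, dtype=float
    )
    if wl.min() < 205.0 - 1e-9 or wl.max() > 250.0 + 1e-9:
        raise ValidationError("wavelength grid must lie within 205–250 nm")
    theta = f @ structural_basis(wl)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_rel * np.abs(theta).max(), size=theta.shape)
    return CDSpectrum(
        wavelengths=wl,
        ellipticity=theta,
        pathlength_cm=pathlength_cm,
        residue_conc=residue_conc,
    )
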