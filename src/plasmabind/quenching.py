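"""Inner-filter correction and Stern–Volmer quenching analysis.

A fluorescence titration follows the tryptophan emission of a plasma
protein (HSA or AAG) as increasing amounts of a quenching ligand are
added.  Observed intensities are first corrected for the inner-filter
effect (re-absorption of excitation/emission light by the sample):

    F_corr = F_obs * 10^((A_ex + A_em) / 2)

and the corrected intensities are analysed with the Stern–Volmer law

    F0 / F = 1 + Ksv [Q]

whose slope Ksv, together with the unquenched fluorophore lifetime tau0,
gives the bimolecular quenching rate constant kq = Ksv / tau0.  Comparing
the temperature trend of Ksv and the magnitude of kq against the
diffusion-controlled collisional limit (~2e10 dm3 mol-1 s-1) classifies
the quenching mechanism as static (ground-state complex) or dynamic
(collisional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InsufficientDataError, ValidationError

#: Default unquenched fluorophore lifetime, s.  A standard value for
#: intrinsic biomolecule (tryptophan) fluorescence; it is the value
#: consistent with Ksv ~ 1e5 dm3/mol giving kq ~ 1e13 dm3 mol-1 s-1.
DEFAULT_TAU0 = 1e-8

#: Maximum diffusion-controlled collisional quenching rate constant,
#: dm3 mol-1 s-1.  kq above this bound implies static quenching.
DEFAULT_KQ_MAX = 2e10


def inner_filter_correct(f_obs, a_ex, a_em):
    """Correct observed intensities for the inner-filter effect.

    Parameters are scalars or arrays: observed intensity (a.u.) and the
    absorbances at the excitation and emission wavelengths.  Returns
    ``F_obs * 10**((A_ex + A_em) / 2)``, which is >= F_obs with equality
    iff both absorbances vanish.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(f_obs <= 0):
        raise ValidationError("observed intensities must be positive")
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValidationError("absorbances must be non-negative")
    out = f_obs * 10.0 ** ((a_ex + a_em) / 2.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: quencher concentration (mol/dm3), observed
    intensity (a.u.), absorbances at the excitation/emission wavelengths,
    and optionally the emission-maximum wavelength (nm)."""

    q: float
    f_obs: float
    a_ex: float = 0.0
    a_em: float = 0.0
    lambda_max: float | None = None

    def __post_init__(self):
        if self.q < 0:
            raise ValidationError(f"quencher concentration {self.q} < 0")
        if self.f_obs <= 0:
            raise ValidationError(f"intensity {self.f_obs} <= 0")
        if self.a_ex < 0 or self.a_em < 0:
            raise ValidationError("absorbances must be non-negative")


@dataclass(frozen=True)
class TitrationSeries:
    """One protein–ligand titration at a single temperature.

    The first point must be the quencher-free reference (Q = 0) and Q
    must be strictly increasing.  ``f0`` is the inner-filter-corrected
    intensity at Q = 0 (equal to the observed one, since A(0) = 0 for a
    quencher-borne absorbance).
    """

    points: tuple[TitrationPoint, ...]
    temperature: float

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (K)")
        if not self.points or self.points[0].q != 0.0:
            raise ValidationError("series must start with a Q = 0 reference point")
        q = self.q
        if sum(1 for v in q if v == 0.0) != 1:
            raise ValidationError("series must contain exactly one Q = 0 point")
        if np.any(np.diff(q) <= 0):
            raise ValidationError("quencher concentrations must be strictly increasing")

    @property
    def q(self) -> np.ndarray:
        return np.array([p.q for p in self.points])

    @property
    def f_obs(self) -> np.ndarray:
        return np.array([p.f_obs for p in self.points])

    @property
    def f_corr(self) -> np.ndarray:
        return inner_filter_correct(
            self.f_obs,
            np.array([p.a_ex for p in self.points]),
            np.array([p.a_em for p in self.points]),
        )

    @property
    def f0(self) -> float:
        return float(self.f_corr[0])

    @property
    def wavelengths(self) -> np.ndarray | None:
        lam = [p.lambda_max for p in self.points]
        if any(v is None for v in lam):
            return None
        return np.array(lam, dtype=float)


class SternVolmerRegression(RegressorMixin, BaseEstimator):
    """Ordinary least-squares Stern–Volmer fit, F0/F = 1 + Ksv [Q].

    scikit-learn style: ``fit(X, y)`` with X the quencher concentrations
    (mol/dm3, shape (n,) or (n, 1)) and y the corrected intensity ratio
    F0/F.  The intercept is left free (ideally ~1); a drift
    ``|intercept - 1| > 0.1`` is recorded as a quality warning.

    Parameters
    ----------
    tau0 : float
        Unquenched fluorophore lifetime in seconds, used to derive the
        quenching rate constant ``kq_ = ksv_ / tau0``.

    Attributes
    ----------
    ksv_ : float          Stern–Volmer constant, dm3/mol (the slope).
    intercept_ : float    Fitted intercept (dimensionless).
    r2_ : float           Coefficient of determination.
    kq_ : float           Quenching rate constant, dm3 mol-1 s-1.
    warnings_ : tuple[str, ...]
    """

    def __init__(self, tau0: float = DEFAULT_TAU0):
        self.tau0 = tau0

    def fit(self, X, y):
        q = np.asarray(X, dtype=float).reshape(-1)
        ratio = np.asarray(y, dtype=float).reshape(-1)
        if q.shape != ratio.shape:
            raise ValidationError("X and y must have matching lengths")
        if q.size < 3:
            raise InsufficientDataError(
                f"Stern–Volmer fit needs >= 3 points, got {q.size}"
            )
        if np.any(ratio <= 0):
            raise ValidationError("intensity ratios must be positive")
        if self.tau0 <= 0:
            raise ValidationError("tau0 must be positive")
        if np.allclose(ratio, ratio[0]):
            # flat series: no quenching; slope 0 by construction
            slope, intercept, r2 = 0.0, float(ratio[0]), 1.0
        else:
            res = stats.linregress(q, ratio)
            slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
        self.ksv_ = slope
        self.intercept_ = intercept
        self.r2_ = r2
        self.kq_ = slope / self.tau0
        warns = []
        if abs(intercept - 1.0) > 0.1:
            warns.append(
                f"Stern–Volmer intercept {intercept:.3f} deviates from 1 by > 0.1"
            )
        self.warnings_ = tuple(warns)
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.ksv_ * q


@dataclass(frozen=True)
class QuenchingFit:
    """Result of a Stern–Volmer analysis at one temperature."""

    ksv: float
    intercept: float
    r2: float
    kq: float
    tau0: float
    temperature: float
    warnings: tuple[str, ...] = field(default_factory=tuple)


def fit_stern_volmer(series: TitrationSeries, tau0: float = DEFAULT_TAU0) -> QuenchingFit:
    """Fit the Stern–Volmer law to an inner-filter-corrected titration."""
    f = series.f_corr
    est = SternVolmerRegression(tau0=tau0).fit(series.q, series.f0 / f)
    return QuenchingFit(
        ksv=est.ksv_,
        intercept=est.intercept_,
        r2=est.r2_,
        kq=est.kq_,
        tau0=tau0,
        temperature=series.temperature,
        warnings=est.warnings_,
    )


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism verdict with a human-readable rationale."""

    mechanism: str  # static | dynamic | ambiguous | indeterminate
    rationale: str


def classify_mechanism(
    fits: Iterable[QuenchingFit],
    kq_max: float = DEFAULT_KQ_MAX,
    rel_tol: float = 1e-3,
) -> MechanismCall:
    """Classify quenching as static or dynamic from multi-temperature fits.

    Static quenching (ground-state complex): Ksv strictly decreasing with
    temperature AND every kq above the collisional maximum ``kq_max``.
    Dynamic (collisional): Ksv strictly increasing AND every kq at or
    below the maximum.  Any other pattern is ambiguous, with the failing
    criterion named.  Monotonicity uses a relative tolerance ``rel_tol``
    to absorb floating-point noise; the verdict is invariant to a common
    rescaling of all intensities (Ksv is scale-free).
    """
    fits = sorted(fits, key=lambda f: f.temperature)
    if len(fits) < 2:
        return MechanismCall(
            "indeterminate", "single temperature: no temperature trend available"
        )
    ksv = np.array([f.ksv for f in fits])
    kq = np.array([f.kq for f in fits])
    decreasing = bool(np.all(ksv[1:] < ksv[:-1] * (1 - rel_tol)))
    increasing = bool(np.all(ksv[1:] > ksv[:-1] * (1 + rel_tol)))
    all_fast = bool(np.all(kq > kq_max))
    all_slow = bool(np.all(kq <= kq_max))

    if decreasing and all_fast:
        return MechanismCall(
            "static",
            f"Ksv decreases with temperature and all kq > {kq_max:.2g} "
            "dm3 mol-1 s-1: ground-state complex formation",
        )
    if increasing and all_slow:
        return MechanismCall(
            "dynamic",
            f"Ksv increases with temperature and all kq <= {kq_max:.2g} "
            "dm3 mol-1 s-1: collisional quenching",
        )
    reasons = []
    if not (decreasing or increasing):
        reasons.append("Ksv is not monotone in temperature")
    elif decreasing and not all_fast:
        reasons.append(f"Ksv decreases but some kq <= {kq_max:.2g}")
    elif increasing and not all_slow:
        reasons.append(f"Ksv increases but some kq > {kq_max:.2g}")
    return MechanismCall("ambiguous", "; ".join(reasons))


def peak_shift(series: TitrationSeries) -> float | None:
    """Signed emission-maximum shift over the titration, nm.

    Negative values are a blue shift (toward shorter wavelengths,
    indicating a less polar chromophore environment).  Returns ``None``
    when wavelengths were not recorded.
    """
    lam = series.wavelengths
    if lam is None:
        return None
    return float(lam[-1] - lam[0])
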