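"""van't Hoff analysis and interaction-force classification.

The temperature dependence of the binding constant gives the standard
enthalpy and entropy of complex formation via the van't Hoff relation

    ln Kb = -dH/(R T) + dS/R

(an OLS line of ln Kb against 1/T), and the Gibbs energy follows from
either form of

    dG = dH - T dS = -R T ln Kb.

The signs of dH and dS classify the dominant intermolecular forces
(Ross–Subramanian criteria): both negative -> van der Waals forces and
hydrogen bonding; both positive -> hydrophobic contacts; dH near zero
with dS > 0 -> electrostatic interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InsufficientDataError, ValidationError

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314

#: |dH| below which the enthalpy counts as "near zero", J/mol.
DEFAULT_NEAR_ZERO_TOL = 5000.0


class VantHoffModel(RegressorMixin, BaseEstimator):
    """OLS van't Hoff fit of ln Kb against 1/T.

    ``fit(X, y)`` takes X = absolute temperatures (K) and y = binding
    constants (dm3/mol, > 0).

    Parameters
    ----------
    log_base : {"e", "10"}
        "e" (default) is the standard, dimensionally consistent van't
        Hoff form.  "10" is a strict as-printed audit mode in which the
        decadic log replaces ln in the regression (slope and intercept
        are still multiplied by -R and R respectively).

    Attributes
    ----------
    dh_ : float    Standard enthalpy change, J/mol (-slope * R).
    ds_ : float    Standard entropy change, J mol-1 K-1 (intercept * R).
    r2_ : float    Coefficient of determination.
    """

    def __init__(self, log_base: str = "e"):
        self.log_base = log_base

    def _log(self, x):
        return np.log(x) if self.log_base == "e" else np.log10(x)

    def fit(self, X, y):
        if self.log_base not in ("e", "10"):
            raise ValidationError("log_base must be 'e' or '10'")
        t = np.asarray(X, dtype=float).reshape(-1)
        kb = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != kb.shape:
            raise ValidationError("X and y must have matching lengths")
        if np.any(t <= 0):
            raise ValidationError("temperatures must be positive (K)")
        if np.any(kb <= 0):
            raise ValidationError("binding constants must be positive")
        if np.unique(t).size < 2:
            raise InsufficientDataError("van't Hoff fit needs >= 2 distinct temperatures")
        x = 1.0 / t
        ly = self._log(kb)
        if t.size == 2:
            slope = (ly[1] - ly[0]) / (x[1] - x[0])
            intercept = ly[0] - slope * x[0]
            r2 = 1.0
        else:
            res = stats.linregress(x, ly)
            slope, intercept = float(res.slope), float(res.intercept)
            r2 = 1.0 if np.allclose(ly, ly[0]) else float(res.rvalue**2)
        self.dh_ = -slope * R_GAS
        self.ds_ = intercept * R_GAS
        self.r2_ = r2
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        exponent = -self.dh_ / (R_GAS * t) + self.ds_ / R_GAS
        return np.exp(exponent) if self.log_base == "e" else 10.0**exponent


def fit_vant_hoff(
    kb_by_t: Mapping[float, float], log_base: str = "e"
) -> tuple[float, float, float]:
    """Fit (dH, dS, r2) from a temperature -> Kb mapping."""
    temps = sorted(kb_by_t)
    est = VantHoffModel(log_base=log_base).fit(temps, [kb_by_t[t] for t in temps])
    return est.dh_, est.ds_, est.r2_


def gibbs_from_k(kb: float, t: float) -> float:
    """Gibbs energy change dG = -R T ln Kb, J/mol."""
    if kb <= 0:
        raise ValidationError("binding constant must be positive")
    if t <= 0:
        raise ValidationError("temperature must be positive (K)")
    return -R_GAS * t * math.log(kb)


def classify_forces(
    dh: float, ds: float, near_zero_tol: float = DEFAULT_NEAR_ZERO_TOL
) -> str:
    """Ross–Subramanian force classification from the signs of dH and dS.

    The near-zero enthalpy test is evaluated first.  Returns one of
    ``electrostatic``, ``vdW_hbond``, ``hydrophobic``, ``unclassified``.
    """
    if abs(dh) < near_zero_tol and ds > 0:
        return "electrostatic"
    if dh < 0 and ds < 0:
        return "vdW_hbond"
    if dh > 0 and ds > 0:
        return "hydrophobic"
    return "unclassified"


@dataclass(frozen=True)
class ThermoFit:
    """van't Hoff result: dH (J/mol), dS (J mol-1 K-1), per-temperature
    Gibbs energies dG = dH - T dS (J/mol), spontaneity flags (dG < 0),
    and the force classification."""

    dh: float
    ds: float
    r2: float
    dg_by_t: dict[float, float]
    spontaneous: dict[float, bool]
    force_class: str


def analyze_thermodynamics(
    kb_by_t: Mapping[float, float],
    near_zero_tol: float = DEFAULT_NEAR_ZERO_TOL,
    log_base: str = "e",
) -> ThermoFit:
    """Full thermodynamic analysis of a temperature -> Kb mapping."""
    dh, ds, r2 = fit_vant_hoff(kb_by_t, log_base=log_base)
    dg_by_t = {t: dh - t * ds for t in sorted(kb_by_t)}
    return ThermoFit(
        dh=dh,
        ds=ds,
        r2=r2,
        dg_by_t=dg_by_t,
        spontaneous={t: dg < 0 for t, dg in dg_by_t.items()},
        force_class=classify_forces(dh, ds, near_zero_tol),
    )
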