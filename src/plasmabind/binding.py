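"""Binding constant and stoichiometry from the double-logarithm plot.

For static quenching by complex formation, the corrected intensities obey

    log10((F0 - F) / F) = log10(Kb) + n * log10([Q])

so an ordinary least-squares line through (log10 [Q], log10((F0-F)/F))
yields the binding constant Kb (10^intercept, dm3/mol) and the apparent
number of binding sites n (slope).  The Q = 0 reference point is excluded
(its logarithm is undefined), as is any point with F >= F0 (no net
quenching; log of a non-positive number).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InsufficientDataError, ValidationError
from .quenching import TitrationSeries

#: |n - 1| beyond which the fit is flagged as deviating from 1:1 binding.
STOICHIOMETRY_TOL = 0.2


class DoubleLogBindingModel(RegressorMixin, BaseEstimator):
    """OLS fit of the double-logarithm binding law.

    ``fit(X, y)`` takes X = quencher concentrations (> 0, mol/dm3) and
    y = (F0 - F)/F quenching ratios (> 0).  Both are log10-transformed
    and fitted linearly; results are invariant to the logarithm base.

    Attributes
    ----------
    kb_ : float    Binding constant, dm3/mol (10^intercept).
    n_ : float     Apparent binding-site number (slope).
    r2_ : float    Coefficient of determination in log–log space.
    """

    def fit(self, X, y):
        q = np.asarray(X, dtype=float).reshape(-1)
        ratio = np.asarray(y, dtype=float).reshape(-1)
        if q.shape != ratio.shape:
            raise ValidationError("X and y must have matching lengths")
        if np.any(q <= 0):
            raise ValidationError("quencher concentrations must be > 0 for the log fit")
        if np.any(ratio <= 0):
            raise ValidationError("(F0 - F)/F must be > 0 for the log fit")
        if q.size < 3:
            raise InsufficientDataError(
                f"double-log fit needs >= 3 usable points, got {q.size}"
            )
        res = stats.linregress(np.log10(q), np.log10(ratio))
        self.kb_ = float(10.0 ** res.intercept)
        self.n_ = float(res.slope)
        self.r2_ = float(res.rvalue**2)
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).reshape(-1)
        return self.kb_ * q**self.n_


@dataclass(frozen=True)
class BindingFit:
    """Result of the double-log binding analysis at one temperature."""

    kb: float
    n: float
    r2: float
    temperature: float
    points_used: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


def fit_double_log(series: TitrationSeries) -> BindingFit:
    """Fit Kb and n to an inner-filter-corrected titration series.

    Points with F >= F0 at Q > 0 are excluded with a warning; fewer than
    three usable points raises :class:`InsufficientDataError`.  A fitted
    stoichiometry with |n - 1| > 0.2 is flagged as non-1:1.
    """
    f = series.f_corr
    f0 = series.f0
    q = series.q
    warns: list[str] = []

    usable = (q > 0) & (f < f0)
    excluded = np.flatnonzero((q > 0) & (f >= f0))
    if excluded.size:
        warns.append(
            f"excluded {excluded.size} point(s) with F >= F0 at Q > 0 "
            f"(indices {excluded.tolist()})"
        )
    q_use, f_use = q[usable], f[usable]
    if q_use.size < 3:
        raise InsufficientDataError(
            f"double-log fit needs >= 3 usable points, got {q_use.size}"
        )
    est = DoubleLogBindingModel().fit(q_use, (f0 - f_use) / f_use)
    if abs(est.n_ - 1.0) > STOICHIOMETRY_TOL:
        warns.append(
            f"stoichiometry n = {est.n_:.3f} deviates from 1 by more than "
            f"{STOICHIOMETRY_TOL}: binding may not be 1:1"
        )
    return BindingFit(
        kb=est.kb_,
        n=est.n_,
        r2=est.r2_,
        temperature=series.temperature,
        points_used=int(q_use.size),
        warnings=tuple(warns),
    )
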