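"""Inner-filter correction, Stern–Volmer fitting, mechanism calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmabind import (
    GroundTruth,
    QuenchingFit,
    SternVolmerRegression,
    TitrationDesign,
    TitrationPoint,
    TitrationSeries,
    classify_mechanism,
    fit_stern_volmer,
    generate_collisional_titration,
    generate_titration,
    inner_filter_correct,
    peak_shift,
)
from plasmabind.errors import InsufficientDataError, ValidationError


class TestInnerFilter:
    @pytest.mark.parametrize(
        "f_obs,a_ex,a_em,expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (100.0, 0.05, 0.03, 109.6478),  # 100 * 10**0.04
            (50.0, 1.0, 1.0, 500.0),
        ],
    )
    def test_values(self, f_obs, a_ex, a_em, expected):
        assert inner_filter_correct(f_obs, a_ex, a_em) == pytest.approx(
            expected, abs=1e-4
        )

    def test_rejects_negative_absorbance_and_nonpositive_intensity(self):
        with pytest.raises(ValidationError):
            inner_filter_correct(100.0, -0.1, 0.0)
        with pytest.raises(ValidationError):
            inner_filter_correct(0.0, 0.1, 0.1)

    @settings(derandomize=True, max_examples=100)
    @given(
        f=st.floats(1e-3, 1e6),
        a1=st.floats(0, 2),
        a2=st.floats(0, 2),
        da=st.floats(1e-6, 1),
    )
    def test_monotone_and_multiplicative(self, f, a1, a2, da):
        """Correction grows strictly with total absorbance and its factor
        does not depend on the observed intensity."""
        base = inner_filter_correct(f, a1, a2)
        assert base >= f
        assert inner_filter_correct(f, a1 + da, a2) > base
        factor = base / f
        assert inner_filter_correct(1.0, a1, a2) == pytest.approx(factor, rel=1e-12)


class TestSternVolmer:
    def test_exact_recovery_on_noiseless_static_data(self):
        truth = GroundTruth(kb_ref=1e5, n=1.0)
        series = generate_titration(TitrationDesign(temperatures=(297.0,)), truth)[0]
        fit = fit_stern_volmer(series, tau0=1e-8)
        assert fit.ksv == pytest.approx(1e5, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert fit.kq == pytest.approx(1e13, rel=1e-9)
        assert fit.warnings == ()

    def test_flat_series_has_zero_slope(self):
        points = tuple(
            TitrationPoint(q=q, f_obs=500.0) for q in (0.0, 1e-6, 2e-6, 3e-6)
        )
        fit = fit_stern_volmer(TitrationSeries(points=points, temperature=297.0))
        assert fit.ksv == 0.0

    def test_estimator_requires_three_points(self):
        with pytest.raises(InsufficientDataError):
            SternVolmerRegression().fit([0.0, 1e-6], [1.0, 1.1])

    def test_intercept_drift_warning(self):
        est = SternVolmerRegression().fit(
            [0.0, 1e-6, 2e-6], np.array([1.3, 1.4, 1.5])
        )
        assert any("intercept" in w for w in est.warnings_)

    def test_series_validation(self):
        with pytest.raises(ValidationError):
            TitrationSeries(
                points=(TitrationPoint(q=1e-6, f_obs=1.0),), temperature=297.0
            )  # no Q = 0 reference
        with pytest.raises(ValidationError):
            TitrationSeries(
                points=(
                    TitrationPoint(q=0.0, f_obs=1.0),
                    TitrationPoint(q=2e-6, f_obs=0.9),
                    TitrationPoint(q=1e-6, f_obs=0.8),
                ),
                temperature=297.0,
            )  # not increasing


class TestMechanism:
    @staticmethod
    def _fit(ksv, t, tau0=1e-8):
        return QuenchingFit(
            ksv=ksv, intercept=1.0, r2=1.0, kq=ksv / tau0, tau0=tau0, temperature=t
        )

    def test_static_call(self):
        fits = [self._fit(k, t) for k, t in zip((1.1e5, 1.0e5, 0.9e5), (297, 303, 308))]
        assert classify_mechanism(fits).mechanism == "static"

    def test_dynamic_call(self):
        fits = [
            self._fit(k, t, tau0=1e-3)
            for k, t in zip((0.9e3, 1.0e3, 1.1e3), (297, 303, 308))
        ]
        assert classify_mechanism(fits).mechanism == "dynamic"

    def test_non_monotone_is_ambiguous_with_named_reason(self):
        fits = [self._fit(k, t) for k, t in zip((1.0e5, 1.2e5, 0.9e5), (297, 303, 308))]
        call = classify_mechanism(fits)
        assert call.mechanism == "ambiguous"
        assert "monotone" in call.rationale

    def test_decreasing_but_slow_kq_is_ambiguous(self):
        fits = [
            self._fit(k, t, tau0=1.0)
            for k, t in zip((1.1e3, 1.0e3, 0.9e3), (297, 303, 308))
        ]
        assert classify_mechanism(fits).mechanism == "ambiguous"

    def test_single_temperature_indeterminate(self):
        assert classify_mechanism([self._fit(1e5, 297)]).mechanism == "indeterminate"

    def test_invariant_to_common_intensity_rescaling(self):
        truth = GroundTruth.from_kb_and_enthalpy(kb_ref=1e5, dh=-60e3)
        series = generate_titration(TitrationDesign(), truth)
        scaled = [
            TitrationSeries(
                points=tuple(
                    TitrationPoint(q=p.q, f_obs=7.3 * p.f_obs, a_ex=p.a_ex, a_em=p.a_em)
                    for p in s.points
                ),
                temperature=s.temperature,
            )
            for s in series
        ]
        call_a = classify_mechanism([fit_stern_volmer(s) for s in series])
        call_b = classify_mechanism([fit_stern_volmer(s) for s in scaled])
        assert call_a.mechanism == call_b.mechanism == "static"

    def test_collisional_fixture_classifies_dynamic(self):
        design = TitrationDesign(temperatures=(297.0, 303.0, 308.0))
        series = generate_collisional_titration(
            design, {297.0: 0.9e3, 303.0: 1.0e3, 308.0: 1.1e3}
        )
        fits = [fit_stern_volmer(s, tau0=1e-3) for s in series]
        assert classify_mechanism(fits).mechanism == "dynamic"


class TestPeakShift:
    @staticmethod
    def _series(lams):
        points = tuple(
            TitrationPoint(q=i * 1e-6, f_obs=100.0 - i, lambda_max=lam)
            for i, lam in enumerate(lams)
        )
        return TitrationSeries(points=points, temperature=297.0)

    def test_blue_red_and_zero_shift(self):
        assert peak_shift(self._series([343, 341, 339])) == pytest.approx(-4.0)
        assert peak_shift(self._series([340, 340, 340])) == pytest.approx(0.0)
        assert peak_shift(self._series([340, 342, 345])) == pytest.approx(+5.0)

    def test_missing_wavelengths_skipped(self):
        s = self._series([343, None, 339])
        assert peak_shift(s) is None
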