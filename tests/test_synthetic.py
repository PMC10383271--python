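"""The generator produces exactly the structure the analysis assumes."""

import numpy as np
import pytest

from plasmabind import (
    GroundTruth,
    TitrationDesign,
    generate_cd,
    generate_collisional_titration,
    generate_displacement,
    generate_titration,
)
from plasmabind.cd import structural_basis
from plasmabind.errors import ConfigurationError, ValidationError


class TestTitrationGenerator:
    def test_noiseless_static_data_is_exactly_linear_in_stern_volmer_form(self):
        truth = GroundTruth(kb_ref=1e5, n=1.0)
        series = generate_titration(TitrationDesign(temperatures=(297.0,)), truth)[0]
        q = series.q
        ratio = series.f0 / series.f_corr
        slope = np.polyfit(q, ratio, 1)[0]
        assert slope == pytest.approx(1e5, rel=1e-9)
        # six grid points: ratios 0, 0.4 .. 2.0 times 1e-6 M protein
        assert len(series.points) == 6
        assert q[-1] == pytest.approx(2e-6)

    def test_exothermic_truth_gives_decreasing_kb_with_temperature(self):
        truth = GroundTruth.from_kb_and_enthalpy(kb_ref=1e5, dh=-50e3)
        assert truth.kb_at(297.0) == pytest.approx(1e5, rel=1e-12)
        assert truth.kb_at(303.0) < truth.kb_at(297.0)
        assert truth.kb_at(308.0) < truth.kb_at(303.0)

    def test_seed_determinism(self):
        truth = GroundTruth(kb_ref=1e5)
        d1 = TitrationDesign(noise_rel=0.01, seed=7)
        a = generate_titration(d1, truth)
        b = generate_titration(d1, truth)
        c = generate_titration(TitrationDesign(noise_rel=0.01, seed=8), truth)
        assert all(
            np.array_equal(x.f_obs, y.f_obs) for x, y in zip(a, b)
        )
        assert not np.array_equal(a[0].f_obs, c[0].f_obs)

    def test_inner_filter_attenuation_applied_to_observed_only(self):
        design = TitrationDesign(eps_ex=2e4, eps_em=1e4, temperatures=(297.0,))
        truth = GroundTruth(kb_ref=1e5)
        series = generate_titration(design, truth)[0]
        clean = generate_titration(
            TitrationDesign(temperatures=(297.0,)), truth
        )[0]
        # F(0) = F0: no attenuation at zero quencher
        assert series.f_obs[0] == pytest.approx(clean.f_obs[0])
        assert np.all(series.f_obs[1:] < clean.f_obs[1:])
        # correcting the observed intensities recovers the clean series
        assert series.f_corr == pytest.approx(clean.f_corr, rel=1e-12)

    def test_intensities_positive_even_with_noise(self):
        truth = GroundTruth(kb_ref=1e7)
        series = generate_titration(TitrationDesign(noise_rel=0.05, seed=3), truth)
        for s in series:
            assert np.all(s.f_obs > 0)

    def test_truth_requires_kb_or_enthalpy_pair(self):
        with pytest.raises(ConfigurationError):
            GroundTruth()
        with pytest.raises(ConfigurationError):
            GroundTruth(kb_ref=1e5, dh=-10e3)  # ds missing

    def test_collisional_variant_follows_linear_law(self):
        design = TitrationDesign(temperatures=(297.0, 303.0))
        series = generate_collisional_titration(
            design, {297.0: 1e3, 303.0: 1.2e3}
        )
        s = series[1]
        slope = np.polyfit(s.q, s.f0 / s.f_corr, 1)[0]
        assert slope == pytest.approx(1.2e3, rel=1e-9)


class TestDisplacementGenerator:
    def test_zero_strength_is_flat(self):
        s = generate_displacement("DanG", 0.0)
        assert np.allclose(s.f, s.f0)

    def test_plateau_approaches_strength(self):
        s = generate_displacement("DanF", 0.6, ratios=(0.0, 1.0, 10.0, 1e6))
        assert (s.f0 - s.f[-1]) / s.f0 == pytest.approx(0.6, abs=1e-5)

    def test_default_ratio_ladders(self):
        assert len(generate_displacement("DanG", 0.3).ratios) == 8
        assert len(generate_displacement("DanF", 0.3).ratios) == 8
        qr = generate_displacement("QR", 0.3)
        assert len(qr.ratios) == 9
        assert 6.0 in qr.ratios and 8.0 in qr.ratios

    def test_overlarge_strength_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            s = generate_displacement("QR", 1.4, ratios=(0.0, 1e9))
        assert s.f[-1] >= 0.0


class TestCDGenerator:
    def test_pure_component_reproduces_basis_row(self):
        spec = generate_cd((1.0, 0.0, 0.0))
        assert np.allclose(spec.ellipticity, structural_basis(spec.wavelengths)[0])

    def test_fraction_validation(self):
        with pytest.raises(ValidationError):
            generate_cd((0.5, 0.5, 0.5))
        with pytest.raises(ValidationError):
            generate_cd((1.2, -0.2, 0.0))
        with pytest.raises(ValidationError):
            generate_cd((0.3, 0.3, 0.4), wavelengths=[190.0, 210.0, 240.0])

    def test_helix_rich_spectrum_has_minima_near_209_and_222(self):
        spec = generate_cd((0.6, 0.1, 0.3))
        wl, el = spec.wavelengths, spec.ellipticity
        lo = (wl >= 205) & (wl <= 214)
        hi = (wl >= 217) & (wl <= 228)
        assert abs(wl[lo][np.argmin(el[lo])] - 209.0) <= 2.0
        assert abs(wl[hi][np.argmin(el[hi])] - 222.0) <= 2.0

    def test_noise_seeded(self):
        a = generate_cd((0.2, 0.3, 0.5), noise_rel=0.02, seed=11)
        b = generate_cd((0.2, 0.3, 0.5), noise_rel=0.02, seed=11)
        c = generate_cd((0.2, 0.3, 0.5), noise_rel=0.02, seed=12)
        assert np.array_equal(a.ellipticity, b.ellipticity)
        assert not np.array_equal(a.ellipticity, c.ellipticity)
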