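"""CD conversion and constrained secondary-structure decomposition."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmabind import (
    CDSpectrum,
    SecondaryStructureDecomposer,
    estimate_fractions,
    fraction_change,
    generate_cd,
    structural_basis,
    to_mean_residue_ellipticity,
)
from plasmabind.cd import from_mean_residue_ellipticity
from plasmabind.errors import ConditioningError, ValidationError

WL = np.arange(205.0, 250.5, 0.5)


def _spec(ellipticity, **kw):
    return CDSpectrum(wavelengths=WL, ellipticity=ellipticity, **kw)


class TestMeanResidueEllipticity:
    def test_linearity_in_concentration(self):
        spec = generate_cd((0.6, 0.1, 0.3), residue_conc=2e-4)
        half = to_mean_residue_ellipticity(spec)
        double = to_mean_residue_ellipticity(
            _spec(spec.ellipticity, residue_conc=4e-4)
        )
        assert np.allclose(half.ellipticity, 2.0 * double.ellipticity)

    def test_zero_maps_to_zero(self):
        spec = _spec(np.zeros_like(WL), residue_conc=1e-4)
        assert np.all(to_mean_residue_ellipticity(spec).ellipticity == 0.0)

    def test_round_trip(self):
        spec = generate_cd((0.2, 0.3, 0.5), residue_conc=3.3e-4)
        back = from_mean_residue_ellipticity(to_mean_residue_ellipticity(spec))
        assert np.allclose(back.ellipticity, spec.ellipticity, atol=1e-12)

    def test_missing_concentration_rejected(self):
        with pytest.raises(ValidationError):
            to_mean_residue_ellipticity(generate_cd((0.2, 0.3, 0.5)))


def _grid_search_oracle(basis, y, step=0.01):
    """Exhaustive simplex search at fixed resolution (independent check
    of the active-set solver)."""
    best, best_res = None, np.inf
    grid = np.arange(0.0, 1.0 + step / 2, step)
    for fa, fb in itertools.product(grid, grid):
        if fa + fb > 1.0 + 1e-12:
            continue
        f = np.array([fa, fb, 1.0 - fa - fb])
        res = np.linalg.norm(basis.T @ f - y)
        if res < best_res:
            best, best_res = f, res
    return best, best_res


class TestDecomposition:
    @pytest.mark.parametrize("component", [0, 1, 2])
    def test_pure_components(self, component):
        fractions = [0.0, 0.0, 0.0]
        fractions[component] = 1.0
        got = estimate_fractions(generate_cd(tuple(fractions)))
        assert got.fractions[component] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "fractions",
        [(0.2, 0.3, 0.5), (0.6, 0.1, 0.3), (0.2, 0.3, 0.5), (0.0, 0.5, 0.5)],
    )
    def test_exact_recovery_of_noiseless_mixtures(self, fractions):
        got = estimate_fractions(generate_cd(fractions))
        assert got.fractions == pytest.approx(np.array(fractions), abs=1e-6)
        assert got.residual_norm < 1e-9

    def test_aag_like_composition(self):
        """A sheet-rich glycoprotein-like mixture (30% beta, 20% alpha)
        is recovered exactly."""
        got = estimate_fractions(generate_cd((0.20, 0.30, 0.50)))
        assert got.f_beta == pytest.approx(0.30, abs=1e-6)
        assert got.f_alpha == pytest.approx(0.20, abs=1e-6)

    def test_matches_grid_search_oracle_on_noisy_input(self):
        rng = np.random.default_rng(5)
        basis = structural_basis(WL)
        y = np.array([0.5, 0.2, 0.3]) @ basis + rng.normal(0, 0.4, WL.size)
        f = SecondaryStructureDecomposer(basis=basis).fit().transform(y)[0]
        f_oracle, res_oracle = _grid_search_oracle(basis, y)
        # the exact solver can only do better than the 0.01-resolution grid
        assert np.linalg.norm(basis.T @ f - y) <= res_oracle + 1e-12
        # and must land within one grid cell of the oracle's optimum
        assert f == pytest.approx(f_oracle, abs=0.02)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_simplex_constraints_hold_on_arbitrary_input(self, seed):
        """Even pure-noise spectra decompose to fractions on the simplex."""
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 5.0, WL.size)
        f = SecondaryStructureDecomposer(basis=structural_basis(WL)).fit().transform(y)[0]
        assert np.all(f >= 0.0)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_collinear_basis_rejected(self):
        b = structural_basis(WL)
        bad = np.vstack([b[0], 2.0 * b[0], b[2]])
        with pytest.raises(ConditioningError):
            SecondaryStructureDecomposer(basis=bad).fit()

    def test_external_basis_resampled_onto_spectrum_grid(self):
        coarse_wl = np.arange(205.0, 251.0, 2.0)
        got = estimate_fractions(
            generate_cd((0.25, 0.25, 0.5)),
            basis=structural_basis(coarse_wl),
            basis_wavelengths=coarse_wl,
        )
        # linear resampling of a 2 nm tabulation of smooth bands
        assert got.fractions == pytest.approx([0.25, 0.25, 0.5], abs=0.02)


class TestFractionChange:
    def test_identical_structures(self):
        s = estimate_fractions(generate_cd((0.6, 0.1, 0.3)))
        change = fraction_change(s, s)
        assert all(v == 0.0 for v in change.deltas_pp.values())
        assert change.verdict == "not destabilized"

    def test_small_helix_loss_not_destabilizing(self):
        before = estimate_fractions(generate_cd((0.600, 0.100, 0.300)))
        after = estimate_fractions(generate_cd((0.576, 0.100, 0.324)))
        change = fraction_change(before, after)
        assert change.deltas_pp["alpha"] == pytest.approx(-2.4, abs=1e-6)
        assert not change.destabilized

    def test_large_helix_loss_flags_destabilization(self):
        before = estimate_fractions(generate_cd((0.60, 0.10, 0.30)))
        after = estimate_fractions(generate_cd((0.50, 0.10, 0.40)))
        assert fraction_change(before, after).destabilized

    def test_helix_loss_with_fixed_coil_appears_as_sheet_gain(self):
        """On a two-component change the alpha loss equals the beta gain."""
        before = estimate_fractions(generate_cd((0.20, 0.30, 0.50)))
        after = estimate_fractions(generate_cd((0.18, 0.32, 0.50)))
        change = fraction_change(before, after)
        assert change.deltas_pp["alpha"] == pytest.approx(-2.0, abs=1e-6)
        assert change.deltas_pp["beta"] == pytest.approx(+2.0, abs=1e-6)
        assert change.deltas_pp["coil"] == pytest.approx(0.0, abs=1e-6)
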