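"""Densities, closed-form peak-to-trough ratios, and circular statistics."""

import math

import numpy as np
import pytest

from repliptr.distributions import (
    TWO_PI,
    DistributionSpec,
    ParameterSet,
    concentration_for_pptr,
    log_pdf,
    mean_resultant_length,
    pdf,
    pptr,
    rho_from_kappa,
)
from repliptr.errors import (
    EmptyInputError,
    InvalidParameterError,
    UnsupportedFamilyError,
)
from repliptr.transforms import simpson_integrate

from conftest import ALL_FAMILIES, FAMILY_CONC, random_params

GRID = np.linspace(0.0, TWO_PI, 100_001)[:-1]


class TestLogPdf:
    def test_von_mises_uniform_limit(self):
        spec = DistributionSpec("von_mises")
        p = ParameterSet(mu=1.0, concentration=0.0)
        assert log_pdf(spec, 1.0, p) == pytest.approx(math.log(1 / TWO_PI), abs=1e-12)

    def test_cardioid_mode_value(self):
        # density at the mode for the rho printed alongside pPTR = 2
        spec = DistributionSpec("cardioid")
        p = ParameterSet(mu=0.5, concentration=0.16666)
        expected = math.log((1 + 2 * 0.16666) / TWO_PI)
        assert log_pdf(spec, 0.5, p) == pytest.approx(expected, abs=1e-12)

    def test_von_mises_against_bessel_series(self):
        # independent I0(kappa) via its power series (40 terms)
        kappa = 1.0
        i0 = sum((kappa / 2) ** (2 * m) / math.factorial(m) ** 2 for m in range(40))
        expected = kappa * math.cos(math.pi / 3) - math.log(TWO_PI * i0)
        spec = DistributionSpec("von_mises")
        p = ParameterSet(mu=0.0, concentration=kappa)
        assert log_pdf(spec, math.pi / 3, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_normalization_simpson(self, family, rng):
        spec = DistributionSpec(family)
        for _ in range(8):
            params = random_params(family, rng)
            integral = simpson_integrate(
                lambda th: pdf(spec, th, params), n_subintervals=2000
            )
            assert integral == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_symmetry_about_mode(self, family, rng):
        spec = DistributionSpec(family)
        params = random_params(family, rng)
        delta = rng.uniform(0, math.pi, size=50)
        left = pdf(spec, params.mu - delta, params)
        right = pdf(spec, params.mu + delta, params)
        np.testing.assert_allclose(left, right, rtol=1e-10)

    def test_out_of_bounds_raises_named_bound(self):
        spec = DistributionSpec("cardioid")
        with pytest.raises(InvalidParameterError, match=r"0\.5"):
            log_pdf(spec, 0.0, ParameterSet(concentration=0.6))
        with pytest.raises(InvalidParameterError, match="kappa"):
            log_pdf(DistributionSpec("von_mises"), 0.0,
                    ParameterSet(concentration=-0.1))

    def test_jones_pewsey_reduces_to_von_mises(self):
        vm = DistributionSpec("von_mises")
        jp = DistributionSpec("jones_pewsey")
        for psi in (1e-3, 1e-4):
            pj = ParameterSet(mu=1.0, concentration=0.7, psi=psi)
            pv = ParameterSet(mu=1.0, concentration=0.7)
            diff = np.abs(pdf(jp, GRID[::10], pj) - pdf(vm, GRID[::10], pv))
            assert diff.max() < 1e-3

    def test_jones_pewsey_location_acts_like_other_families(self):
        # the kernel argument is theta - mu: shifting mu shifts the density
        spec = DistributionSpec("jones_pewsey")
        p0 = ParameterSet(mu=0.0, concentration=0.7, psi=0.5)
        p1 = ParameterSet(mu=1.0, concentration=0.7, psi=0.5)
        np.testing.assert_allclose(
            pdf(spec, GRID[:1000], p0), pdf(spec, GRID[:1000] + 1.0, p1), rtol=1e-10
        )


class TestPptr:
    @pytest.mark.parametrize("family,conc", [
        ("von_mises", 0.34657),
        ("cardioid", 0.16666),
        ("wrapped_cauchy", 0.17157),
        ("linear_cardioid", 0.1061),
    ])
    def test_printed_concentrations_give_two(self, family, conc):
        spec = DistributionSpec(family)
        assert pptr(spec, ParameterSet(concentration=conc)) == pytest.approx(
            2.0, abs=5e-4
        )

    def test_wrapped_cauchy_uniform(self):
        assert pptr(DistributionSpec("wrapped_cauchy"),
                    ParameterSet(concentration=0.0)) == 1.0

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_analytic_matches_grid_max_over_min(self, family, rng):
        spec = DistributionSpec(family)
        for _ in range(50):
            params = random_params(family, rng)
            # grid anchored at the mode so the kinked families hit their
            # exact extrema
            grid = params.mu + GRID
            dens = pdf(spec, grid, params)
            ratio = dens.max() / dens.min()
            assert ratio == pytest.approx(pptr(spec, params), rel=1e-4)

    def test_jones_pewsey_pptr_independent_of_psi(self):
        spec = DistributionSpec("jones_pewsey")
        for psi in (-0.5, 0.5, 1.0):
            params = ParameterSet(mu=0.0, concentration=0.6, psi=psi)
            dens = pdf(spec, GRID, params)
            assert dens.max() / dens.min() == pytest.approx(
                math.exp(2 * 0.6), rel=1e-4
            )

    def test_pole_raises(self):
        with pytest.raises(InvalidParameterError):
            pptr(DistributionSpec("cardioid"), ParameterSet(concentration=0.5))


class TestConcentrationForPptr:
    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_round_trip(self, family):
        spec = DistributionSpec(family)
        for target in (1.0, 1.3, 2.0, 5.0):
            conc = concentration_for_pptr(spec, target)
            assert pptr(spec, ParameterSet(concentration=conc)) == pytest.approx(
                target, rel=1e-10
            )

    def test_known_values(self):
        assert concentration_for_pptr(
            DistributionSpec("von_mises"), 2.0
        ) == pytest.approx(math.log(2) / 2, rel=1e-12)
        assert concentration_for_pptr(DistributionSpec("cardioid"), 1.0) == 0.0
        assert concentration_for_pptr(
            DistributionSpec("exp_linear_cardioid"), 2.0
        ) == pytest.approx(math.log(2) / (2 * math.pi), rel=1e-12)

    def test_below_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            concentration_for_pptr(DistributionSpec("von_mises"), 0.9)


class TestRhoFromKappa:
    def test_values(self):
        assert rho_from_kappa("cardioid", 0.0) == 0.0
        assert rho_from_kappa("wrapped_cauchy", 50.0) > 0.999999
        # high-precision tanh(1)/2 (20 digits)
        assert rho_from_kappa("cardioid", 1.0) == pytest.approx(
            0.76159415595576488812 / 2, rel=1e-14
        )

    def test_unsupported_family(self):
        with pytest.raises(UnsupportedFamilyError):
            rho_from_kappa("von_mises", 1.0)


class TestMeanResultantLength:
    def test_point_mass_and_symmetry(self):
        assert mean_resultant_length([1.3], [10]) == pytest.approx(1.0)
        angles = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
        assert mean_resultant_length(angles, [5, 5, 5, 5]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_weighted_equals_expanded(self, rng):
        angles = rng.vonmises(0.0, 0.7, size=200) % TWO_PI
        weights = rng.integers(0, 50, size=200)
        expanded = np.repeat(angles, weights)
        assert mean_resultant_length(angles, weights) == pytest.approx(
            mean_resultant_length(expanded), rel=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            mean_resultant_length([1.0, 2.0], [0, 0])


def test_spec_validation():
    with pytest.raises(UnsupportedFamilyError):
        DistributionSpec("wrapped_normal")
    with pytest.raises(InvalidParameterError):
        DistributionSpec("von_mises", "skewed")
    assert DistributionSpec("jones_pewsey").n_shape_params == 1
    assert DistributionSpec("von_mises", "SE").n_shape_params == 1
    assert DistributionSpec("jones_pewsey", "MIAE").n_shape_params == 2
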