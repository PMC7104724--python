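"""Likelihoods, priors, discrete normalization, mixtures, estimands."""

import math

import numpy as np
import pytest
from scipy import special, stats

from repliptr.distributions import (
    TWO_PI,
    DistributionSpec,
    ParameterSet,
    concentration_for_pptr,
    log_pdf,
)
from repliptr.errors import (
    DegenerateInputError,
    InvalidParameterError,
    ModelMisuseError,
    UnsupportedFamilyError,
)
from repliptr.model import (
    CoverageTrack,
    MixtureParameterSet,
    PriorSpec,
    binomial_depth_predictive,
    discrete_normalization_constant,
    half_t_cdf,
    log_prior,
    loglik_mixture,
    loglik_multinomial_full,
    loglik_single,
    multinomial_constant,
    position_to_angle,
    reparam_location,
    wptr_and_mwptr,
)

VM = DistributionSpec("von_mises")


class TestPositionToAngle:
    def test_endpoints_and_midpoint(self):
        assert position_to_angle(1000, 1000) == 0.0  # 2*pi wraps to 0
        assert position_to_angle(500, 1000) == pytest.approx(math.pi)
        assert position_to_angle(1, 1000) == pytest.approx(0.0062832, abs=1e-7)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            position_to_angle(0, 10)
        with pytest.raises(IndexError):
            position_to_angle(11, 10)


class TestLoglikSingle:
    def test_uniform_limit_total_weight(self, toy_track):
        p = ParameterSet(mu=0.3, concentration=0.0)
        expected = toy_track.total_T * math.log(1 / TWO_PI)
        assert loglik_single(toy_track, VM, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("family", ["von_mises", "cardioid", "wrapped_cauchy"])
    def test_matches_expansion_oracle(self, family, toy_track):
        # brute force: expand each depth count into repeated observations
        spec = DistributionSpec(family)
        p = ParameterSet(mu=math.pi, concentration=0.2)
        obs = toy_track.to_angular()
        expanded = np.repeat(obs.angles, obs.weights)
        oracle = sum(float(log_pdf(spec, th, p)) for th in expanded)
        assert loglik_single(toy_track, spec, p) == pytest.approx(oracle, rel=1e-10)

    def test_all_zero_depths_rejected(self):
        track = CoverageTrack(np.zeros(5, dtype=int))
        with pytest.raises(DegenerateInputError):
            loglik_single(track, VM, ParameterSet(concentration=0.5))

    def test_rotation_equivariance(self, vm_track):
        p = ParameterSet(mu=1.0, concentration=0.7)
        base = loglik_single(vm_track, VM, p)
        shift = 250
        rolled = CoverageTrack(np.roll(vm_track.depths, shift))
        p2 = p.with_(mu=(1.0 + shift / vm_track.length_I * TWO_PI) % TWO_PI)
        assert loglik_single(rolled, VM, p2) == pytest.approx(base, rel=1e-8)

    def test_per_sample_concentrations(self, toy_track):
        other = CoverageTrack(np.array([1, 2, 3, 4, 5]), sample_id="b")
        p = ParameterSet(mu=1.0, concentration=np.array([0.3, 0.9]))
        combined = loglik_single([toy_track, other], VM, p)
        sep = (
            loglik_single(toy_track, VM, p.with_(concentration=0.3))
            + loglik_single(other, VM, p.with_(concentration=0.9))
        )
        assert combined == pytest.approx(sep, rel=1e-12)


class TestMultinomial:
    def test_combinatorial_term_exact(self, toy_track):
        # exact integer oracle: log T! - sum log d_i!
        d = toy_track.depths
        oracle = math.log(math.factorial(int(d.sum()))) - sum(
            math.log(math.factorial(int(x))) for x in d
        )
        assert multinomial_constant(toy_track) == pytest.approx(oracle, rel=1e-12)

    def test_single_observation_constant_is_zero(self):
        track = CoverageTrack(np.array([0, 1, 0]))
        assert multinomial_constant(track) == pytest.approx(0.0, abs=1e-12)

    def test_difference_invariant_to_params(self, toy_track, rng):
        diffs = []
        for _ in range(10):
            p = ParameterSet(mu=rng.uniform(0, TWO_PI),
                             concentration=rng.uniform(0, 2))
            diffs.append(
                loglik_multinomial_full(toy_track, VM, p)
                - loglik_single(toy_track, VM, p)
            )
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-12)


class TestBinomialPredictive:
    def test_uniform_mean(self):
        track = CoverageTrack(np.full(100, 7))
        mean, var = binomial_depth_predictive(
            track, VM, ParameterSet(concentration=0.0), i=13
        )
        assert mean == pytest.approx(track.total_T / 100)

    def test_mode_exceeds_antipode_and_variance(self, rng):
        I, T = 200, 100_000
        p = ParameterSet(mu=math.pi, concentration=0.7)
        track = CoverageTrack(rng.multinomial(T, np.full(I, 1 / I)))
        m_mode, v_mode = binomial_depth_predictive(track, VM, p, i=I // 2)
        m_anti, _ = binomial_depth_predictive(track, VM, p, i=I)
        assert m_mode > m_anti
        # Binomial variance identity
        dens = math.exp(float(log_pdf(VM, math.pi, p)))
        pi = dens * TWO_PI / I
        assert v_mode == pytest.approx(T * pi * (1 - pi), rel=1e-12)

    def test_coarse_binning_rejected(self):
        track = CoverageTrack(np.array([5, 5]))
        with pytest.raises(ModelMisuseError):
            binomial_depth_predictive(
                track, VM, ParameterSet(concentration=2.0), i=2  # the mode bin
            )


class TestPriors:
    def test_half_t_is_folded_student_t(self):
        p = ParameterSet(mu=0.0, concentration=0.0)
        lp = log_prior(VM, p)
        expected = math.log(2) + stats.t.logpdf(0.0, 2.5, scale=0.2)
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_prior_cdf_near_080_at_pptr_two(self):
        kappa = concentration_for_pptr(VM, 2.0)
        assert half_t_cdf(kappa, 2.5, 0.2) == pytest.approx(0.8, abs=0.05)

    def test_dirichlet_against_log_gamma_oracle(self):
        M, A = 3, 50.0 / 3
        alpha = np.full(M, 1 / 3)
        mix = MixtureParameterSet(
            mus=np.array([0.0, 2.0, 4.0]),
            concentrations=np.zeros((M, 1)),
            alpha=alpha,
        )
        lp = log_prior(VM, mix)
        # log Dirichlet density via log-gamma identity
        dir_lp = (
            special.gammaln(M * A) - M * special.gammaln(A)
            + (A - 1) * np.sum(np.log(alpha))
        )
        half_t = M * (math.log(2) + stats.t.logpdf(0.0, 2.5, scale=0.2))
        assert lp == pytest.approx(dir_lp + half_t, rel=1e-10)

    def test_shape_priors_counted(self):
        spec = DistributionSpec("jones_pewsey", "SE")
        p = ParameterSet(mu=0.0, concentration=0.5, psi=0.3, lam=0.2)
        lp = log_prior(spec, p)
        expected = (
            math.log(2) + stats.t.logpdf(0.5, 2.5, scale=0.2)
            + stats.norm.logpdf(0.3) + stats.norm.logpdf(0.2)
        )
        assert lp == pytest.approx(expected, rel=1e-10)


class TestDiscreteNormalization:
    def test_closed_forms(self):
        p = ParameterSet(concentration=0.1)
        assert discrete_normalization_constant(
            DistributionSpec("cardioid"), p, 100
        ) == pytest.approx(100 / TWO_PI)
        assert discrete_normalization_constant(
            DistributionSpec("linear_cardioid"), p, 100
        ) == pytest.approx(102 / TWO_PI)

    def test_von_mises_direct_sum_close_to_riemann(self):
        p = ParameterSet(mu=1.0, concentration=0.7)
        c = discrete_normalization_constant(VM, p, 1000)
        assert c == pytest.approx(1000 / TWO_PI, rel=0.005)

    def test_underived_families_rejected(self):
        with pytest.raises(NotImplementedError):
            discrete_normalization_constant(
                DistributionSpec("jones_pewsey"), ParameterSet(concentration=0.5), 10
            )


class TestMixture:
    def test_m1_reduction_bit_for_bit(self, toy_track):
        p = ParameterSet(mu=1.2, concentration=0.6)
        mix = MixtureParameterSet(
            mus=[1.2], concentrations=[[0.6]], alpha=[1.0]
        )
        assert loglik_mixture(toy_track, VM, mix) == loglik_single(toy_track, VM, p)

    def test_degenerate_weight_selects_component(self, toy_track):
        mix = MixtureParameterSet(
            mus=[1.0, 2.0], concentrations=[[0.5], [1.5]], alpha=[1.0, 0.0]
        )
        single = loglik_single(
            toy_track, VM, ParameterSet(mu=1.0, concentration=0.5)
        )
        assert loglik_mixture(toy_track, VM, mix) == pytest.approx(single, rel=1e-10)

    def test_matches_naive_non_log_oracle(self, toy_track):
        mus = np.array([0.5, 2.5, 4.5])
        concs = np.array([[0.4], [0.8], [1.2]])
        alpha = np.array([0.2, 0.3, 0.5])
        mix = MixtureParameterSet(mus, concs, alpha)
        obs = toy_track.to_angular()
        oracle = 0.0
        for th, d in zip(obs.angles, obs.weights):
            mixture_density = sum(
                a * math.exp(float(log_pdf(
                    VM, th, ParameterSet(mu=m, concentration=float(c[0]))
                )))
                for a, m, c in zip(alpha, mus, concs)
            )
            oracle += d * math.log(mixture_density)
        assert loglik_mixture(toy_track, VM, mix) == pytest.approx(oracle, abs=1e-8)

    def test_permutation_invariance(self, toy_track):
        mus = np.array([0.5, 2.5, 4.5])
        concs = np.array([[0.4], [0.8], [1.2]])
        alpha = np.array([0.2, 0.3, 0.5])
        base = loglik_mixture(toy_track, VM, MixtureParameterSet(mus, concs, alpha))
        perm = [2, 0, 1]
        shuffled = loglik_mixture(
            toy_track, VM,
            MixtureParameterSet(mus[perm], concs[perm], alpha[perm]),
        )
        assert shuffled == pytest.approx(base, rel=1e-12)

    def test_bad_weights_rejected(self, toy_track):
        mix = MixtureParameterSet(
            mus=[1.0, 2.0], concentrations=[[0.5], [1.5]], alpha=[0.6, 0.6]
        )
        with pytest.raises(InvalidParameterError):
            loglik_mixture(toy_track, VM, mix)


class TestWptr:
    def test_single_component_equals_pptr(self):
        mix = MixtureParameterSet(mus=[0.0], concentrations=[[0.7]], alpha=[1.0])
        w, mw = wptr_and_mwptr(VM, mix)
        assert w[0, 0] == pytest.approx(math.exp(2 * 0.7), rel=1e-12)
        assert mw[0] == pytest.approx(w[0, 0])

    def test_printed_exponential_phase_mean(self):
        # arithmetic reduction of per-origin wPTRs to the chromosome score
        wptrs = np.array([3.59, 3.18, 2.66])
        assert wptrs.mean() == pytest.approx(3.1433, abs=5e-4)

    def test_equal_weights_unit_kappa(self):
        mix = MixtureParameterSet(
            mus=[0.0, 3.0], concentrations=[[1.0], [1.0]], alpha=[0.5, 0.5]
        )
        w, mw = wptr_and_mwptr(VM, mix)
        np.testing.assert_allclose(w, math.e)
        assert mw[0] == pytest.approx(math.e)

    def test_non_von_mises_rejected(self):
        mix = MixtureParameterSet(mus=[0.0], concentrations=[[0.1]], alpha=[1.0])
        with pytest.raises(UnsupportedFamilyError):
            wptr_and_mwptr(DistributionSpec("cardioid"), mix)


class TestReparamLocation:
    def test_cardinal_directions(self):
        assert reparam_location((1.0, 0.0)) == 0.0
        assert reparam_location((0.0, -1.0)) == pytest.approx(3 * math.pi / 2)

    def test_round_trip(self, rng):
        for mu in rng.uniform(0, TWO_PI, size=100):
            back = reparam_location((math.cos(mu), math.sin(mu)))
            assert back == pytest.approx(mu, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            reparam_location((0.0, 0.0))
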