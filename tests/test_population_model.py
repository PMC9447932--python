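import numpy as np
import pytest

import serialdep as sd
from serialdep.population_model import population_response, prior_density

from conftest import brute_force_map


class TestGainProfile:
    def test_no_adaptation_gives_unit_gain(self, population):
        g = sd.gain_profile(40.0, 0.0, 1.0, population.centers)
        np.testing.assert_allclose(g, 1.0)

    def test_dip_depth_at_previous_stimulus(self, population):
        # a unit tuned exactly to theta_prev has gain 1 - gamma_m
        g = sd.gain_profile(population.centers[10], 0.3, 1.0,
                            population.centers)
        assert g[10] == pytest.approx(0.7)
        assert g.min() == pytest.approx(0.7)
        assert (g >= 0.7 - 1e-12).all() and (g <= 1.0 + 1e-12).all()

    def test_gain_unity_at_rectified_zero_crossing(self):
        # gamma_s * (Phi - theta_prev) = 90 deg in doubled space -> gain 1
        g = sd.gain_profile(0.0, 0.3, 1.0, np.array([45.0]))
        assert g[0] == pytest.approx(1.0)

    def test_parameter_validation(self, population):
        with pytest.raises(ValueError):
            sd.gain_profile(0.0, 1.5, 1.0, population.centers)
        with pytest.raises(ValueError):
            sd.gain_profile(0.0, 0.3, -1.0, population.centers)


class TestPopulationResponse:
    def test_unadapted_peak_rate_is_R(self, population):
        theta = population.centers[25]
        rates = population_response(theta, model=population)
        assert rates[25] == pytest.approx(population.rate_scale)

    def test_orthogonal_rate(self, population):
        # unit 90 deg away (doubled-angle pi): rate = R * exp(-2*kappa)
        theta = population.centers[0]
        rates = population_response(theta, model=population)
        i_orth = population.n_units // 2
        expect = population.rate_scale * np.exp(-2.0 * population.kappa)
        assert rates[i_orth] == pytest.approx(expect)

    def test_adapted_peak_reduction(self, population, adaptation):
        # the unit tuned to the repeated stimulus is attenuated by 1 - gamma_m
        idx = 30
        theta = population.centers[idx]
        r = population_response(theta, theta, population, adaptation)
        assert r[idx] == pytest.approx(
            (1 - adaptation.gamma_m) * population.rate_scale, rel=1e-9)


class TestLikelihoods:
    def test_unaware_self_consistency(self, population):
        theta = 73.0
        resp = population_response(theta, model=population)
        prof = sd.likelihood_unaware(resp, population)
        assert abs(sd.wrap_ori(prof.map_orientation - theta)) < 0.5

    def test_unaware_repulsion_matches_brute_force(self, population,
                                                   adaptation):
        theta_n, theta_prev = 80.0, 100.0  # delta = +20
        resp = population_response(theta_n, theta_prev, population, adaptation)
        prof = sd.likelihood_unaware(resp, population)
        err = sd.wrap_ori(prof.map_orientation - theta_n)
        assert err < -0.5  # repelled away from theta_prev
        oracle = brute_force_map(
            resp, lambda th: population_response(th, model=population))
        assert abs(sd.wrap_ori(prof.map_orientation - oracle)) <= 0.75

    def test_unaware_symmetry_points(self, population, adaptation):
        for delta in (0.0, 90.0):
            theta_n = 45.0
            resp = population_response(theta_n, theta_n + delta, population,
                                       adaptation)
            prof = sd.likelihood_unaware(resp, population)
            assert abs(sd.wrap_ori(prof.map_orientation - theta_n)) < 1e-6

    def test_aware_is_exact_on_noiseless_input(self, population, adaptation):
        for theta_n, theta_prev in [(10.0, 40.0), (120.0, 100.0),
                                    (5.0, 170.0)]:
            resp = population_response(theta_n, theta_prev, population,
                                       adaptation)
            prof = sd.likelihood_aware(resp, population, theta_prev,
                                       adaptation)
            # exact up to the grid step (peak interpolation may wiggle within)
            err = abs(sd.wrap_ori(prof.map_orientation - theta_n))
            assert err < population.grid_step

    def test_aware_reduces_to_unaware_without_adaptation(self, population):
        resp = population_response(30.0, model=population)
        none = sd.AdaptationParams(0.0, 1.0)
        a = sd.likelihood_aware(resp, population, 70.0, none)
        u = sd.likelihood_unaware(resp, population)
        np.testing.assert_allclose(a.log_likelihood, u.log_likelihood)

    def test_overaware_reduces_to_aware_and_attracts(self, population,
                                                     adaptation):
        theta_n, theta_prev = 60.0, 90.0  # delta = +30
        resp = population_response(theta_n, theta_prev, population, adaptation)
        same = sd.likelihood_overaware(resp, population, theta_prev,
                                       adaptation)
        aware = sd.likelihood_aware(resp, population, theta_prev, adaptation)
        np.testing.assert_allclose(same.log_likelihood, aware.log_likelihood)
        over = sd.likelihood_overaware(
            resp, population, theta_prev, sd.AdaptationParams(0.45, 1.0))
        assert sd.wrap_ori(over.map_orientation - theta_n) > 0.3
        under = sd.likelihood_overaware(
            resp, population, theta_prev, sd.AdaptationParams(0.15, 1.0))
        assert sd.wrap_ori(under.map_orientation - theta_n) < -0.1

    def test_poisson_sampled_aware_is_centered(self, population, adaptation):
        rng = np.random.default_rng(0)
        theta_n, theta_prev = 50.0, 75.0
        rates = population_response(theta_n, theta_prev, population,
                                    adaptation)
        errs = []
        for _ in range(300):
            prof = sd.likelihood_aware(rng.poisson(rates), population,
                                       theta_prev, adaptation)
            errs.append(sd.wrap_ori(prof.map_orientation - theta_n))
        assert abs(sd.circ_mean_ori(errs)) < 1.5


class TestPrior:
    def test_flat_prior_preserves_map(self, population):
        resp = population_response(30.0, model=population)
        prof = sd.likelihood_unaware(resp, population)
        post = sd.apply_prior(prof, 120.0, sd.PriorParams(p_same=0.0))
        assert post.map_orientation == pytest.approx(prof.map_orientation)

    def test_flat_likelihood_posterior_peaks_at_previous(self, population):
        flat = sd.LikelihoodProfile(population.grid,
                                    np.zeros(len(population.grid)), 0.0)
        post = sd.apply_prior(flat, 77.0, sd.PriorParams(psi=10.0))
        assert post.map_orientation == pytest.approx(77.0, abs=0.5)

    def test_prior_density_normalized_and_floored(self, population):
        prior = sd.PriorParams(psi=15.0)
        dens = prior_density(population.grid, 50.0, prior)
        assert dens.sum() * population.grid_step == pytest.approx(1.0,
                                                                  abs=1e-6)
        assert (dens >= (1 - prior.p_same) / 180.0 - 1e-15).all()

    def test_posterior_normalization(self, population, adaptation):
        resp = population_response(20.0, 40.0, population, adaptation)
        prof = sd.likelihood_unaware(resp, population)
        post = sd.apply_prior(prof, 40.0, sd.PriorParams(psi=20.0))
        assert post.posterior.sum() == pytest.approx(1.0, abs=1e-10)


class TestBiasCurves:
    DELTA = np.arange(-90.0, 90.1, 7.5)

    def test_aware_curve_identically_zero(self, population, adaptation):
        c = sd.bias_curve("aware", population, adaptation, self.DELTA)
        assert np.abs(c).max() < population.grid_step

    def test_unaware_curve_repulsive_odd_with_zeros(self, population,
                                                    adaptation):
        c = sd.bias_curve("unaware", population, adaptation, self.DELTA)
        np.testing.assert_allclose(c, -c[::-1], atol=0.05)
        mid = (self.DELTA > 5) & (self.DELTA < 60)
        assert (c[mid] < 0).all()
        for z in (-90.0, 0.0, 90.0):
            assert abs(c[self.DELTA == z][0]) < 0.05

    def test_bayes_aware_curve_attractive(self, population, adaptation):
        c = sd.bias_curve("bayes-aware", population, adaptation, self.DELTA,
                          prior=sd.PriorParams(psi=20.0))
        mid = (self.DELTA > 5) & (self.DELTA < 60)
        assert (c[mid] > 0).all()
        np.testing.assert_allclose(c, -c[::-1], atol=0.05)

    def test_reduction_chain_no_adaptation_no_bias(self, population):
        none = sd.AdaptationParams(0.0, 1.0)
        for dec, kw in [("unaware", {}), ("aware", {}),
                        ("overaware", {"assumed": none})]:
            c = sd.bias_curve(dec, population, none, self.DELTA, **kw)
            assert np.abs(c).max() < population.grid_step

    def test_unknown_decoder_rejected(self, population, adaptation):
        with pytest.raises(ValueError, match="decoder"):
            sd.bias_curve("psychic", population, adaptation, self.DELTA)


class TestDecoderVariance:
    def test_unaware_variance_higher_for_close(self, population, adaptation):
        errs, delta = sd.simulate_decoder_variance("unaware", population,
                                                   adaptation, 800, seed=0)
        close = np.abs(delta) < 30
        assert sd.circ_sd(errs[close]) > sd.circ_sd(errs[~close])

    def test_no_adaptation_variance_flat(self, population):
        none = sd.AdaptationParams(0.0, 1.0)
        errs, delta = sd.simulate_decoder_variance("unaware", population,
                                                   none, 800, seed=1)
        close = np.abs(delta) < 30
        assert sd.circ_sd(errs[close]) == pytest.approx(
            sd.circ_sd(errs[~close]), rel=0.2)

    def test_doubling_rate_reduces_variance(self, population, adaptation):
        import dataclasses
        errs_lo, _ = sd.simulate_decoder_variance("unaware", population,
                                                  adaptation, 600, seed=2)
        hi = dataclasses.replace(population, rate_scale=20.0)
        errs_hi, _ = sd.simulate_decoder_variance("unaware", hi, adaptation,
                                                  600, seed=2)
        assert sd.circ_sd(errs_hi) < sd.circ_sd(errs_lo)
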