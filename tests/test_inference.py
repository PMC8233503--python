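"""Expected spectra, Poisson composite likelihood, optimization machinery,
one-population models and parameter unscaling."""

import numpy as np
import pytest

from jafsim import DemographyParams, SampleConfig, simulate_jafs
from jafsim.demography import build_model_catalogue
from jafsim.inference import (
    FitResult,
    OptimizationSchedule,
    expected_afs_one_pop,
    expected_spectrum,
    fit_model,
    fit_one_pop,
    one_pop_models,
    poisson_loglik,
    sequence_length_from_snp_counts,
    snm_expected_afs,
    unscale,
)
from jafsim.spectrum import Spectrum

CATALOGUE = {m.name: m for m in build_model_catalogue(extended=True)}
IM_TRUTH = np.array([1.0, 0.25, 0.05, 4.0, 4.0])


class TestPoissonLoglik:
    @pytest.fixture
    def model_density(self, rng):
        return Spectrum(rng.random((6, 6)) + 0.1)

    def test_theta_recovered_exactly(self, model_density):
        obs = Spectrum(3.7 * model_density.data)
        _, theta = poisson_loglik(obs, model_density)
        assert theta == pytest.approx(3.7, rel=1e-12)

    def test_scale_invariance(self, model_density, rng):
        obs = Spectrum(rng.poisson(10 * model_density.data).astype(float))
        ll1, th1 = poisson_loglik(obs, model_density)
        ll2, th2 = poisson_loglik(obs, Spectrum(2.0 * model_density.data))
        assert ll2 == pytest.approx(ll1, rel=1e-12)
        assert th2 == pytest.approx(th1 / 2.0, rel=1e-12)

    def test_profiled_theta_maximises_likelihood(self, model_density, rng):
        """Brute-force 1-D scan: any theta other than the profiled one gives
        a lower Poisson log-likelihood."""
        from scipy.special import gammaln

        obs = Spectrum(rng.poisson(5 * model_density.data).astype(float))
        _, theta_hat = poisson_loglik(obs, model_density)
        use = ~(obs.mask | model_density.mask)
        d, m = obs.data[use], model_density.data[use]

        def ll_at(theta):
            lam = theta * m
            return float(np.sum(d * np.log(lam) - lam - gammaln(d + 1)))

        grid_ll = [ll_at(theta_hat * f) for f in
                   (0.5, 0.8, 0.95, 1.0, 1.05, 1.2, 2.0)]
        assert np.argmax(grid_ll) == 3

    def test_mismatched_inputs_rejected(self):
        a = Spectrum(np.ones((4, 4)))
        with pytest.raises(ValueError):
            poisson_loglik(a, Spectrum(np.ones((5, 4))))
        with pytest.raises(ValueError):
            poisson_loglik(a, Spectrum(np.ones((4, 4))).fold())
        with pytest.raises(ValueError):
            poisson_loglik(a, Spectrum(np.zeros((4, 4))))


class TestExpectedSpectrum:
    def test_snm_matches_analytic_form(self):
        s = snm_expected_afs(8)
        assert np.allclose(s.data[1:8] * np.arange(1, 8), 1.0)

    def test_zero_mixture_equals_homogeneous(self):
        hom = expected_spectrum(CATALOGUE["IM"], IM_TRUTH, 5, 5,
                                mc_reps=2_000, seed=3)
        het = expected_spectrum(CATALOGUE["IM2N2M"],
                                np.r_[IM_TRUTH, 0.0, 0.5, 0.0, 0.5],
                                5, 5, mc_reps=2_000, seed=3)
        assert np.array_equal(hom.data, het.data)

    def test_common_random_numbers_bit_identical(self):
        a = expected_spectrum(CATALOGUE["SC"],
                              [1.0, 0.5, 0.05, 0.02, 2.0, 2.0],
                              4, 4, mc_reps=1_000, seed=7)
        b = expected_spectrum(CATALOGUE["SC"],
                              [1.0, 0.5, 0.05, 0.02, 2.0, 2.0],
                              4, 4, mc_reps=1_000, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_sc_with_vanishing_isolation_approaches_im(self):
        im = expected_spectrum(CATALOGUE["IM"], [1.0, 0.25, 0.05, 4.0, 4.0],
                               6, 6, mc_reps=60_000, seed=5)
        sc = expected_spectrum(CATALOGUE["SC"],
                               [1.0, 0.25, 1e-5, 0.05 - 1e-5, 4.0, 4.0],
                               6, 6, mc_reps=60_000, seed=6)
        big = im.data > 0.02 * im.data.sum()
        assert np.allclose(im.data[big], sc.data[big], rtol=0.08)

    def test_mixture_shifts_mass_toward_fixed_classes(self):
        """A barrier-island class with zero migration adds weight to
        high-differentiation cells relative to the homogeneous model."""
        hom = expected_spectrum(CATALOGUE["IM"], IM_TRUTH, 5, 5,
                                mc_reps=20_000, seed=3)
        het = expected_spectrum(CATALOGUE["IM2M"], np.r_[IM_TRUTH, 0.4, 0.0],
                                5, 5, mc_reps=20_000, seed=3)
        hom_fixed = hom.data[5, 0] / hom.sum()
        het_fixed = het.data[5, 0] / het.sum()
        assert het_fixed > hom_fixed

    def test_mc_reps_floor(self):
        with pytest.raises(ValueError):
            expected_spectrum(CATALOGUE["IM"], IM_TRUTH, 4, 4, mc_reps=50,
                              seed=0)


class TestSchedules:
    def test_fold_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            OptimizationSchedule(((5, 2.0, 10), (5, 3.0, 10)))
        with pytest.raises(ValueError):
            OptimizationSchedule(((5, 0.5, 10),))

    def test_presets(self):
        assert len(OptimizationSchedule.simulated().rounds) == 3
        assert len(OptimizationSchedule.empirical().rounds) == 5
        assert OptimizationSchedule.empirical().n_routines == 5


class TestFitModel:
    @pytest.fixture(scope="class")
    def small_obs(self, ):
        demo = DemographyParams(nu1=1.0, nu2=0.25, t_s=0.05, m12=4.0,
                                m21=4.0)
        cfg = SampleConfig(n1=8, n2=8, n_loci=30_000)
        return simulate_jafs(demo, cfg, seed=5, folded=True)

    def test_noop_schedule_returns_start(self, small_obs):
        sched = OptimizationSchedule(((1, 1.0, 0),))
        fit = fit_model(small_obs, CATALOGUE["IM"], schedule=sched,
                        start=IM_TRUTH, seed=1, mc_reps=1_000)
        assert np.array_equal(fit.params, IM_TRUTH)

    def test_determinism(self, small_obs):
        sched = OptimizationSchedule(((2, 2.0, 5),))
        a = fit_model(small_obs, CATALOGUE["IM"], schedule=sched, seed=9,
                      mc_reps=1_000)
        b = fit_model(small_obs, CATALOGUE["IM"], schedule=sched, seed=9,
                      mc_reps=1_000)
        assert np.array_equal(a.params, b.params)
        assert a.loglik == b.loglik

    def test_aic_identity_and_k(self, small_obs):
        sched = OptimizationSchedule(((1, 1.0, 0),))
        fit = fit_model(small_obs, CATALOGUE["IM"], schedule=sched,
                        start=IM_TRUTH, seed=1, mc_reps=1_000)
        assert fit.k == 6  # five shape parameters plus profiled theta
        assert fit.aic == -2.0 * fit.loglik + 2.0 * fit.k

    def test_trace_records_every_restart(self, small_obs):
        sched = OptimizationSchedule(((3, 2.0, 2), (2, 1.0, 2)))
        fit = fit_model(small_obs, CATALOGUE["IM"], schedule=sched, seed=2,
                        mc_reps=1_000)
        # fold-1 restarts collapse to a single deterministic search
        assert len(fit.trace) == 3 + 1
        assert fit.loglik == pytest.approx(max(t[-1] for t in fit.trace))

    def test_requires_two_population_spectrum(self):
        with pytest.raises(ValueError):
            fit_model(Spectrum(np.ones(9)), CATALOGUE["IM"])


class TestOnePopModels:
    @staticmethod
    def _snm_obs(seed, n_loci=30_000):
        demo = DemographyParams(t_s=0.0, nu_anc=1.0)
        cfg = SampleConfig(n1=12, n2=0, n_loci=n_loci)
        afs = simulate_jafs(demo, cfg, seed=seed, max_snps_per_locus=None)
        return Spectrum(afs.data[:, 0])

    def test_two_epoch_with_no_change_reduces_to_snm(self):
        s = expected_afs_one_pop(one_pop_models()["2EP"], [1.0, 0.1], 10,
                                 mc_reps=40_000, seed=2)
        i = np.arange(1, 10)
        assert np.max(np.abs(s.data[1:10] * i - 1.0)) < 0.06

    def test_snm_preferred_on_snm_data(self):
        """The AIC penalty beats the nested 2EP model's small likelihood
        gain in the majority of replicates of neutral data."""
        wins = 0
        for seed in (21, 22, 23):
            obs = self._snm_obs(seed)
            snm = fit_one_pop(obs, "SNM")
            two = fit_one_pop(obs, "2EP",
                              schedule=OptimizationSchedule.quick(),
                              seed=seed, mc_reps=20_000)
            wins += snm.aic < two.aic
        assert wins >= 2

    def test_bottleneck_model_beats_snm_on_bottleneck_data(self):
        # recent crash to 5% of the ancestral size, 0.02 x 4N ago
        demo = DemographyParams(t_s=0.0, nu_anc=1.0, nu_ae=0.05, t_ae=0.02)
        cfg = SampleConfig(n1=12, n2=0, n_loci=100_000)
        afs = simulate_jafs(demo, cfg, seed=22, max_snps_per_locus=None)
        obs = Spectrum(afs.data[:, 0])
        snm = fit_one_pop(obs, "SNM")
        epb = fit_one_pop(obs, "3EPB",
                          schedule=OptimizationSchedule.quick(), seed=4,
                          mc_reps=8_000)
        assert snm.aic - epb.aic > 10.0

    def test_snm_has_single_parameter(self):
        fit = fit_one_pop(self._snm_obs(21), "SNM")
        assert fit.k == 1 and fit.params.size == 0
        assert fit.aic == -2 * fit.loglik + 2


class TestUnscale:
    def _fit(self, theta, names, values):
        return FitResult(model="IM", family="IM", param_names=tuple(names),
                         params=np.asarray(values, dtype=float),
                         theta_hat=theta, loglik=-10.0, k=len(names) + 1)

    def test_reference_size_from_theta(self):
        # theta over 1e6 loci of 36 bp with mu = 1e-8 and N_ANC = 20,000
        theta = 4 * 20_000 * 1e-8 * 36e6
        fit = self._fit(theta, ["nu1"], [1.0])
        u = unscale(fit, mu=1e-8, l_total=36e6)
        assert u.n_anc == pytest.approx(20_000)
        assert u.sizes["nu1"] == pytest.approx(20_000)

    def test_time_scaling(self):
        theta = 4 * 20_000 * 1e-8 * 36e6
        fit = self._fit(theta, ["t_s"], [0.05])
        u = unscale(fit, mu=1e-8, l_total=36e6, generation_time=3.5)
        assert u.times_generations["t_s"] == pytest.approx(4_000)
        assert u.times_years["t_s"] == pytest.approx(14_000)

    def test_migration_fraction(self):
        theta = 4 * 20_000 * 1e-8 * 36e6
        fit = self._fit(theta, ["m12"], [4.0])
        u = unscale(fit, mu=1e-8, l_total=36e6)
        assert u.migration_fractions["m12"] == pytest.approx(4 / 80_000)

    def test_sequence_length_helper(self):
        assert sequence_length_from_snp_counts(1e6, 5_000, 10_000) == 5e5
        with pytest.raises(ValueError):
            sequence_length_from_snp_counts(0, 1, 1)

    def test_requires_positive_theta(self):
        fit = self._fit(0.0, ["nu1"], [1.0])
        with pytest.raises(ValueError):
            unscale(fit, mu=1e-8, l_total=1e6)
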