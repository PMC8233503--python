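"""Structured-coalescent simulator: analytic oracles, msprime cross-check,
determinism and symmetry properties."""

import numpy as np
import pytest

from jafsim import DemographyParams, SampleConfig
from jafsim.coalsim import (
    EpochModel,
    class_branch_lengths,
    expected_branch_jafs,
    simulate_genealogy,
    simulate_jafs,
)


def harmonic(n):
    return sum(1.0 / k for k in range(1, n + 1))


class TestGenealogy:
    def test_pairwise_tmrca_is_half(self):
        """Two lineages in a constant-size population coalesce at rate 2, so
        the mean TMRCA is 0.5 in units of 4N generations."""
        demo = DemographyParams(t_s=0.0, nu_anc=1.0)
        reps = 20_000
        rng_seeds = range(reps)
        total = sum(simulate_genealogy(demo, 2, 0, seed=s).tmrca
                    for s in rng_seeds)
        mean = total / reps
        se = 0.5 / np.sqrt(reps)  # Exp(2) has sd == mean
        assert abs(mean - 0.5) < 3 * se

    def test_branch_classes_partition_samples(self):
        demo = DemographyParams(nu1=1.0, nu2=0.25, t_s=0.05, m12=4.0, m21=4.0)
        g = simulate_genealogy(demo, 5, 3, seed=11)
        assert g.n1 == 5 and g.n2 == 3
        for length, i, j in g.branches:
            assert length >= 0.0
            assert 1 <= i + j <= 7  # every branch subtends a proper subset
        # the two root children together subtend everything exactly once
        assert len(g.branches) == 2 * (5 + 3 - 1)

    def test_python_path_agrees_with_kernel(self):
        """The readable per-genealogy path and the batch kernel sample the
        same process: their mean class branch lengths agree."""
        demo = DemographyParams(nu1=1.0, nu2=0.5, t_s=0.1, m12=2.0, m21=2.0)
        reps = 4_000
        acc = np.zeros((4, 4))
        acc2 = np.zeros((4, 4))
        for s in range(reps):
            cur = simulate_genealogy(demo, 3, 3, seed=s).class_lengths()
            acc += cur
            acc2 += cur ** 2
        py_mean = acc / reps
        py_se = np.sqrt(np.maximum(acc2 / reps - py_mean ** 2, 0) / reps)
        kern = expected_branch_jafs(demo, 3, 3, n_reps=50_000, seed=123).data
        assert np.isclose(py_mean.sum(), kern.sum(), rtol=0.05)
        diff = np.abs(py_mean - kern)
        assert (diff < 4 * py_se + 0.02 * py_mean + 1e-4).all()

    def test_too_few_samples_rejected(self):
        demo = DemographyParams(t_s=0.0)
        with pytest.raises(ValueError):
            simulate_genealogy(demo, 1, 0, seed=1)

    def test_zero_split_collapses_to_single_deme(self):
        """A split at time zero makes both samples one panmictic population
        of the ancestral size: for one lineage per population in a deme of
        relative size 2 the mean pairwise TMRCA is 2 x 0.5 = 1."""
        demo = DemographyParams(t_s=0.0, nu_anc=2.0)
        T = class_branch_lengths(EpochModel.from_demography(demo),
                                 1, 1, 30_000, seed=13) / 30_000
        # both branches of the pair genealogy have length TMRCA
        assert T[1, 0] + T[0, 1] == pytest.approx(2.0, rel=0.05)


class TestSingleZPopulationOracles:
    def test_fu_expected_afs(self):
        """E[xi_i] = theta / i for a constant-size population (Fu 1995);
        branch-expectation cells must be proportional to 1/i."""
        demo = DemographyParams(t_s=0.0, nu_anc=1.0)
        afs = expected_branch_jafs(demo, 10, 0, n_reps=20_000, seed=1)
        i = np.arange(1, 10)
        rel = afs.data[1:10, 0] * i  # should all be 1
        assert np.max(np.abs(rel - 1.0)) < 0.05

    def test_watterson_segregating_sites(self):
        """Mean segregating sites per locus equals theta * a_{n-1} within
        three Monte-Carlo standard errors (all-sites counting)."""
        demo = DemographyParams(t_s=0.0, nu_anc=1.0)
        cfg = SampleConfig(n1=10, n2=0, n_loci=200_000)
        theta = cfg.theta_locus
        afs = simulate_jafs(demo, cfg, seed=2, max_snps_per_locus=None)
        a_n = harmonic(9)
        expected = theta * a_n * cfg.n_loci
        # Var(S) = theta E[L] + theta^2 Var(L) per locus
        var_locus = theta * a_n + theta ** 2 * sum(
            1.0 / (k - 1) ** 2 for k in range(2, 11))
        se = np.sqrt(var_locus * cfg.n_loci)
        assert abs(afs.sum() - expected) < 3 * se

    def test_growth_epoch_matches_piecewise_constant(self):
        """An exponential-growth epoch handled by closed-form inversion must
        match a fine piecewise-constant staircase of the same trajectory."""
        n, reps = 8, 40_000
        # backward: size 1 now, shrinking exponentially to 0.2 at t=0.3
        smooth = EpochModel.one_population([0.0, 0.3], [1.0, 0.2],
                                           x_end=[0.2, 0.2])
        steps = 60
        ts = np.linspace(0.0, 0.3, steps + 1)[:-1]
        mids = ts + 0.15 / steps
        sizes = 1.0 * (0.2 / 1.0) ** (mids / 0.3)
        stair = EpochModel.one_population(list(ts) + [0.3],
                                          list(sizes) + [0.2])
        a = class_branch_lengths(smooth, n, 0, reps, seed=5)[1:n, 0] / reps
        b = class_branch_lengths(stair, n, 0, reps, seed=6)[1:n, 0] / reps
        assert np.allclose(a, b, rtol=0.08, atol=0.003)


class TestJointSpectra:
    def test_zero_mutation_rate_gives_empty_spectrum(self, baseline_im):
        cfg = SampleConfig(n1=4, n2=4, n_loci=500, mu=0.0)
        assert simulate_jafs(baseline_im, cfg, seed=3).sum() == 0.0
        assert simulate_jafs(baseline_im, cfg, seed=3,
                             max_snps_per_locus=None).sum() == 0.0

    def test_determinism_across_runs(self, baseline_im):
        cfg = SampleConfig(n1=6, n2=6, n_loci=5_000)
        a = simulate_jafs(baseline_im, cfg, seed=42)
        b = simulate_jafs(baseline_im, cfg, seed=42)
        assert np.array_equal(a.data, b.data)
        c = simulate_jafs(baseline_im, cfg, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_counts_are_integers(self, baseline_im):
        cfg = SampleConfig(n1=6, n2=6, n_loci=2_000)
        a = simulate_jafs(baseline_im, cfg, seed=9, max_snps_per_locus=None)
        assert np.array_equal(a.data, np.round(a.data))

    def test_pop_swap_symmetry(self):
        """Exchangeable demography (equal sizes, symmetric migration, equal
        samples): the expected branch jAFS is symmetric under pop swap."""
        demo = DemographyParams(nu1=1.0, nu2=1.0, t_s=0.1, m12=3.0, m21=3.0)
        T = expected_branch_jafs(demo, 6, 6, n_reps=60_000, seed=8).data
        mass = T.sum()
        big = (T > 0.01 * mass) | (T.T > 0.01 * mass)
        assert np.allclose(T[big], T.T[big], rtol=0.1)

    def test_isolated_demes_share_no_polymorphism(self):
        """Deep split with zero migration: internal cells (shared
        polymorphism) carry a vanishing fraction of the branch mass."""
        demo = DemographyParams(nu1=1.0, nu2=1.0, t_s=4.0, m12=0.0, m21=0.0)
        T = expected_branch_jafs(demo, 5, 5, n_reps=20_000, seed=4).data
        shared = T[1:5, 1:5].sum()
        assert shared / T.sum() < 0.01

    def test_expected_branch_times_theta_matches_simulation(self,
                                                            baseline_im):
        """Law of total expectation: theta_locus x expected branch jAFS x
        n_loci reproduces the mean of the all-sites simulated jAFS."""
        cfg = SampleConfig(n1=5, n2=5, n_loci=150_000)
        exp = expected_branch_jafs(baseline_im, 5, 5, n_reps=100_000,
                                   seed=10).data
        expected_counts = exp * cfg.theta_locus * cfg.n_loci
        sim = simulate_jafs(baseline_im, cfg, seed=11,
                            max_snps_per_locus=None).data
        big = expected_counts > 50
        # Poisson sampling plus residual Monte-Carlo error in the expectation
        tol = 5 * np.sqrt(expected_counts[big]) + 0.03 * expected_counts[big]
        assert (np.abs(sim[big] - expected_counts[big]) < tol).all()

    def test_folded_output(self, baseline_im):
        cfg = SampleConfig(n1=6, n2=6, n_loci=3_000)
        f = simulate_jafs(baseline_im, cfg, seed=12, folded=True)
        u = simulate_jafs(baseline_im, cfg, seed=12, folded=False)
        assert f.folded and not u.folded
        assert np.isclose(f.sum(), u.sum())  # folding conserves SNPs


class TestAgainstMsprime:
    """msprime as the independent oracle for the two-population simulator."""

    @pytest.fixture(scope="class")
    def msprime_branch_jafs(self):
        msprime = pytest.importorskip("msprime")
        n_ref = 20_000
        dem = msprime.Demography()
        dem.add_population(name="anc", initial_size=n_ref)
        dem.add_population(name="p1", initial_size=n_ref)
        dem.add_population(name="p2", initial_size=0.25 * n_ref)
        m = 4.0 / (4 * n_ref)
        dem.set_migration_rate(source="p1", dest="p2", rate=m)
        dem.set_migration_rate(source="p2", dest="p1", rate=m)
        dem.add_population_split(time=0.05 * 4 * n_ref,
                                 derived=["p1", "p2"], ancestral="anc")
        reps, n1, n2 = 4_000, 4, 4
        acc = np.zeros((n1 + 1, n2 + 1))
        acc2 = np.zeros_like(acc)
        # ploidy 2 so that `initial_size` means diploid N as in our scaling;
        # two diploid individuals = four sampled haploid genomes per deme
        sims = msprime.sim_ancestry(
            samples={"p1": n1 // 2, "p2": n2 // 2}, demography=dem, ploidy=2,
            num_replicates=reps, random_seed=97)
        for ts in sims:
            tree = ts.first()
            cur = np.zeros_like(acc)
            pop = {u: ts.node(u).population for u in ts.samples()}
            for u in tree.nodes():
                if tree.parent(u) == -1:
                    continue
                i = sum(1 for s in tree.samples(u) if pop[s] == 1)
                j = sum(1 for s in tree.samples(u) if pop[s] == 2)
                cur[i, j] += tree.branch_length(u) / (4 * n_ref)
            acc += cur
            acc2 += cur ** 2
        mean = acc / reps
        se = np.sqrt(np.maximum(acc2 / reps - mean ** 2, 0.0) / reps)
        return mean, se

    def test_branch_class_expectations_match(self, msprime_branch_jafs,
                                             baseline_im):
        ms_mean, ms_se = msprime_branch_jafs
        ours = expected_branch_jafs(baseline_im, 4, 4, n_reps=60_000,
                                    seed=21).data
        mask = np.ones_like(ours, dtype=bool)
        mask[0, 0] = mask[4, 4] = False
        diff = np.abs(ours - ms_mean)[mask]
        tol = (4.0 * ms_se + 0.02 * ms_mean + 1e-4)[mask]
        assert (diff < tol).all(), (ours, ms_mean)

    def test_total_tree_length_matches(self, msprime_branch_jafs,
                                       baseline_im):
        ms_mean, ms_se = msprime_branch_jafs
        ours = expected_branch_jafs(baseline_im, 4, 4, n_reps=60_000,
                                    seed=22).data
        assert np.isclose(ours.sum(), ms_mean.sum(),
                          rtol=3 * ms_se.sum() / ms_mean.sum() + 0.01)
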