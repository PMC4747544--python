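"""Coalescent simulator validation: closed forms, independent oracle,
rate-map geometry, ascertainment and degradation."""

import numpy as np
import pytest

from rhomap.genotypes import MISSING
from rhomap.simulate import (Hotspot, PopulationModel, RateMap,
                             ascertain_markers, degrade_genotypes,
                             four_gamete_violations, pairwise_diversity,
                             segregating_sites, simulate_haplotypes,
                             site_frequency_spectrum)


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


class TestRateMap:
    def test_cumulative_integral_inverse(self):
        rm = RateMap(10_000, 100.0, (Hotspot(2_000, 4_000, 10.0),))
        # total = 100/1e6 * (10_000 + 9*2_000)
        assert np.isclose(rm.total_rho(), 100e-6 * 28_000)
        assert np.isclose(rm.integral(2_000, 4_000), 100e-6 * 20_000)
        for u in [0.1, 0.5, 0.9]:
            x = rm.inverse_cumulative(u * rm.total_rho())
            assert np.isclose(float(rm.cumulative(x)), u * rm.total_rho())

    def test_overlapping_hotspots_add(self):
        rm = RateMap(5_000, 100.0, (Hotspot(1_000, 3_000, 5.0),
                                    Hotspot(2_000, 4_000, 3.0)))
        # [2000,3000): 1 + 4 + 2 = 7x background
        assert np.isclose(rm.integral(2_000, 3_000), 100e-6 * 7_000)

    def test_invalid_hotspot(self):
        with pytest.raises(ValueError):
            Hotspot(0, 100, 2.0)  # narrower than 200 bp
        with pytest.raises(ValueError):
            RateMap(1_000, 50.0, (Hotspot(500, 1_200, 2.0),))


class TestCoalescentClosedForms:
    N_REPS = 350
    N, L, THETA = 20, 10_000, 1e-3

    @pytest.fixture(scope="class")
    def replicates(self):
        pop = PopulationModel(theta=self.THETA)
        rm = RateMap(self.L, 0.0)
        return [simulate_haplotypes(pop, rm, self.N, seed=10_000 + i)
                for i in range(self.N_REPS)]

    def test_watterson_segregating_sites(self, replicates):
        S = np.array([r.n_sites for r in replicates])
        expected = self.THETA * self.L * harmonic(self.N)
        se = S.std(ddof=1) / np.sqrt(len(S))
        assert abs(S.mean() - expected) < 3 * se

    def test_pairwise_diversity_equals_theta(self, replicates):
        pi = np.array([pairwise_diversity(r.haplotypes) / self.L
                       for r in replicates])
        se = pi.std(ddof=1) / np.sqrt(len(pi))
        assert abs(pi.mean() - self.THETA) < 3 * se

    def test_site_frequency_spectrum_neutral(self, replicates):
        # per-class counts vary between replicates (sites share one
        # genealogy), so the Monte-Carlo error comes from replicate scatter
        per_rep = np.array([site_frequency_spectrum(r.haplotypes)
                            for r in replicates], float)
        i = np.arange(1, self.N)
        expected = self.THETA * self.L / i  # E[xi_i] = theta*L/i
        mean = per_rep.mean(axis=0)
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(len(replicates))
        for cls in range(6):  # lowest frequency classes carry most sites
            assert abs(mean[cls] - expected[cls]) < 3 * se[cls]

    def test_no_recombination_implies_four_gamete_theorem(self, replicates):
        for r in replicates[:40]:
            assert not four_gamete_violations(r.haplotypes).any()


class TestAgainstMsprime:
    """The hand-rolled back-in-time simulator against msprime at identical
    scaled parameters (independent implementation of the same process)."""

    def test_summaries_match(self):
        import msprime

        n, L, theta, rho_mb = 12, 8_000, 1.2e-3, 250.0
        reps = 220
        pop = PopulationModel(theta=theta)
        rm = RateMap(L, rho_mb)
        S_ours, pi_ours = [], []
        for i in range(reps):
            s = simulate_haplotypes(pop, rm, n, seed=500 + i)
            S_ours.append(s.n_sites)
            pi_ours.append(pairwise_diversity(s.haplotypes) / L)
        S_ms, pi_ms = [], []
        for i in range(reps):
            # ploidy=1, N=1: pair coalescence rate 1 per generation,
            # matching our time unit; then theta/2 mutations and rho/2
            # recombinations per unit time
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=1.0,
                sequence_length=L,
                recombination_rate=rho_mb / 1e6 / 2.0, random_seed=900 + i)
            ts = msprime.sim_mutations(ts, rate=theta / 2.0,
                                       random_seed=1900 + i,
                                       model=msprime.BinaryMutationModel())
            S_ms.append(ts.num_sites)
            pi_ms.append(ts.diversity(mode="site"))
        for ours, ref in ((S_ours, S_ms), (pi_ours, pi_ms)):
            ours, ref = np.array(ours, float), np.array(ref, float)
            se = np.hypot(ours.std(ddof=1) / np.sqrt(reps),
                          ref.std(ddof=1) / np.sqrt(reps))
            assert abs(ours.mean() - ref.mean()) < 3 * se


class TestHotspotSignal:
    def test_hotspot_produces_local_four_gamete_excess(self):
        """A 50x hotspot yields more four-gamete-violating pairs spanning
        it than a background-only simulation at matched theta."""
        pop = PopulationModel(theta=2e-3)
        L = 20_000
        hot = RateMap(L, 100.0, (Hotspot(9_000, 11_000, 50.0),))
        flat = RateMap(L, 100.0)
        reps = 80

        def spanning_violations(rm, seed0):
            count = 0
            for i in range(reps):
                s = simulate_haplotypes(pop, rm, 20, seed=seed0 + i)
                pos = s.site_positions
                viol = four_gamete_violations(s.haplotypes)
                span = (pos[:, None] < 9_000) & (pos[None, :] > 11_000)
                count += int((viol & span).sum())
            return count

        assert spanning_violations(hot, 3_000) > spanning_violations(
            flat, 6_000)

    def test_ld_decay_monotone_in_rho(self):
        """Mean r^2 between marker pairs is non-increasing in pairwise rho
        (binned), averaged over replicates."""
        pop = PopulationModel(theta=1.5e-3)
        rm = RateMap(40_000, 200.0)
        edges = [0.0, 0.5, 2.0, 5.0, 1e9]
        sums = np.zeros(len(edges) - 1)
        counts = np.zeros(len(edges) - 1)
        for i in range(120):
            s = simulate_haplotypes(pop, rm, 20, seed=7_000 + i)
            h, pos = s.haplotypes, s.site_positions.astype(float)
            freq = h.mean(axis=0)
            keep = (freq >= 0.1) & (freq <= 0.9)
            h, pos = h[:, keep], pos[keep]
            for a in range(0, h.shape[1], 2):
                for b in range(a + 1, h.shape[1], 3):
                    rho = 200.0 / 1e6 * (pos[b] - pos[a])
                    pA, pB = h[:, a].mean(), h[:, b].mean()
                    D = (h[:, a] * h[:, b]).mean() - pA * pB
                    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
                    k = np.searchsorted(edges, rho, side="right") - 1
                    sums[k] += r2
                    counts[k] += 1
        means = sums / counts
        assert np.all(np.diff(means) < 0)


class TestAscertainment:
    @pytest.fixture(scope="class")
    def sample(self):
        pop = PopulationModel(theta=1.5e-3)
        return simulate_haplotypes(pop, RateMap(30_000, 150.0), 20, seed=21)

    def test_maf_threshold_removes_rare_sites(self, sample):
        g = ascertain_markers(sample, min_maf=0.1, target_density=1e9,
                              seed=1)
        maf = np.minimum(g.maf, 1 - g.maf)
        assert np.all(g.maf >= 0.1)
        singleton_sites = np.where(
            sample.haplotypes.sum(axis=0) == 1)[0]
        assert singleton_sites.size > 0  # the filter had work to do
        assert g.markers.k < sample.n_sites

    def test_no_filter_is_identity(self, sample):
        g = ascertain_markers(sample, min_maf=0.0, target_density=1e9,
                              seed=1)
        assert g.markers.k == sample.n_sites
        assert np.array_equal(
            g.haplotypes, sample.haplotypes)

    def test_deterministic_under_seed(self, sample):
        g1 = ascertain_markers(sample, 0.1, 500.0, seed=9)
        g2 = ascertain_markers(sample, 0.1, 500.0, seed=9)
        assert np.array_equal(g1.markers.positions, g2.markers.positions)
        assert np.array_equal(g1.calls, g2.calls)

    def test_diploid_pairing(self, sample):
        g = ascertain_markers(sample, 0.1, 500.0, seed=2)
        assert g.n_individuals == sample.n // 2
        assert np.array_equal(g.haplotypes[0::2] + g.haplotypes[1::2],
                              g.calls.T)


class TestDegradation:
    def test_zero_rate_identity(self):
        pop = PopulationModel(theta=1e-3)
        s = simulate_haplotypes(pop, RateMap(10_000, 0.0), 10, seed=3)
        g = ascertain_markers(s, 0.0, 1e9, seed=1)
        assert degrade_genotypes(g, 0.0, seed=5) is g

    def test_missing_fraction_binomial(self):
        pop = PopulationModel(theta=3e-3)
        s = simulate_haplotypes(pop, RateMap(60_000, 0.0), 20, seed=4)
        g = ascertain_markers(s, 0.0, 1e9, seed=1)
        rate = 0.25
        d = degrade_genotypes(g, rate, seed=11)
        n_calls = d.calls.size
        frac = (d.calls == MISSING).mean()
        se = np.sqrt(rate * (1 - rate) / n_calls)
        assert n_calls >= 2_000
        assert abs(frac - rate) < 3 * se

    def test_deterministic_under_seed(self):
        pop = PopulationModel(theta=1e-3)
        s = simulate_haplotypes(pop, RateMap(10_000, 0.0), 10, seed=6)
        g = ascertain_markers(s, 0.0, 1e9, seed=1)
        d1 = degrade_genotypes(g, 0.3, seed=8)
        d2 = degrade_genotypes(g, 0.3, seed=8)
        assert np.array_equal(d1.calls, d2.calls)


def test_population_model_theta_consistency():
    pm = PopulationModel(n_e=12_500, mu=1e-8)
    assert np.isclose(pm.theta, 4 * 12_500 * 1e-8)
    with pytest.raises(ValueError):
        PopulationModel(theta=1e-3, n_e=1_000, mu=1e-8)
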