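"""Two-locus lookup table and composite likelihood engine."""

import numpy as np
import pytest

from rhomap.genotypes import GenotypeMatrix, MarkerSet
from rhomap.likelihood import (CompositeLikelihood, build_two_locus_table,
                               canonical_config, default_rho_grid,
                               simulate_two_locus_config)
from rhomap.simulate import Hotspot


def msprime_two_locus_config(n, rho, rng, seed):
    """Independent oracle: two-locus configuration draw from an msprime
    ancestry simulation with branch-proportional mutation placement."""
    import msprime

    ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1.0,
                              sequence_length=2.0,
                              recombination_rate=rho / 2.0,
                              random_seed=seed)
    picks = []
    for x in (0.5, 1.5):
        t = ts.at(x)
        nodes, w = [], []
        for u in t.nodes():
            bl = t.branch_length(u)
            if bl > 0:
                nodes.append(u)
                w.append(bl)
        w = np.asarray(w)
        u = nodes[rng.choice(len(nodes), p=w / w.sum())]
        picks.append(set(t.samples(u)))
    SA, SB = picks
    n11 = len(SA & SB)
    n10 = len(SA - SB)
    n01 = len(SB - SA)
    return canonical_config(n - n11 - n10 - n01, n01, n10, n11)


def total_variation(c1: dict, c2: dict) -> float:
    n1, n2 = sum(c1.values()), sum(c2.values())
    keys = set(c1) | set(c2)
    return 0.5 * sum(abs(c1.get(k, 0) / n1 - c2.get(k, 0) / n2)
                     for k in keys)


class TestConfigCanonicalization:
    def test_folding_invariance(self):
        base = (3, 1, 2, 4)
        for variant in [(2, 4, 3, 1), (1, 3, 4, 2), (4, 2, 1, 3)]:
            assert canonical_config(*variant) == canonical_config(*base)

    def test_counts_sum_preserved(self):
        assert sum(canonical_config(5, 0, 2, 3)) == 10


class TestTwoLocusTable:
    def test_probabilities_normalized(self, table_n4):
        for gi in range(table_n4.grid.size):
            assert abs(table_n4.probabilities(gi).sum() - 1.0) < 0.05

    def test_rho_zero_has_no_four_gamete_configs(self, table_n8):
        gi = int(np.where(table_n8.grid == 0.0)[0][0])
        probs = table_n8.probabilities(gi)
        floor = 1.0 / table_n8.reps  # unseen configs sit at the floor value
        for cfg, p in zip(table_n8.configs, probs):
            if p > floor and min(cfg) > 0:
                raise AssertionError(
                    f"four-gamete-complete config {cfg} at rho=0 (p={p})")

    def test_large_rho_factorizes_into_marginals(self):
        """At rho >> 1 the joint frequency distribution of the two loci is
        the product of the marginals, within Monte-Carlo error."""
        rng = np.random.default_rng(12)
        n, reps = 10, 3_000
        joint = {}  # folded marginal frequency classes 1..n//2
        for _ in range(reps):
            n00, n01, n10, n11 = simulate_two_locus_config(n, 1_000.0, rng)
            fa = min(n10 + n11, n00 + n01)
            fb = min(n01 + n11, n00 + n10)
            joint[(fa, fb)] = joint.get((fa, fb), 0) + 1
        pa, pb = {}, {}
        for (fa, fb), c in joint.items():
            pa[fa] = pa.get(fa, 0) + c
            pb[fb] = pb.get(fb, 0) + c
        tv = 0.5 * sum(
            abs(c / reps - (pa[fa] / reps) * (pb[fb] / reps))
            for (fa, fb), c in joint.items())
        assert tv < 0.05

    def test_kernel_matches_msprime_oracle(self):
        """Configuration distributions from the hand-rolled two-locus
        ancestral process and from msprime agree (total variation below
        twice the self-distance of two independent kernel runs)."""
        n, reps = 8, 1_800
        rng = np.random.default_rng(3)
        for rho in (0.0, 8.0):
            ours_a, ours_b, oracle = {}, {}, {}
            for i in range(reps):
                c = simulate_two_locus_config(n, rho, rng)
                ours_a[c] = ours_a.get(c, 0) + 1
                c = simulate_two_locus_config(n, rho, rng)
                ours_b[c] = ours_b.get(c, 0) + 1
                c = msprime_two_locus_config(n, rho, rng, seed=i + 1)
                oracle[c] = oracle.get(c, 0) + 1
            null_tv = total_variation(ours_a, ours_b)
            cross_tv = total_variation(ours_a, oracle)
            assert cross_tv < 2.0 * null_tv + 0.02

    def test_maf_conditioning_restricts_support(self):
        rng = np.random.default_rng(5)
        n = 20
        for _ in range(200):
            n00, n01, n10, n11 = simulate_two_locus_config(
                n, 4.0, rng, min_maf=0.1)
            fa, fb = n10 + n11, n01 + n11
            assert min(fa, n - fa) >= 2 and min(fb, n - fb) >= 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_two_locus_table(4, grid=np.array([]), reps=10)


def toy_genotypes(hap, positions, region_end=None):
    hap = np.asarray(hap, dtype=np.int8)
    ms = MarkerSet("toy", np.asarray(positions),
                   region_start=1,
                   region_end=region_end or int(positions[-1]))
    calls = (hap[0::2] + hap[1::2]).T.astype(np.int8)
    samples = tuple(f"i{k}" for k in range(hap.shape[0] // 2))
    return GenotypeMatrix(ms, samples, calls, np.ascontiguousarray(hap))


class TestCompositeLikelihood:
    def test_single_marker_region_gives_zero(self, table_n4):
        g = toy_genotypes([[0], [1], [0], [1]], [100])
        eng = CompositeLikelihood(g, table_n4)
        assert eng.loglik(200.0) == 0.0

    def test_grid_node_equals_stored_value(self, table_n4):
        """A pair whose map-implied rho hits a grid node exactly must score
        the stored log-probability with no interpolation error."""
        hap = [[0, 0], [1, 1], [0, 1], [1, 0]]
        d = 5_000
        g = toy_genotypes(hap, [1, 1 + d])
        eng = CompositeLikelihood(g, table_n4)
        rho_node = 2.0
        bg = rho_node / d * 1e6
        cfg = canonical_config(1, 1, 1, 1)
        gi = int(np.where(table_n4.grid == rho_node)[0][0])
        expected = table_n4.logp[gi, table_n4.config_index[cfg]]
        assert np.isclose(eng.loglik(bg), expected)

    def test_three_marker_sum_matches_hand_enumeration(self, table_n4):
        """4 haplotypes x 3 markers: engine equals the brute-force sum of
        the three pairwise interpolated log-probabilities."""
        hap = np.array([[0, 0, 1], [1, 1, 0], [0, 1, 1], [1, 0, 0]])
        pos = np.array([1, 2_001, 6_001])
        g = toy_genotypes(hap, pos)
        eng = CompositeLikelihood(g, table_n4)
        bg = 400.0
        grid, total = table_n4.grid, 0.0
        for (i, j) in [(0, 1), (1, 2), (0, 2)]:
            hi, hj = hap[:, i], hap[:, j]
            n11 = int((hi & hj).sum())
            n10 = int((hi & (1 - hj)).sum())
            n01 = int(((1 - hi) & hj).sum())
            cfg = canonical_config(4 - n11 - n10 - n01, n01, n10, n11)
            col = table_n4.config_index.get(cfg, len(table_n4.configs))
            rho = bg / 1e6 * (pos[j] - pos[i])
            hi_idx = int(np.clip(np.searchsorted(grid, rho), 1,
                                 grid.size - 1))
            lo_idx = hi_idx - 1
            w = (rho - grid[lo_idx]) / (grid[hi_idx] - grid[lo_idx])
            total += ((1 - w) * table_n4.logp[lo_idx, col]
                      + w * table_n4.logp[hi_idx, col])
        assert np.isclose(eng.loglik(bg), total)

    def test_rho_above_grid_clamped_and_counted(self, table_n4):
        g = toy_genotypes([[0, 0], [1, 1], [0, 1], [1, 0]], [1, 10_001])
        eng = CompositeLikelihood(g, table_n4)
        big_bg = 17.0 / 10_000 * 1e6  # implies rho 17 > grid max 16
        ll_clamped = eng.loglik(big_bg)
        assert eng.n_clamped_last == 1
        assert np.isclose(ll_clamped,
                          eng.loglik(16.0 / 10_000 * 1e6))

    def test_hotspot_raises_pairwise_rho(self, table_n4):
        g = toy_genotypes([[0, 0], [1, 1], [0, 1], [1, 0]], [1, 4_001],
                          region_end=6_000)
        eng = CompositeLikelihood(g, table_n4)
        h = Hotspot(1_000, 3_000, 10.0)
        base = eng.pair_rho(100.0)
        with_h = eng.pair_rho(100.0, (h,))
        assert np.isclose(with_h[0] - base[0], 100e-6 * 9 * 2_000)

    def test_temperature_scales_loglik(self, table_n4):
        g = toy_genotypes([[0, 0], [1, 1], [0, 1], [1, 0]], [1, 2_001])
        e1 = CompositeLikelihood(g, table_n4, temperature=1.0)
        e5 = CompositeLikelihood(g, table_n4, temperature=5.0)
        assert np.isclose(e1.loglik(300.0), 5.0 * e5.loglik(300.0))

    def test_mismatched_sample_size_rejected(self, table_n8):
        g = toy_genotypes([[0], [1], [0], [1]], [100])
        with pytest.raises(ValueError, match="n=8"):
            CompositeLikelihood(g, table_n8)


def test_default_grid_shape():
    grid = default_rho_grid()
    assert grid[0] == 0.0
    assert grid[-1] == 1024.0
    assert np.all(np.diff(grid) > 0)
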