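"""Coalescent-with-recombination simulator under a background-plus-hotspot
recombination map.

The generator is the back-in-time (Hudson-style) ancestral recombination
graph: lineages carry intervals of ancestral material, recombination splits
a lineage at a breakpoint drawn by inverse-CDF on the cumulative rate map,
pairs of lineages coalesce at rate 1 per pair (time in units of 2N_e
generations).  Infinite-sites mutations are dropped on branch segments in
proportion to branch length x span, at rate theta/2 per site.  Crossing-over
only; no gene conversion, demography or selection.

The default preset emulates a GoldenGate-array study design: 22 diploid
individuals (44 haplotypes), an 850 kb region, roughly 70 ascertained
markers with sample MAF >= 0.1, a background rate of ~200 rho/Mb and
optional kb-scale hotspots of strongly elevated rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, MarkerSet


@dataclass(frozen=True)
class PopulationModel:
    """Neutral panmictic population; theta = 4*N_e*mu per site."""

    theta: float = None  # type: ignore[assignment]
    n_e: float = None  # type: ignore[assignment]
    mu: float = None  # type: ignore[assignment]
    ploidy_factor: int = 4

    def __post_init__(self):
        theta = self.theta
        if theta is None:
            if self.n_e is None or self.mu is None:
                raise ValueError("give theta, or both n_e and mu")
            theta = self.ploidy_factor * self.n_e * self.mu
            object.__setattr__(self, "theta", theta)
        elif self.n_e is not None and self.mu is not None:
            if not math.isclose(theta, self.ploidy_factor * self.n_e * self.mu,
                                rel_tol=1e-9):
                raise ValueError("theta inconsistent with 4*N_e*mu")
        if theta <= 0:
            raise ValueError("theta must be positive")


@dataclass(frozen=True)
class Hotspot:
    """Interval of elevated recombination: rate inside is multiplied by
    ``intensity``; width constrained to [200 bp, 10 kb]."""

    start: float
    end: float
    intensity: float

    def __post_init__(self):
        if not (200.0 <= self.end - self.start <= 10_000.0):
            raise ValueError("hotspot width must lie in [200 bp, 10 kb]")
        if not np.isfinite(self.intensity) or self.intensity < 1.0:
            raise ValueError("intensity multiplier must be finite and >= 1")

    @property
    def width(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class RateMap:
    """Piecewise-constant population recombination rate over [0, L) bp.

    The local rate is ``background * (1 + sum_h (intensity_h - 1))`` over the
    hotspots covering a site, i.e. a single hotspot of intensity lambda
    elevates the rate to lambda x background.
    """

    region_length: float
    background_rho_per_mb: float
    hotspots: tuple = ()

    def __post_init__(self):
        if self.region_length <= 0:
            raise ValueError("region length must be positive")
        if self.background_rho_per_mb < 0:
            raise ValueError("background rate must be >= 0")
        hs = tuple(self.hotspots)
        for h in hs:
            if not (0 <= h.start and h.end <= self.region_length):
                raise ValueError("hotspot outside region")
        object.__setattr__(self, "hotspots", hs)

    def _edges_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints and per-bp rates of the piecewise-constant map."""
        pts = {0.0, float(self.region_length)}
        for h in self.hotspots:
            pts.add(float(h.start))
            pts.add(float(h.end))
        edges = np.array(sorted(pts))
        mids = 0.5 * (edges[:-1] + edges[1:])
        mult = np.ones_like(mids)
        for h in self.hotspots:
            mult += np.where((mids >= h.start) & (mids < h.end),
                             h.intensity - 1.0, 0.0)
        rates = self.background_rho_per_mb / 1e6 * mult
        return edges, rates

    def cumulative(self, x) -> np.ndarray:
        """Integral of the per-bp rate over [0, x] (vectorised)."""
        edges, rates = self._edges_rates()
        cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
        x = np.asarray(x, float)
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                      len(rates) - 1)
        return cum[idx] + rates[idx] * (x - edges[idx])

    def integral(self, a, b) -> np.ndarray:
        """Total scaled rate (rho) accumulated between positions a and b."""
        return self.cumulative(b) - self.cumulative(a)

    def inverse_cumulative(self, u: float) -> float:
        """Position x with cumulative(x) = u; inverse-CDF breakpoint draw."""
        edges, rates = self._edges_rates()
        cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
        i = int(np.clip(np.searchsorted(cum, u, side="right") - 1, 0,
                        len(rates) - 1))
        if rates[i] == 0:
            return float(edges[i])
        return float(edges[i] + (u - cum[i]) / rates[i])

    def total_rho(self) -> float:
        return float(self.cumulative(self.region_length))

    def mean_rho_per_mb(self) -> float:
        return self.total_rho() / (self.region_length / 1e6)


@dataclass(frozen=True)
class SimulatedSample:
    """Haplotypes from one coalescent replicate, plus ground truth."""

    haplotypes: np.ndarray  # (n, S) int8
    site_positions: np.ndarray  # 1-based int bp
    true_rate_map: RateMap
    theta: float
    seed: int

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


# ---------------------------------------------------------------------------
# Hudson back-in-time ARG

def _merge_segments(segs_a, segs_b, full_mask):
    """Union two lineages' ancestral-material segment lists.

    Segments are (left, right, mask) with mask a bitmask of descendant
    samples.  Intervals whose union covers all samples have found their MRCA
    and are dropped.
    """
    pts = sorted({p for (l, r, _) in segs_a + segs_b for p in (l, r)})
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        m = 0
        for (l, r, s) in segs_a:
            if l <= a and b <= r:
                m |= s
        for (l, r, s) in segs_b:
            if l <= a and b <= r:
                m |= s
        if m and m != full_mask:
            if out and out[-1][1] == a and out[-1][2] == m:
                out[-1] = (out[-1][0], b, m)
            else:
                out.append((a, b, m))
    return out


def simulate_haplotypes(pop: PopulationModel, rate_map: RateMap, n: int,
                        seed: int) -> SimulatedSample:
    """Draw ``n`` haplotypes from the coalescent with recombination.

    Recombination breakpoints are placed by inverse-CDF on the cumulative
    rate map restricted to each lineage's ancestral span; mutations follow
    the infinite-sites model at ``pop.theta`` per site per 4N_e generations.
    """
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    L = float(rate_map.region_length)
    rng = np.random.default_rng(seed)
    full_mask = (1 << n) - 1
    lineages = [[(0.0, L, 1 << i)] for i in range(n)]
    exposure: dict = {}  # (left, right, mask) -> total branch duration

    while lineages:
        k = len(lineages)
        spans = [(segs[0][0], segs[-1][1]) for segs in lineages]
        rec_rates = 0.5 * np.array(
            [rate_map.integral(a, b) for (a, b) in spans])
        total_rec = float(rec_rates.sum())
        coal = k * (k - 1) / 2.0
        total = coal + total_rec
        dt = rng.exponential(1.0 / total)
        for segs in lineages:
            for seg in segs:
                exposure[seg] = exposure.get(seg, 0.0) + dt
        if rng.random() < coal / total:
            i, j = rng.choice(k, size=2, replace=False)
            merged = _merge_segments(lineages[i], lineages[j], full_mask)
            for idx in sorted((int(i), int(j)), reverse=True):
                lineages.pop(idx)
            if merged:
                lineages.append(merged)
        else:
            i = int(rng.choice(k, p=rec_rates / total_rec))
            a, b = spans[i]
            u = rate_map.cumulative(a) + rng.random() * float(
                rate_map.integral(a, b))
            bp = rate_map.inverse_cumulative(float(u))
            left, right = [], []
            for (l, r, m) in lineages[i]:
                if r <= bp:
                    left.append((l, r, m))
                elif l >= bp:
                    right.append((l, r, m))
                else:
                    left.append((l, bp, m))
                    right.append((bp, r, m))
            new = [segs for segs in (left, right) if segs]
            lineages.pop(i)
            lineages.extend(new)

    # infinite-sites mutation dropping on accumulated branch segments
    sites: list[tuple[float, int]] = []
    theta = pop.theta
    for (l, r, m), dur in exposure.items():
        lam = 0.5 * theta * dur * (r - l)
        for _ in range(rng.poisson(lam)):
            sites.append((l + rng.random() * (r - l), m))
    sites.sort()
    positions, masks = [], []
    for pos, m in sites:
        bp = int(pos) + 1  # 1-based bp
        if positions and bp == positions[-1]:
            continue  # rounding collision; drop (infinite sites in bp)
        positions.append(bp)
        masks.append(m)
    hap = np.zeros((n, len(positions)), dtype=np.int8)
    for j, m in enumerate(masks):
        for i in range(n):
            if m >> i & 1:
                hap[i, j] = 1
    return SimulatedSample(hap, np.array(positions, dtype=np.int64),
                           rate_map, theta, seed)


# ---------------------------------------------------------------------------
# Array-style marker ascertainment and degradation

def ascertain_markers(sample: SimulatedSample, min_maf: float = 0.1,
                      target_density: float = 80.0, seed: int = 0,
                      chromosome: str = "sim",
                      region_start: int = 1) -> GenotypeMatrix:
    """Emulate array SNP ascertainment: drop sites below the sample-MAF
    threshold, thin uniformly at random to ``target_density`` markers/Mb,
    then pair haplotypes (1,2),(3,4),... into diploid genotypes."""
    if sample.n_sites == 0:
        raise ValueError("sample has no segregating sites")
    freq = sample.haplotypes.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.where(maf >= min_maf)[0]
    if keep.size == 0:
        raise ValueError("no site survives the MAF filter")
    target = int(round(target_density * sample.true_rate_map.region_length / 1e6))
    rng = np.random.default_rng(seed)
    if keep.size > target:
        keep = np.sort(rng.choice(keep, size=target, replace=False))
    hap = sample.haplotypes[:, keep]
    if sample.n % 2:
        raise ValueError("need an even haplotype count to form diploids")
    calls = (hap[0::2] + hap[1::2]).T.astype(np.int8)  # (k, n_ind)
    positions = sample.site_positions[keep] + (region_start - 1)
    markers = MarkerSet(chromosome, positions,
                        region_start,
                        region_start + int(sample.true_rate_map.region_length) - 1)
    samples = tuple(f"ind{i + 1}" for i in range(sample.n // 2))
    hap_rows = np.ascontiguousarray(hap)
    return GenotypeMatrix(markers, samples, calls, hap_rows)


def degrade_genotypes(g: GenotypeMatrix, missing_rate: float,
                      seed: int) -> GenotypeMatrix:
    """Independently set each call to missing with probability
    ``missing_rate`` (emulates genotyping failures)."""
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0, 1)")
    if missing_rate == 0:
        return g
    rng = np.random.default_rng(seed)
    mask = rng.random(g.calls.shape) < missing_rate
    calls = np.where(mask, MISSING, g.calls).astype(np.int8)
    return GenotypeMatrix(g.markers, g.samples, calls, None)


@dataclass(frozen=True)
class StudyPreset:
    """Default study-emulation conditions: 22 diploids, 850 kb region,
    ~70 markers with MAF >= 0.1, background ~200 rho/Mb."""

    n_haplotypes: int = 44
    region_length: float = 850_000.0
    theta: float = 5e-4
    background_rho_per_mb: float = 200.0
    target_density: float = 82.0  # markers/Mb -> ~70 per 850 kb
    min_maf: float = 0.1
    hotspots: tuple = ()


def simulate_study_region(preset: StudyPreset = StudyPreset(), seed: int = 1,
                          chromosome: str = "sim",
                          region_start: int = 1) -> tuple[GenotypeMatrix, SimulatedSample]:
    """One study-like region: simulate, ascertain, return genotypes + truth."""
    rate_map = RateMap(preset.region_length, preset.background_rho_per_mb,
                       preset.hotspots)
    pop = PopulationModel(theta=preset.theta)
    sample = simulate_haplotypes(pop, rate_map, preset.n_haplotypes, seed)
    g = ascertain_markers(sample, preset.min_maf, preset.target_density,
                          seed=seed + 1, chromosome=chromosome,
                          region_start=region_start)
    return g, sample


# ---------------------------------------------------------------------------
# Summary statistics used by validation suites

def segregating_sites(hap: np.ndarray) -> int:
    freq = hap.mean(axis=0)
    return int(np.sum((freq > 0) & (freq < 1)))


def pairwise_diversity(hap: np.ndarray) -> float:
    """Mean pairwise difference count (sum over sites of 2p(1-p)n/(n-1))."""
    n = hap.shape[0]
    p = hap.mean(axis=0)
    return float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))


def site_frequency_spectrum(hap: np.ndarray) -> np.ndarray:
    """Counts of derived-allele multiplicities 1..n-1."""
    n = hap.shape[0]
    counts = hap.sum(axis=0)
    return np.bincount(counts, minlength=n + 1)[1:n]


def four_gamete_violations(hap: np.ndarray) -> np.ndarray:
    """Boolean matrix: pair (i, j) of sites shows all four gametes."""
    h = hap.astype(bool)
    S = h.shape[1]
    out = np.zeros((S, S), dtype=bool)
    g00 = (~h[:, :, None] & ~h[:, None, :]).any(axis=0)
    g01 = (~h[:, :, None] & h[:, None, :]).any(axis=0)
    g10 = (h[:, :, None] & ~h[:, None, :]).any(axis=0)
    g11 = (h[:, :, None] & h[:, None, :]).any(axis=0)
    out = g00 & g01 & g10 & g11
    np.fill_diagonal(out, False)
    return out
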