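"""SNP genotype containers, readers, filters and block partitioning.

Genotypes are diploid alternate-allele dosages in {0, 1, 2} with -1 for
missing, held as a markers x individuals integer matrix.  Marker positions
are 1-based inclusive assembly coordinates (the convention of genome-browser
tables); interval arithmetic downstream converts to 0-based half-open at
module boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


class EmptyRegionError(ValueError):
    """All markers removed: the region is unusable for inference."""


@dataclass(frozen=True)
class MarkerSet:
    """Ordered SNP marker positions within one chromosomal region.

    Parameters
    ----------
    chromosome : str
        Chromosome label, e.g. ``"A1"`` or ``"chrE2"``.
    positions : ndarray of int
        Strictly increasing 1-based bp coordinates, length ``k``.
    region_start, region_end : int
        1-based inclusive bounds of the analysed region.  Default to the
        first/last marker position.
    unique_mapping : ndarray of bool, optional
        Per-marker flag: marker maps to a single chromosomal location.
    """

    chromosome: str
    positions: np.ndarray
    region_start: int = 0
    region_end: int = 0
    unique_mapping: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if self.region_start == 0:
            object.__setattr__(self, "region_start", int(pos[0]) if pos.size else 1)
        if self.region_end == 0:
            object.__setattr__(self, "region_end", int(pos[-1]) if pos.size else 1)
        if pos.size and not (self.region_start <= pos[0] and pos[-1] <= self.region_end):
            raise ValueError("markers fall outside the declared region")
        um = self.unique_mapping
        um = np.ones(pos.size, bool) if um is None else np.asarray(um, bool)
        if um.size != pos.size:
            raise ValueError("unique_mapping length mismatch")
        object.__setattr__(self, "unique_mapping", um)

    @property
    def k(self) -> int:
        return int(self.positions.size)

    @property
    def inter_marker_distances(self) -> np.ndarray:
        """d_i = x_{i+1} - x_i in bp, length k-1."""
        return np.diff(self.positions)

    @property
    def region_size(self) -> int:
        return int(self.region_end - self.region_start)

    def subset(self, keep: np.ndarray) -> "MarkerSet":
        return MarkerSet(self.chromosome, self.positions[keep],
                         self.region_start, self.region_end,
                         self.unique_mapping[keep])


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid genotype calls for a set of markers and individuals."""

    markers: MarkerSet
    samples: tuple
    calls: np.ndarray  # (k, n_individuals) int8, -1 = missing
    haplotypes: np.ndarray = None  # type: ignore[assignment]  # (2n, k) in {0,1}

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.shape != (self.markers.k, len(self.samples)):
            raise ValueError("calls must be (k, n_individuals)")
        if not np.all(np.isin(calls, [MISSING, 0, 1, 2])):
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "samples", tuple(self.samples))
        if self.haplotypes is not None:
            hap = np.asarray(self.haplotypes, dtype=np.int8)
            geno = hap[0::2] + hap[1::2]
            obs = calls.T
            ok = (obs == MISSING) | (geno == obs)
            if not np.all(ok):
                raise ValueError("haplotype pair sums do not reproduce genotype calls")
            object.__setattr__(self, "haplotypes", hap)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return (self.calls != MISSING).mean(axis=1)

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, from non-missing calls only."""
        obs = np.ma.masked_equal(self.calls, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = obs.sum(axis=1) / (2.0 * obs.count(axis=1))
        p = np.asarray(p.filled(np.nan), float)
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        hap = None if self.haplotypes is None else self.haplotypes[:, keep]
        return GenotypeMatrix(self.markers.subset(keep), self.samples,
                              self.calls[keep], hap)

    def to_haplotypes(self, seed: int) -> np.ndarray:
        """Resolve unphased genotypes to 2n haplotypes by random phasing.

        Heterozygotes are phased at random; missing calls are filled with
        seeded Bernoulli draws from the marker's sample allele frequency.
        Both choices are stand-ins for unavailable phase information and a
        caveat is logged.
        """
        if self.haplotypes is not None:
            return self.haplotypes
        rng = np.random.default_rng(seed)
        k, n = self.calls.shape
        obs = np.ma.masked_equal(self.calls, MISSING)
        p_alt = np.asarray((obs.sum(axis=1) / (2.0 * obs.count(axis=1))).filled(0.5))
        hap = np.zeros((2 * n, k), dtype=np.int8)
        for j in range(k):
            for i in range(n):
                g = self.calls[j, i]
                if g == MISSING:
                    draws = rng.random(2) < p_alt[j]
                    hap[2 * i, j], hap[2 * i + 1, j] = draws.astype(np.int8)
                elif g == 1:
                    a = int(rng.integers(2))
                    hap[2 * i + a, j], hap[2 * i + 1 - a, j] = 1, 0
                else:
                    hap[2 * i, j] = hap[2 * i + 1, j] = g // 2
        n_miss = int((self.calls == MISSING).sum())
        logger.info("random phasing (seed=%d): %d heterozygote sites phased at "
                    "random, %d missing calls imputed from allele frequencies",
                    seed, int((self.calls == 1).sum()), n_miss)
        return hap


@dataclass(frozen=True)
class BlockPartition:
    """Contiguous marker blocks; every block except possibly the last holds
    ``block_size_target`` markers (a short remainder is merged back)."""

    block_sizes: tuple
    block_size_target: int = 20

    @property
    def block_assignments(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)


def partition_blocks(markers: MarkerSet, block_size: int = 20,
                     min_remainder: int = 5) -> BlockPartition:
    """Split ``k`` markers into contiguous blocks of ``block_size``.

    The remainder forms its own final block unless shorter than
    ``min_remainder`` markers, in which case it is merged into the preceding
    block (a 1-SNP block carries no recombination information).
    """
    k = markers.k
    if k < 2:
        raise ValueError("need at least 2 markers")
    n_full, rem = divmod(k, block_size)
    sizes = [block_size] * n_full
    if rem:
        if sizes and rem < min_remainder:
            sizes[-1] += rem
        else:
            sizes.append(rem)
    return BlockPartition(tuple(sizes), block_size)


@dataclass(frozen=True)
class FilterReport:
    """Counts of markers removed, attributed in order
    unique-mapping -> call rate -> MAF."""

    n_in: int
    n_out: int
    removed_unique_mapping: int
    removed_call_rate: int
    removed_maf: int

    def as_dict(self) -> dict:
        return {"unique_mapping": self.removed_unique_mapping,
                "call_rate": self.removed_call_rate,
                "maf": self.removed_maf}


def apply_filters(g: GenotypeMatrix, min_call_rate: float = 0.8,
                  min_maf: float = 0.1) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain markers that map uniquely, have call rate >= ``min_call_rate``
    and sample MAF >= ``min_maf`` (thresholds inclusive).

    Raises
    ------
    EmptyRegionError
        If no marker survives.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    um = g.markers.unique_mapping
    cr_ok = g.call_rate >= min_call_rate
    maf = g.maf
    maf_ok = np.where(np.isnan(maf), False, maf >= min_maf)
    keep = um & cr_ok & maf_ok
    n_um = int((~um).sum())
    n_cr = int((um & ~cr_ok).sum())
    n_maf = int((um & cr_ok & ~maf_ok).sum())
    report = FilterReport(g.markers.k, int(keep.sum()), n_um, n_cr, n_maf)
    if not keep.any():
        raise EmptyRegionError(
            f"all {g.markers.k} markers removed by filters; region unusable")
    return g.subset_markers(keep), report


# ---------------------------------------------------------------------------
# Readers

#: TSV dialect: columns chrom, pos, ref, alt, then one column per sample
#: holding 0/1/2 alternate-allele dosages or NA.
TSV_FIXED_COLUMNS = ("chrom", "pos", "ref", "alt")


def _finalize(chrom, positions, calls, samples, region=None) -> GenotypeMatrix:
    positions = np.asarray(positions, dtype=np.int64)
    calls = np.asarray(calls, dtype=np.int8)
    order = np.argsort(positions, kind="stable")
    if not np.array_equal(order, np.arange(positions.size)):
        warnings.warn("input markers were not position-sorted; sorting",
                      stacklevel=3)
        positions, calls = positions[order], calls[order]
    if positions.size and np.any(np.diff(positions) == 0):
        dup = positions[np.where(np.diff(positions) == 0)[0][0]]
        raise ValueError(f"duplicate marker position {dup}")
    if region is not None:
        lo, hi = region
        keep = (positions >= lo) & (positions <= hi)
        positions, calls = positions[keep], calls[keep]
        ms = MarkerSet(chrom, positions, lo, hi)
    else:
        ms = MarkerSet(chrom, positions)
    return GenotypeMatrix(ms, samples, calls)


def read_genotypes_tsv(path, region: tuple[int, int] | None = None) -> GenotypeMatrix:
    """Read the package's genotype TSV dialect (see :data:`TSV_FIXED_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = set(TSV_FIXED_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"TSV missing required columns: {sorted(missing_cols)}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("genotype TSV must contain a single chromosome")
    samples = tuple(c for c in df.columns if c not in TSV_FIXED_COLUMNS)
    calls = df[list(samples)].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return _finalize(str(chroms[0]), df["pos"].to_numpy(), calls, samples, region)


def read_genotypes_vcf(path, region: tuple[int, int] | None = None) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF; multi-allelic records are skipped
    with a logged count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = tuple(vcf.samples)
    positions, rows, chrom = [], [], None
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom = rec.CHROM if chrom is None else chrom
        if rec.CHROM != chrom:
            raise ValueError("VCF must contain a single chromosome region")
        positions.append(rec.POS)
        gt = rec.gt_types.astype(np.int8)  # 0,1,2,3=unknown under gts012
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)
    if not positions:
        raise EmptyRegionError("no biallelic SNVs in VCF")
    return _finalize(chrom, positions, np.array(rows), samples, region)


def read_genotypes(path, region: tuple[int, int] | None = None) -> GenotypeMatrix:
    """Dispatch on file extension: ``.vcf``/``.vcf.gz`` else TSV dialect."""
    s = str(path)
    if s.endswith((".vcf", ".vcf.gz")):
        return read_genotypes_vcf(path, region)
    return read_genotypes_tsv(path, region)


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame({"chrom": g.markers.chromosome,
                       "pos": g.markers.positions,
                       "ref": "A", "alt": "G"})
    for i, s in enumerate(g.samples):
        col = g.calls[:, i].astype(object)
        df[s] = [("NA" if v == MISSING else int(v)) for v in col]
    df.to_csv(path, sep="\t", index=False)
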