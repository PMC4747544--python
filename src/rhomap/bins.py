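"""Binned hotspot probabilities, Bayes factors, hotspot calls and rate
summaries.

The region is tiled with 200-bp bins.  For each bin j the posterior
probability p_j is the fraction of posterior samples in which some hotspot
interval overlaps the bin, and q_j is the same quantity under the prior
(constant-likelihood) chain.  The Bayes factor for a hotspot in bin j is the
posterior-to-prior odds ratio

    BF_j = [p_j / (1 - p_j)] / [q_j / (1 - q_j)],

with p and q clamped away from {0, 1} by epsilon = 1/(2M) for M samples,
since prior chains commonly yield q_j = 0.  A hotspot call is a maximal run
of at least two consecutive bins with BF >= 100; all other bins are
"neutral".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BinTrack:
    """Per-bin hotspot probabilities over a tiled region.

    ``starts``/``ends`` are region-relative 0-based half-open bp intervals;
    the final bin may be partial (flagged).  ``p`` and ``q`` are posterior
    and prior occupancy probabilities; ``bf`` the per-bin Bayes factors.
    """

    bin_width: int
    starts: np.ndarray
    ends: np.ndarray
    p: np.ndarray
    q: np.ndarray = None  # type: ignore[assignment]
    bf: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("starts", "ends", "p"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), float))
        if not (self.p.size == self.starts.size == self.ends.size):
            raise ValueError("track arrays must have equal length")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p out of [0, 1]")

    @property
    def n_bins(self) -> int:
        return int(self.starts.size)

    @property
    def partial_final_bin(self) -> bool:
        return bool(self.n_bins
                    and (self.ends[-1] - self.starts[-1]) < self.bin_width)

    def with_prior(self, q: np.ndarray, n_posterior: int,
                   n_prior: int) -> "BinTrack":
        """Attach prior probabilities and compute per-bin Bayes factors."""
        q = np.asarray(q, float)
        if q.size != self.n_bins:
            raise ValueError("prior track length mismatch")
        bf = bayes_factor(self.p, q, min(n_posterior, n_prior))
        return BinTrack(self.bin_width, self.starts, self.ends, self.p, q, bf)

    def to_frame(self, chromosome: str = "region",
                 region_start: int = 1) -> pd.DataFrame:
        off = region_start - 1
        return pd.DataFrame({
            "chrom": chromosome,
            "start": (self.starts + off).astype(int),
            "end": (self.ends + off).astype(int),
            "p": self.p,
            "q": self.q if self.q is not None else np.nan,
            "bf": self.bf if self.bf is not None else np.nan,
        })


def tile_bins(region_length: float, bin_width: int = 200):
    """0-based half-open bins starting at 0; final partial bin kept."""
    edges = np.arange(0, float(region_length), bin_width, dtype=float)
    starts = edges
    ends = np.minimum(edges + bin_width, float(region_length))
    return starts, ends


def bin_probability(samples, region_length: float,
                    bin_width: int = 200) -> BinTrack:
    """Fraction of samples whose hotspot set overlaps each bin.

    Overlap is non-empty intersection of half-open intervals: a hotspot
    touching only a bin's end coordinate does not overlap it.
    """
    if not samples:
        raise ValueError("need at least one sample")
    starts, ends = tile_bins(region_length, bin_width)
    hits = np.zeros(starts.size)
    for s in samples:
        if not s.hotspots:
            continue
        covered = np.zeros(starts.size, bool)
        for h in s.hotspots:
            covered |= (starts < h.end) & (ends > h.start)
        hits += covered
    return BinTrack(bin_width, starts, ends, hits / len(samples))


def bayes_factor(p, q, n_samples: int):
    """Posterior-to-prior odds ratio with epsilon-clamping.

    p and q are clamped to [eps, 1 - eps] with eps = 1/(2*n_samples) so that
    empirical probabilities of exactly 0 or 1 give finite odds.
    """
    if n_samples < 1:
        raise ValueError("need n_samples >= 1")
    eps = 1.0 / (2.0 * n_samples)
    p = np.clip(np.asarray(p, float), eps, 1.0 - eps)
    q = np.clip(np.asarray(q, float), eps, 1.0 - eps)
    out = (p / (1.0 - p)) / (q / (1.0 - q))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HotspotCall:
    """Maximal run of >= 2 consecutive bins with BF >= threshold.

    Coordinates are the outer edges of the member bins (region-relative,
    0-based half-open).
    """

    start: float
    end: float
    n_bins: int
    mean_pp: float
    mean_bf: float

    @property
    def size(self) -> float:
        return self.end - self.start


def call_hotspots(track: BinTrack, bf_threshold: float = 100.0,
                  min_consecutive: int = 2) -> list[HotspotCall]:
    """Maximal runs of consecutive bins at or above the BF threshold."""
    if track.bf is None:
        raise ValueError("track has no Bayes factors; attach a prior first")
    hot = track.bf >= bf_threshold
    calls = []
    i = 0
    n = track.n_bins
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            if j - i + 1 >= min_consecutive:
                sl = slice(i, j + 1)
                calls.append(HotspotCall(
                    float(track.starts[i]), float(track.ends[j]),
                    j - i + 1, float(track.p[sl].mean()),
                    float(track.bf[sl].mean())))
            i = j + 1
        else:
            i += 1
    return calls


@dataclass(frozen=True)
class RateSummary:
    """Length-weighted mean population recombination rate of a region."""

    mean_rho_per_mb: float
    total_rho: float
    region_length_mb: float


def mean_rho(rho_per_interval, d) -> RateSummary:
    """rho_bar = sum(rho_i * d_i) / sum(d_i), the inter-marker rates
    weighted by inter-marker distances d_i (bp)."""
    rho = np.asarray(rho_per_interval, float)
    d = np.asarray(d, float)
    if rho.size != d.size:
        raise ValueError("rho and d must have equal length")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    d_mb = d / 1e6
    total = float(np.sum(rho * d_mb))
    length = float(d_mb.sum())
    return RateSummary(total / length, total, length)


def rho_to_cm_per_mb(rho_per_mb: float, n_e: float,
                     ploidy_factor: int = 4) -> float:
    """Convert a population-scaled rate to cM/Mb: c = rho/(ploidy*N_e)
    recombinations per Mb per generation, x100 for centiMorgans."""
    if n_e <= 0:
        raise ValueError("effective population size must be positive")
    return 100.0 * rho_per_mb / (ploidy_factor * n_e)


def posterior_mean_interval_rates(samples, markers) -> np.ndarray:
    """Posterior mean rho/Mb between consecutive markers.

    For each posterior sample the rate map is integrated over each
    inter-marker interval; the per-interval scaled rates (per Mb) are then
    averaged over samples.
    """
    x = (markers.positions - markers.region_start).astype(float)
    d = np.diff(x)
    acc = np.zeros(d.size)
    for s in samples:
        rates = np.full(d.size, s.background_rho_per_mb)
        for h in s.hotspots:
            ov = (np.minimum(x[1:], h.end) - np.maximum(x[:-1], h.start))
            rates += (s.background_rho_per_mb * (h.intensity - 1.0)
                      * np.clip(ov, 0.0, None) / d)
        acc += rates
    return acc / len(samples)
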