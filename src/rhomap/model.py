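"""Model/Results interface for recombination-map inference.

`RecombinationHotspotModel` wraps a filtered genotype matrix together with
the prior and likelihood-engine configuration; `fit()` runs the
reversible-jump MCMC plus the matching prior-only chain and returns a
`RecombinationHotspotResults` carrying posterior samples, the binned
posterior/prior/Bayes-factor track, hotspot calls, rate summaries and chain
diagnostics.

Typical use::

    g = read_genotypes("region.vcf")
    g, report = apply_filters(g)
    model = RecombinationHotspotModel(g, table=table)
    res = model.fit(iterations=20_000, seed=1)
    print(res.summary())
    calls = res.hotspot_calls()
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import bins as _bins
from .diagnostics import compute_ess
from .genotypes import GenotypeMatrix, apply_filters, read_genotypes
from .likelihood import CompositeLikelihood, TwoLocusTable, build_two_locus_table
from .mcmc import ChainSettings, PriorSpec, RJSampler, run_prior_chain


class RecombinationHotspotModel:
    """Bayesian background-plus-hotspot recombination map model.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Filtered genotype data for one region.
    prior : PriorSpec
        Priors on hotspot arrivals, widths, intensities, background, theta.
    table : TwoLocusTable, optional
        Pre-built two-locus lookup table for ``2 * n_individuals``
        haplotypes; built on demand (expensive) when omitted.
    max_pair_span : float
        Only marker pairs closer than this enter the composite likelihood.
    temperature : float
        Composite-likelihood tempering constant (see CompositeLikelihood).
    """

    def __init__(self, genotypes: GenotypeMatrix, prior: PriorSpec = None,
                 table: TwoLocusTable = None,
                 max_pair_span: float = 100_000.0, temperature: float = 10.0,
                 bin_width: int = 200, phasing_seed: int = 0,
                 table_reps: int = 10_000):
        self.genotypes = genotypes
        self.prior = prior if prior is not None else PriorSpec()
        self.max_pair_span = max_pair_span
        self.temperature = temperature
        self.bin_width = bin_width
        self.phasing_seed = phasing_seed
        self._table = table
        self._table_reps = table_reps

    @classmethod
    def from_file(cls, path, min_call_rate: float = 0.8,
                  min_maf: float = 0.1, **kwargs):
        """Read genotypes (VCF or TSV dialect), apply the three marker
        filters, and build the model."""
        g = read_genotypes(path)
        g, _ = apply_filters(g, min_call_rate, min_maf)
        return cls(g, **kwargs)

    @property
    def region_length(self) -> float:
        return float(self.genotypes.markers.region_size)

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.genotypes.n_individuals

    def table(self) -> TwoLocusTable:
        if self._table is None:
            self._table = build_two_locus_table(
                self.n_haplotypes, reps=self._table_reps, min_maf=0.1)
        return self._table

    def engine(self) -> CompositeLikelihood:
        return CompositeLikelihood(self.genotypes, self.table(),
                                   self.max_pair_span, self.phasing_seed,
                                   self.temperature)

    def fit(self, iterations: int = 20_000, seed: int = 0,
            n_chains: int = 2, settings: ChainSettings = None,
            prior_iterations: int = None) -> "RecombinationHotspotResults":
        """Run ``n_chains`` independent posterior chains (seeds derived from
        ``seed``) and one prior-only chain, and assemble results."""
        engine = self.engine()
        base = settings if settings is not None else ChainSettings(
            iterations=iterations, seed=seed)
        all_samples, diags = [], []
        for c in range(n_chains):
            s = replace(base, seed=base.seed + 1000 * c)
            sampler = RJSampler(engine, self.region_length, self.prior, s)
            samples, diag = sampler.run()
            all_samples.append(samples)
            diags.append(diag)
        prior_settings = replace(
            base, iterations=prior_iterations or base.iterations,
            seed=base.seed + 99_991)
        prior_samples, prior_diag = run_prior_chain(
            self.region_length, self.prior, prior_settings)
        return RecombinationHotspotResults(self, engine, all_samples,
                                           prior_samples, diags, prior_diag)


@dataclass
class RecombinationHotspotResults:
    """Posterior summaries of a fitted recombination-map model."""

    model: RecombinationHotspotModel
    engine: CompositeLikelihood
    chains: list
    prior_samples: list
    diagnostics: list
    prior_diagnostics: object

    @property
    def posterior_samples(self) -> list:
        return [s for chain in self.chains for s in chain]

    # -- parameter traces and summaries ---------------------------------
    def trace(self, param: str) -> np.ndarray:
        getter = {"background": lambda s: s.background_rho_per_mb,
                  "theta": lambda s: s.theta,
                  "n_hotspots": lambda s: float(len(s.hotspots))}[param]
        return np.array([getter(s) for s in self.posterior_samples])

    def posterior_mean(self, param: str) -> float:
        return float(self.trace(param).mean())

    def ess(self, param: str = "background") -> float:
        # conservative: ESS per chain summed (chains are independent)
        out = 0.0
        for chain in self.chains:
            getter = {"background": lambda s: s.background_rho_per_mb,
                      "theta": lambda s: s.theta,
                      "n_hotspots": lambda s: float(len(s.hotspots))}[param]
            out += compute_ess([getter(s) for s in chain])
        return out

    # -- tracks, calls, rates --------------------------------------------
    def bin_track(self) -> _bins.BinTrack:
        """Posterior/prior occupancy and Bayes factor per 200-bp bin,
        averaged over chains (p_j is linear in the sample set)."""
        track = _bins.bin_probability(self.posterior_samples,
                                      self.model.region_length,
                                      self.model.bin_width)
        prior_track = _bins.bin_probability(self.prior_samples,
                                            self.model.region_length,
                                            self.model.bin_width)
        return track.with_prior(prior_track.p, len(self.posterior_samples),
                                len(self.prior_samples))

    def hotspot_calls(self, bf_threshold: float = 100.0,
                      min_consecutive: int = 2) -> list:
        return _bins.call_hotspots(self.bin_track(), bf_threshold,
                                   min_consecutive)

    def interval_rates(self) -> np.ndarray:
        """Posterior-mean rho/Mb between consecutive markers."""
        return _bins.posterior_mean_interval_rates(
            self.posterior_samples, self.model.genotypes.markers)

    def rate_summary(self) -> _bins.RateSummary:
        m = self.model.genotypes.markers
        return _bins.mean_rho(self.interval_rates(),
                              m.inter_marker_distances)

    def hotspot_table(self) -> pd.DataFrame:
        m = self.model.genotypes.markers
        rows = []
        for c in self.hotspot_calls():
            rows.append({
                "start": int(c.start + m.region_start),
                "end": int(c.end + m.region_start),
                "size_kb": round(c.size / 1000.0, 1),
                "n_bins": c.n_bins,
                "mean_pp": round(c.mean_pp, 2),
                "mean_bf": round(c.mean_bf, 2)})
        return pd.DataFrame(rows, columns=["start", "end", "size_kb",
                                           "n_bins", "mean_pp", "mean_bf"])

    def summary(self) -> str:
        m = self.model.genotypes.markers
        bg = self.trace("background")
        th = self.trace("theta")
        nh = self.trace("n_hotspots")
        rs = self.rate_summary()
        calls = self.hotspot_calls()
        lines = [
            "Recombination hotspot model (reversible-jump MCMC)",
            "=" * 52,
            f"region: {m.chromosome}:{m.region_start}-{m.region_end} "
            f"({m.region_size} bp), {m.k} markers, "
            f"{self.model.genotypes.n_individuals} individuals",
            f"chains: {len(self.chains)} x {len(self.chains[0])} samples "
            f"(post burn-in), prior chain: {len(self.prior_samples)} samples",
            f"composite pairs: {self.engine.n_pairs} "
            f"(span <= {self.model.max_pair_span:.0f} bp, "
            f"temperature {self.model.temperature:g})",
            "-" * 52,
            f"background rho/Mb : {bg.mean():9.2f} (sd {bg.std():.2f}, "
            f"ESS {self.ess('background'):.0f})",
            f"theta per site    : {th.mean():9.6f} (sd {th.std():.6f})",
            f"hotspot count     : {nh.mean():9.2f} (P>=1: "
            f"{(nh >= 1).mean():.2f})",
            f"mean rho/Mb (map) : {rs.mean_rho_per_mb:9.2f}",
            f"hotspot calls (BF>=100, >=2 bins): {len(calls)}",
        ]
        for c in calls:
            lines.append(
                f"  {int(c.start + m.region_start)}-"
                f"{int(c.end + m.region_start)}  size {c.size/1000:.1f} kb  "
                f"bins {c.n_bins}  PP {c.mean_pp:.2f}  BF {c.mean_bf:.1f}")
        return "\n".join(lines)

    def plot_tracks(self, true_hotspots=()):
        """Three-panel figure: posterior rate, hotspot probability and
        log10 Bayes factor along the region (marker rug at bottom)."""
        import matplotlib.pyplot as plt

        m = self.model.genotypes.markers
        track = self.bin_track()
        x = 0.5 * (track.starts + track.ends) / 1000.0
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(9, 7))
        mid = 0.5 * (m.positions[:-1] + m.positions[1:]
                     - 2 * m.region_start) / 1000.0
        axes[0].step(mid, self.interval_rates(), where="mid")
        axes[0].set_ylabel(r"$\rho$/Mb")
        axes[1].plot(x, track.p)
        axes[1].set_ylabel(r"$p_j$")
        axes[2].plot(x, np.log10(np.maximum(track.bf, 1e-3)))
        axes[2].axhline(2.0, ls=":", color="grey")
        axes[2].set_ylabel(r"$\log_{10}$ BF")
        axes[2].set_xlabel("position (kb)")
        for ax in axes:
            for h in true_hotspots:
                ax.axvspan(h.start / 1000.0, h.end / 1000.0, alpha=0.2,
                           color="red")
        axes[2].plot((m.positions - m.region_start) / 1000.0,
                     np.full(m.k, axes[2].get_ylim()[0]), "|", ms=4,
                     color="k")
        fig.tight_layout()
        return fig
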