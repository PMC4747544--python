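"""End-to-end orchestration: filter -> infer -> prior-chain -> call ->
annotate -> report, with a resolved-config + seeds audit trail.

The configuration is a flat YAML document with one section per stage;
unknown keys are rejected (silent threshold typos are the main
reproducibility hazard).  Every stochastic stage takes its seed from the
single top-level seed.  All artifacts land in a run directory:

    run/
      config.resolved.yaml   filter_report.tsv   posterior_samples.tsv
      bin_track.tsv          bin_track.bedgraph  hotspot_calls.tsv
      hotspot_calls.bed      region_summary.tsv  run_metadata.json
      annotation.tsv         annotation_summary.json   (with FASTA/repeats)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as _ann
from . import reporting
from .genotypes import apply_filters, partition_blocks, read_genotypes
from .likelihood import build_two_locus_table, default_rho_grid
from .mcmc import ChainSettings, PriorSpec
from .model import RecombinationHotspotModel
from .simulate import Hotspot, StudyPreset, simulate_study_region

logger = logging.getLogger(__name__)


def _section(cls, data: dict, name: str):
    data = data or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RegionConfig:
    chrom: str = "sim"
    start: int = 1
    end: int = None  # type: ignore[assignment]


@dataclass(frozen=True)
class InputConfig:
    genotypes: str = None  # type: ignore[assignment]
    fasta: str = None  # type: ignore[assignment]
    repeats: str = None  # type: ignore[assignment]


@dataclass(frozen=True)
class SimulateConfig:
    preset: bool = True
    n_haplotypes: int = 44
    region_length: float = 850_000.0
    theta: float = 5e-4
    background_rho_per_mb: float = 200.0
    target_density: float = 82.0
    min_maf: float = 0.1
    hotspots: tuple = ()  # list of [start, end, intensity]


@dataclass(frozen=True)
class FilterConfig:
    min_call_rate: float = 0.8
    min_maf: float = 0.1
    block_size: int = 20


@dataclass(frozen=True)
class LikelihoodConfig:
    max_pair_span: float = 100_000.0
    temperature: float = 10.0
    table_reps: int = 10_000
    rho_max: float = 256.0
    table_cache: str = None  # type: ignore[assignment]


@dataclass(frozen=True)
class ChainConfig:
    iterations: int = 20_000
    n_chains: int = 2
    burn_in_fraction: float = 0.5
    thin: int = None  # type: ignore[assignment]


@dataclass(frozen=True)
class CallingConfig:
    bin_width: int = 200
    bf_threshold: float = 100.0
    min_consecutive: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    region: RegionConfig = field(default_factory=RegionConfig)
    inputs: InputConfig = field(default_factory=InputConfig)
    simulate: SimulateConfig = None  # type: ignore[assignment]
    filters: FilterConfig = field(default_factory=FilterConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    likelihood: LikelihoodConfig = field(default_factory=LikelihoodConfig)
    chain: ChainConfig = field(default_factory=ChainConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {"seed", "region", "inputs", "simulate", "filters", "prior",
                 "likelihood", "chain", "calling"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config must set a top-level seed")
        return cls(
            seed=int(data["seed"]),
            region=_section(RegionConfig, data.get("region"), "region"),
            inputs=_section(InputConfig, data.get("inputs"), "inputs"),
            simulate=(_section(SimulateConfig, data["simulate"], "simulate")
                      if "simulate" in data and data["simulate"] is not None
                      else None),
            filters=_section(FilterConfig, data.get("filters"), "filters"),
            prior=_section(PriorSpec, data.get("prior"), "prior"),
            likelihood=_section(LikelihoodConfig, data.get("likelihood"),
                                "likelihood"),
            chain=_section(ChainConfig, data.get("chain"), "chain"),
            calling=_section(CallingConfig, data.get("calling"), "calling"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        return {"seed": self.seed, "region": enc(self.region),
                "inputs": enc(self.inputs),
                "simulate": enc(self.simulate) if self.simulate else None,
                "filters": enc(self.filters), "prior": enc(self.prior),
                "likelihood": enc(self.likelihood), "chain": enc(self.chain),
                "calling": enc(self.calling)}


def _obtain_genotypes(config: PipelineConfig):
    """Read genotypes from file or simulate the study preset."""
    truth = None
    if config.inputs.genotypes:
        g = read_genotypes(config.inputs.genotypes)
    elif config.simulate is not None:
        sim = config.simulate
        hs = tuple(Hotspot(*h) for h in (sim.hotspots or ()))
        preset = StudyPreset(sim.n_haplotypes, sim.region_length, sim.theta,
                             sim.background_rho_per_mb, sim.target_density,
                             sim.min_maf, hs)
        g, truth = simulate_study_region(preset, seed=config.seed,
                                         chromosome=config.region.chrom,
                                         region_start=config.region.start)
    else:
        raise ValueError("config needs either inputs.genotypes or a "
                         "[simulate] section")
    return g, truth


def _get_table(config: PipelineConfig, n_haplotypes: int):
    import pickle

    lk = config.likelihood
    if lk.table_cache:
        cache = Path(lk.table_cache)
        key = (f"n{n_haplotypes}_reps{lk.table_reps}_rmax{lk.rho_max:g}"
               f"_maf{config.filters.min_maf:g}.pkl")
        path = cache / key
        if path.exists():
            with open(path, "rb") as fh:
                return pickle.load(fh)
    table = build_two_locus_table(
        n_haplotypes, grid=default_rho_grid(lk.rho_max), reps=lk.table_reps,
        seed=config.seed + 7, min_maf=config.filters.min_maf)
    if lk.table_cache:
        cache.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(table, fh)
    return table


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns a dict of output paths and summaries."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    # -- filter ----------------------------------------------------------
    g_raw, truth = _obtain_genotypes(config)
    g, report = apply_filters(g_raw, config.filters.min_call_rate,
                              config.filters.min_maf)
    blocks = partition_blocks(g.markers, config.filters.block_size)
    pd.DataFrame([{"markers_in": report.n_in, "markers_out": report.n_out,
                   **report.as_dict(),
                   "block_sizes": ",".join(map(str, blocks.block_sizes))}]
                 ).to_csv(out / "filter_report.tsv", sep="\t", index=False)

    # -- infer + prior chain --------------------------------------------
    table = _get_table(config, 2 * g.n_individuals)
    model = RecombinationHotspotModel(
        g, prior=config.prior, table=table,
        max_pair_span=config.likelihood.max_pair_span,
        temperature=config.likelihood.temperature,
        bin_width=config.calling.bin_width, phasing_seed=config.seed + 13)
    settings = ChainSettings(iterations=config.chain.iterations,
                             seed=config.seed,
                             thin=config.chain.thin,
                             burn_in_fraction=config.chain.burn_in_fraction)
    res = model.fit(settings=settings, n_chains=config.chain.n_chains)

    rows = []
    for ci, chain in enumerate(res.chains):
        for s in chain:
            rows.append({
                "chain": ci, "iteration": s.iteration, "theta": s.theta,
                "background_rho_per_mb": s.background_rho_per_mb,
                "hotspots": ";".join(
                    f"{h.start:.0f}:{h.end:.0f}:{h.intensity:.2f}"
                    for h in s.hotspots)})
    pd.DataFrame(rows).to_csv(out / "posterior_samples.tsv", sep="\t",
                              index=False)

    # -- call ------------------------------------------------------------
    track = res.bin_track()
    chrom = g.markers.chromosome
    tdf = track.to_frame(chrom, g.markers.region_start)
    tdf.to_csv(out / "bin_track.tsv", sep="\t", index=False)
    bed = tdf.copy()
    bed["start"] -= 1  # BED is 0-based half-open
    bed[["chrom", "start", "end", "bf"]].to_csv(
        out / "bin_track.bedgraph", sep="\t", index=False, header=False)
    calls = res.hotspot_calls(config.calling.bf_threshold,
                              config.calling.min_consecutive)
    call_df = res.hotspot_table()
    call_df.insert(0, "chrom", chrom)
    call_df.to_csv(out / "hotspot_calls.tsv", sep="\t", index=False)
    with open(out / "hotspot_calls.bed", "w") as fh:
        for c in calls:
            fh.write(f"{chrom}\t{int(c.start + g.markers.region_start - 1)}"
                     f"\t{int(c.end + g.markers.region_start - 1)}\t"
                     f"hotspot\t{c.mean_bf:.1f}\n")

    # -- report ----------------------------------------------------------
    summary_row = reporting.inferred_region_summary(
        chrom, g.markers, res.interval_rates(), track)
    pd.DataFrame([summary_row]).to_csv(out / "region_summary.tsv", sep="\t",
                                       index=False)
    meta = {
        "seed": config.seed,
        "n_markers_raw": g_raw.markers.k, "n_markers": g.markers.k,
        "block_sizes": list(blocks.block_sizes),
        "acceptance_rates": [
            {k: (None if np.isnan(v) else round(v, 4))
             for k, v in d.acceptance_rates().items()}
            for d in res.diagnostics],
        "ess_background": res.ess("background"),
        "n_pairs": res.engine.n_pairs,
        "n_clamped_last_eval": res.engine.n_clamped_last,
        "mean_rho_per_mb": summary_row["mean_rho_per_mb"],
        "n_hotspot_calls": len(calls),
    }
    if truth is not None:
        meta["true_background_rho_per_mb"] = (
            truth.true_rate_map.background_rho_per_mb)
        meta["true_hotspots"] = [[h.start, h.end, h.intensity]
                                 for h in truth.true_rate_map.hotspots]
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)

    # -- annotate (optional) --------------------------------------------
    if config.inputs.fasta:
        seq = _ann.read_region_fasta(config.inputs.fasta)
        elements = (_ann.parse_repeat_table(config.inputs.repeats)
                    if config.inputs.repeats else [])
        anns = _ann.annotate_bins(track, elements, seq,
                                  region_start=g.markers.region_start)
        adf = pd.DataFrame([{
            "start": a.start, "end": a.end, "gc": a.gc, "bf": a.bf,
            "bf_class": a.bf_class,
            "elements": ";".join(e.name for e in a.elements)} for a in anns])
        adf.to_csv(out / "annotation.tsv", sep="\t", index=False)
        tallies = _ann.element_class_tallies(anns)
        summ = {"element_tallies": tallies.to_dict(orient="records")}
        gc = adf["gc"].to_numpy()
        bf = adf["bf"].to_numpy()
        try:
            r, p = _ann.correlate_gc_bf(gc, bf)
            summ["gc_vs_log10bf_pearson"] = {"r": r, "p": p}
        except ValueError as exc:
            summ["gc_vs_log10bf_pearson"] = {"error": str(exc)}
        hot = gc[adf["bf_class"] == "hotspot"]
        neu = gc[adf["bf_class"] == "neutral"]
        try:
            t, df_, p = _ann.ttest_gc(hot, neu)
            summ["gc_ttest"] = {"t": t, "df": df_, "p": p}
        except ValueError as exc:
            summ["gc_ttest"] = {"error": str(exc)}
        with open(out / "annotation_summary.json", "w") as fh:
            json.dump(summ, fh, indent=1)

    return {"outdir": str(out), "results": res, "track": track,
            "calls": calls, "summary": summary_row, "metadata": meta}
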