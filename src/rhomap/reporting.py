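"""Study-style summary tables and the bundled cat reference summaries.

The package ships published per-region and per-hotspot summaries of a
fine-scale recombination survey of the domestic cat (ten regions on
chromosomes A1-X, 701 array SNPs in 22 unrelated individuals) as plain-TSV
reference data.  The functions here
recompute the derived arithmetic of those tables — region sizes, mean
inter-SNP distances, totals/means, hotspot sizes and gaps, element class
percentages — and produce the same summaries for new (e.g. simulated)
analyses.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def _data_path(name: str):
    return resources.files("rhomap.datasets") / name


def load_cat_regions() -> pd.DataFrame:
    """Published per-region summaries: SNP counts, assembly coordinates,
    mean scaled rates and Bayes-factor bin counts."""
    return pd.read_csv(_data_path("cat_regions.tsv"), sep="\t")


def load_cat_hotspots() -> pd.DataFrame:
    """Published hotspot intervals with size, bin count, mean posterior
    probability, mean Bayes factor and mean GC."""
    return pd.read_csv(_data_path("cat_hotspots.tsv"), sep="\t")


def load_cat_hotspot_elements() -> pd.DataFrame:
    """Repeat/variation elements within the published hotspot intervals
    (one row per element occurrence)."""
    return pd.read_csv(_data_path("cat_hotspot_elements.tsv"), sep="\t")


def mean_inter_snp_distance(region_size: int, n_snps: int) -> int:
    """region_size/(k-1), truncated to integer bp (table convention)."""
    return int(region_size / (n_snps - 1))


def region_summary_table(df: pd.DataFrame = None) -> pd.DataFrame:
    """Per-region summary with derived columns plus Mean/Total rows.

    Input needs columns chrom, n_snps, start, end and optionally
    mean_rho_per_mb and bin counts; defaults to the bundled cat study table.
    """
    if df is None:
        df = load_cat_regions()
    out = df.copy()
    out["region_size"] = out["end"] - out["start"]
    out["mean_inter_snp_distance"] = [
        mean_inter_snp_distance(s, k)
        for s, k in zip(out["region_size"], out["n_snps"])]
    summary_rows = []
    mean_row = {"chrom": "Mean",
                "n_snps": int(round(out["n_snps"].mean())),
                "region_size": int(round(out["region_size"].mean())),
                "mean_inter_snp_distance": int(round(
                    out["mean_inter_snp_distance"].mean()))}
    total_row = {"chrom": "Total",
                 "n_snps": int(out["n_snps"].sum()),
                 "region_size": int(out["region_size"].sum())}
    for col in ("mean_rho_per_mb",):
        if col in out:
            mean_row[col] = round(float(out[col].mean()), 2)
    for col in ("bins_lt100", "bins_ge100", "bins_total"):
        if col in out:
            mean_row[col] = int(round(out[col].mean()))
            total_row[col] = int(out[col].sum())
    summary_rows = [mean_row, total_row]
    return pd.concat([out, pd.DataFrame(summary_rows)], ignore_index=True)


def hotspot_summary_table(df: pd.DataFrame = None) -> pd.DataFrame:
    """Hotspot table with a Mean row over size, bins, PP, BF and GC."""
    if df is None:
        df = load_cat_hotspots()
    out = df.copy()
    mean_row = {"hotspot_id": "Mean"}
    for col in ("size_kb", "n_bins", "mean_pp", "mean_bf", "mean_gc"):
        if col in out:
            v = float(out[col].mean())
            mean_row[col] = (int(round(v)) if col == "n_bins"
                             else round(v, 2))
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)


def hotspot_gaps(df: pd.DataFrame = None) -> pd.DataFrame:
    """Distances between consecutive hotspots on the same chromosome
    (gap = next start - previous end, bp)."""
    if df is None:
        df = load_cat_hotspots()
    rows = []
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("start")
        for (_, a), (_, b) in zip(grp.iterrows(), grp.iloc[1:].iterrows()):
            rows.append({"chrom": chrom, "first_end": int(a["end"]),
                         "second_start": int(b["start"]),
                         "gap_bp": int(b["start"] - a["end"])})
    return pd.DataFrame(rows, columns=["chrom", "first_end", "second_start",
                                       "gap_bp"])


def element_class_percentages(elements: pd.DataFrame = None) -> pd.DataFrame:
    """Share of each repeat class among hotspot elements, floored to whole
    percent (e.g. 9 of 22 SINEs -> 40)."""
    if elements is None:
        elements = load_cat_hotspot_elements()
    total = len(elements)
    rows = []
    for rc, grp in elements.groupby("repeat_class"):
        rows.append({"repeat_class": rc, "count": len(grp),
                     "percent": int(100 * len(grp) // total)})
    return (pd.DataFrame(rows)
            .sort_values("count", ascending=False)
            .reset_index(drop=True))


def bin_class_shares(df: pd.DataFrame = None) -> dict:
    """Neutral/hotspot bin totals and percentage shares across regions."""
    if df is None:
        df = load_cat_regions()
    neutral = int(df["bins_lt100"].sum())
    hot = int(df["bins_ge100"].sum())
    total = int(df["bins_total"].sum())
    return {"neutral_bins": neutral, "hotspot_bins": hot, "total_bins": total,
            "neutral_percent": 100.0 * neutral / total,
            "hotspot_percent": 100.0 * hot / total}


def inferred_region_summary(chrom: str, markers, rate_track,
                            bin_track) -> dict:
    """Summary row for one analysed region from inference outputs.

    ``rate_track`` is the posterior-mean per-interval rho/Mb array,
    ``bin_track`` a BinTrack with Bayes factors attached.
    """
    from .bins import mean_rho

    d = markers.inter_marker_distances
    rs = mean_rho(rate_track, d)
    hot = int(np.sum(bin_track.bf >= 100))
    return {"chrom": chrom, "n_snps": markers.k,
            "start": int(markers.region_start),
            "end": int(markers.region_end),
            "region_size": markers.region_size,
            "mean_inter_snp_distance": mean_inter_snp_distance(
                markers.region_size, markers.k),
            "mean_rho_per_mb": rs.mean_rho_per_mb,
            "bins_lt100": bin_track.n_bins - hot, "bins_ge100": hot,
            "bins_total": bin_track.n_bins}
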