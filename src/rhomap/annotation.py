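"""GC-content and repeat-element characterisation of hotspot vs neutral bins.

Bins (200 bp) are classed "hotspot" (BF >= 100) or "neutral" (BF < 100).
Per bin we compute GC content from the region FASTA and collect overlapping
RepeatMasker elements; element tallies are reported per class over distinct
elements (an element spanning several bins of one class counts once for
that class).  The association analyses are a Pearson correlation of GC
against log10(BF) and a Welch two-sample t-test of GC between bin classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_VALID = set("ACGTNacgtn")


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T), case-insensitive; N bases are excluded from the
    denominator.  Returns NaN when no unambiguous base remains."""
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)!r}")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    return gc / denom if denom else float("nan")


@dataclass(frozen=True)
class RepeatElement:
    """One RepeatMasker annotation; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    repeat_class: str
    family: str


def parse_repeat_table(path) -> list[RepeatElement]:
    """Read repeat elements from a UCSC rmsk table dump or a RepeatMasker
    ``.out`` file (auto-detected); malformed lines are skipped and counted.

    rmsk dumps are 0-based half-open; ``.out`` coordinates are 1-based
    inclusive and get normalised.
    """
    elements: list[RepeatElement] = []
    n_bad = 0
    with open(path) as fh:
        lines = fh.readlines()
    is_out = any(ln.lstrip().startswith(("SW", "score")) for ln in lines[:3])
    for ln in lines:
        fields = ln.split()
        if not fields:
            continue
        if is_out and (fields[0] in ("SW", "score") or fields[0].startswith("There")):
            continue
        try:
            if is_out:
                # .out: SW pctdiv pctdel pctins query begin end (left) strand
                #        name class/family ...
                chrom = fields[4]
                start, end = int(fields[5]) - 1, int(fields[6])
                strand = "-" if fields[8] == "C" else "+"
                name = fields[9]
                cls, _, fam = fields[10].partition("/")
            else:
                # UCSC rmsk: bin swScore milliDiv milliDel milliIns genoName
                #            genoStart genoEnd genoLeft strand repName
                #            repClass repFamily ...
                chrom = fields[5]
                start, end = int(fields[6]), int(fields[7])
                strand = fields[9]
                name, cls, fam = fields[10], fields[11], fields[12]
            if end <= start:
                raise ValueError("empty interval")
            if not cls or not name:
                raise ValueError("missing class")
            elements.append(RepeatElement(chrom, start, end, strand, name,
                                          cls, fam or cls))
        except (ValueError, IndexError):
            n_bad += 1
    if n_bad:
        logger.info("skipped %d malformed repeat lines", n_bad)
    return elements


@dataclass(frozen=True)
class BinAnnotation:
    """Annotation of one 200-bp bin: interval (0-based half-open,
    region-relative), GC fraction (NaN if all-N), BF class, elements."""

    start: int
    end: int
    gc: float
    bf: float
    bf_class: str  # "hotspot" | "neutral"
    elements: tuple


def annotate_bins(track, elements, sequence: str, chromosome: str = None,
                  region_start: int = 1,
                  bf_threshold: float = 100.0) -> list[BinAnnotation]:
    """Per-bin GC content and overlapping repeat elements.

    ``sequence`` is the region sequence (index 0 = region_start).  Elements
    are given in chromosome coordinates (0-based half-open) and must match
    ``chromosome`` when provided.
    """
    if track.bf is None:
        raise ValueError("track carries no Bayes factors")
    out = []
    offset = region_start - 1  # chromosome bp of sequence[0], 0-based
    for el in elements:
        if chromosome is not None and el.chrom != chromosome:
            raise ValueError(
                f"element chromosome {el.chrom!r} != region {chromosome!r}")
    starts = track.starts.astype(int)
    ends = track.ends.astype(int)
    el_starts = np.array([e.start - offset for e in elements])
    el_ends = np.array([e.end - offset for e in elements])
    for i in range(track.n_bins):
        seq = sequence[starts[i]:ends[i]]
        gc = gc_content(seq) if seq else float("nan")
        if len(elements):
            hit = (el_starts < ends[i]) & (el_ends > starts[i])
            els = tuple(e for e, h in zip(elements, hit) if h)
        else:
            els = ()
        cls = "hotspot" if track.bf[i] >= bf_threshold else "neutral"
        out.append(BinAnnotation(int(starts[i]), int(ends[i]), gc,
                                 float(track.bf[i]), cls, els))
    return out


def element_class_tallies(annotations) -> pd.DataFrame:
    """Distinct-element tallies per repeat class for hotspot and neutral bin
    sets, with percentages floored to whole percent.

    An element intersecting several bins of a class counts once for that
    class (Table-style per-interval listing, not per-bin)."""
    rows = []
    for cls in ("hotspot", "neutral"):
        seen = {}
        for ann in annotations:
            if ann.bf_class != cls:
                continue
            for el in ann.elements:
                seen[(el.chrom, el.start, el.end, el.name)] = el
        total = len(seen)
        by_class: dict = {}
        for el in seen.values():
            by_class[el.repeat_class] = by_class.get(el.repeat_class, 0) + 1
        for rc, cnt in sorted(by_class.items()):
            rows.append({"bin_class": cls, "repeat_class": rc, "count": cnt,
                         "total": total,
                         "percent": int(100 * cnt // total) if total else 0})
    return pd.DataFrame(rows,
                        columns=["bin_class", "repeat_class", "count",
                                 "total", "percent"])


def correlate_gc_bf(gc, bf):
    """Pearson correlation of GC against log10(BF), two-sided p-value.

    Bins with undefined GC are excluded.  Raises if either vector is
    constant (undefined correlation).
    """
    gc = np.asarray(gc, float)
    bf = np.asarray(bf, float)
    ok = ~np.isnan(gc) & ~np.isnan(bf)
    gc, bf = gc[ok], bf[ok]
    if gc.size < 3:
        raise ValueError("need >= 3 bins with defined GC")
    x = np.log10(bf)
    if np.ptp(gc) == 0 or np.ptp(x) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(gc, x)
    return float(r), float(p)


def ttest_gc(hot, neutral):
    """Welch two-sample t-test of GC content between bin classes;
    returns (t, df, two-sided p)."""
    hot = np.asarray(hot, float)
    neutral = np.asarray(neutral, float)
    hot, neutral = hot[~np.isnan(hot)], neutral[~np.isnan(neutral)]
    if hot.size < 2 or neutral.size < 2:
        raise ValueError("each group needs >= 2 values")
    res = stats.ttest_ind(hot, neutral, equal_var=False)
    # Welch-Satterthwaite df
    v1, v2 = hot.var(ddof=1) / hot.size, neutral.var(ddof=1) / neutral.size
    if v1 + v2 == 0:
        df = float(hot.size + neutral.size - 2)
        return 0.0, df, 1.0
    df = (v1 + v2) ** 2 / (v1 ** 2 / (hot.size - 1)
                           + v2 ** 2 / (neutral.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def read_region_fasta(path, name: str = None) -> str:
    """Read one region sequence from a FASTA file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return str(rec.seq)
    raise ValueError(f"sequence {name!r} not found in {path}")
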