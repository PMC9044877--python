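"""Locus definitions and peak-to-gene assignment.

A locus definition (LocDef) is a rule assigning genomic positions to genes:

  nearest_tss    - every base to the gene with the nearest TSS (genome tiling)
  within_5kb     - the +-window promoter interval of each gene (may overlap)
  beyond_5kb     - nearest-TSS territory minus promoter windows
  entdef         - the records of an enhancer-to-target definition
  entdef_plus5kb - entdef records plus the promoter windows

A peak is assigned by its midpoint by default (floor((start+end)/2)): it
increments the count of every gene owning a record containing the midpoint.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .build import EnTDef
from .core import (
    GeneRegistry,
    GenomicInterval,
    PeakSet,
    merge_intervals,
    nearest_tss_partition,
    subtract_intervals,
)

MODES = ("nearest_tss", "within_5kb", "beyond_5kb", "entdef", "entdef_plus5kb")


@dataclasses.dataclass
class LocusDefinition:
    records: pd.DataFrame  # columns: chrom, start, end, gene_id
    mode: str
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = self.mode

    def __len__(self) -> int:
        return len(self.records)


def _records_df(rows: list[tuple[str, int, int, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def build_locusdef(
    mode: str,
    registry: GeneRegistry,
    window: int = 5000,
    entdef: Optional[EnTDef] = None,
) -> LocusDefinition:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if mode in ("entdef", "entdef_plus5kb") and entdef is None:
        raise ValueError(f"mode {mode!r} requires an EnTDef")

    if mode == "nearest_tss":
        rows = [(iv.chrom, iv.start, iv.end, gid) for iv, gid in nearest_tss_partition(registry)]
        return LocusDefinition(_records_df(rows), mode)

    if mode == "within_5kb":
        rows = [
            (w.chrom, w.start, w.end, g.gene_id)
            for g, w in zip(registry.genes, registry.promoter_windows(window))
        ]
        return LocusDefinition(_records_df(rows), mode)

    if mode == "beyond_5kb":
        windows = registry.promoter_windows(window)
        rows = []
        for iv, gid in nearest_tss_partition(registry):
            for piece in subtract_intervals([iv], windows):
                rows.append((piece.chrom, piece.start, piece.end, gid))
        return LocusDefinition(_records_df(rows), mode)

    base = entdef.records[["chrom", "start", "end", "gene_id"]].copy()
    if mode == "entdef":
        return LocusDefinition(base, mode, name=entdef.name)
    promoters = build_locusdef("within_5kb", registry, window).records
    return LocusDefinition(
        pd.concat([base, promoters], ignore_index=True), mode,
        name=f"{entdef.name}_plus5kb",
    )


@dataclasses.dataclass
class AssignmentProfile:
    """Per-gene peak counts and locus lengths for one peak set under one LocDef."""

    peakset_name: str
    genes: pd.DataFrame  # index gene_id; columns peak_count, locus_length, has_peak
    hits: pd.DataFrame  # columns peak_idx, gene_id (one row per peak-gene assignment)
    n_assigned_peaks: int
    n_unassigned_peaks: int
    locus_bp: dict[str, int] = dataclasses.field(default_factory=dict)  # merged bp per gene

    @property
    def gene_universe(self) -> frozenset[str]:
        return frozenset(self.genes.index)

    def to_tsv(self, path) -> None:
        df = self.genes.copy()
        df["has_peak"] = df["has_peak"].astype(int)
        df.to_csv(path, sep="\t", index_label="gene_id")


def assign_peaks(
    locdef: LocusDefinition,
    peaks: PeakSet,
    overlap_rule: str = "midpoint",
) -> AssignmentProfile:
    """Assign each peak to the gene(s) whose loci contain its midpoint
    (overlap_rule="midpoint") or overlap it by >= 1 bp (overlap_rule="any").

    A peak landing in a multi-gene locus counts once for each gene.  Peak
    weights (if present on the peak set) replace unit counts.
    """
    if overlap_rule not in ("midpoint", "any"):
        raise ValueError("overlap_rule must be 'midpoint' or 'any'")
    df = locdef.records
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end, gid in zip(df.chrom, df.start, df.end, df.gene_id):
        trees[chrom].addi(int(start), int(end), gid)

    weights = peaks.weights if peaks.weights is not None else np.ones(len(peaks))
    counts: dict[str, float] = defaultdict(float)
    has_peak: set[str] = set()
    hit_rows: list[tuple[int, str]] = []
    n_assigned = 0
    for idx, peak in enumerate(peaks.peaks):
        if overlap_rule == "midpoint":
            mid = peak.midpoint
            hits = {h.data for h in trees[peak.chrom].at(mid)}
        else:
            hits = {h.data for h in trees[peak.chrom].overlap(peak.start, peak.end)}
        if hits:
            n_assigned += 1
            for gid in hits:
                counts[gid] += weights[idx]
                has_peak.add(gid)
                hit_rows.append((idx, gid))

    lengths: dict[str, int] = {}
    for gid, group in df.groupby("gene_id"):
        merged = merge_intervals(
            [GenomicInterval(c, int(s), int(e)) for c, s, e in zip(group.chrom, group.start, group.end)]
        )
        lengths[gid] = sum(iv.length for iv in merged)

    gene_ids = sorted(lengths)
    genes = pd.DataFrame(
        {
            "peak_count": [counts.get(g, 0.0) for g in gene_ids],
            "locus_length": [lengths[g] for g in gene_ids],
            "has_peak": [g in has_peak for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return AssignmentProfile(
        peakset_name=peaks.name,
        genes=genes,
        hits=pd.DataFrame(hit_rows, columns=["peak_idx", "gene_id"]),
        n_assigned_peaks=n_assigned,
        n_unassigned_peaks=len(peaks) - n_assigned,
        locus_bp=lengths,
    )
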