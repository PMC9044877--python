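"""Assemble enhancer-to-target-gene definitions (EnTDefs).

An EnTDef maps distal loci (outside the +-5 kb promoter windows around
TSSs) to the gene(s) they are inferred to regulate.  Enhancer regions come
from one or more sources (e.g. chromatin-state tracks, DNase hypersensitive
sites, CAGE enhancers); links come from pair tables (correlation-based),
paired interaction anchors (ChIA-PET-style) or chromatin loops.  Optional
steps: extension of short enhancers to a floor length, and a nearest-TSS
fallback covering all remaining distal bases ("nearest_all").
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from collections import defaultdict
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (
    ChromSizes,
    GeneRegistry,
    GenomicInterval,
    PeakSet,
    complement_intervals,
    intersect_intervals,
    merge_intervals,
    nearest_tss_partition,
    sort_intervals,
    subtract_intervals,
    total_bp,
)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EnhancerSource:
    name: str
    regions: list[GenomicInterval]


@dataclasses.dataclass
class LinkEvidence:
    """One enhancer-gene linking dataset.

    method:
      pair_table   - payload: list of (enhancer interval, gene_id)
      anchor_pairs - payload: list of (anchor1, anchor2) intervals
      loops        - payload: list of loop-span intervals
    """

    method: str
    name: str
    payload: list

    def __post_init__(self):
        if self.method not in ("pair_table", "anchor_pairs", "loops"):
            raise ValueError(f"unknown link-evidence method {self.method!r}")


@dataclasses.dataclass(frozen=True)
class EnTDefConfig:
    enhancer_sources: tuple[str, ...]
    link_methods: tuple[str, ...]  # non-loop evidence names
    loop_variant: Optional[int] = None  # max genes per loop (1, 2 or 3), None = no loops
    extend: bool = False
    nearest_all: bool = False
    promoter_window: int = 5000
    extension_target: int = 1000
    ct_mode: bool = False

    def __post_init__(self):
        if not self.enhancer_sources:
            raise ValueError("config needs at least one enhancer source")
        if not self.link_methods and self.loop_variant is None:
            raise ValueError("config needs at least one link method")
        if self.loop_variant is not None and self.loop_variant < 1:
            raise ValueError("loop_variant must be >= 1")

    def feature_set(self) -> frozenset[str]:
        """Method labels present in this config (used for paired contrasts)."""
        feats = set(self.enhancer_sources) | set(self.link_methods)
        if self.loop_variant is not None:
            feats.add(f"L{self.loop_variant}")
        if self.extend:
            feats.add("extend")
        if self.nearest_all:
            feats.add("nearest_all")
        return frozenset(feats)

    def label(self) -> str:
        parts = ["+".join(self.enhancer_sources), "+".join(self.link_methods) or "-"]
        if self.loop_variant is not None:
            parts[1] = (parts[1] + "+" if parts[1] != "-" else "") + f"L{self.loop_variant}"
        parts.append("ext" if self.extend else "noext")
        parts.append("na" if self.nearest_all else "nona")
        return "|".join(parts)


_ENTDEF_COLS = ["chrom", "start", "end", "gene_id", "sources", "link_methods", "fallback"]


class EnTDef:
    """A set of (locus interval -> gene id) records with provenance.

    records: DataFrame with columns chrom, start, end, gene_id,
    sources (comma-joined), link_methods (comma-joined), fallback (bool).
    A locus may map to multiple genes via multiple records.
    """

    def __init__(self, records: pd.DataFrame, config: Optional[EnTDefConfig] = None,
                 name: Optional[str] = None):
        missing = [c for c in _ENTDEF_COLS if c not in records.columns]
        if missing:
            raise ValueError(f"EnTDef records missing columns {missing}")
        self.records = records.reset_index(drop=True)
        self.config = config
        self.name = name or (config.label() if config else "entdef")

    def __len__(self) -> int:
        return len(self.records)

    def loci(self, include_fallback: bool = True) -> list[GenomicInterval]:
        df = self.records if include_fallback else self.records[~self.records["fallback"]]
        return [GenomicInterval(c, int(s), int(e)) for c, s, e in zip(df.chrom, df.start, df.end)]

    def link_pairs(self, include_fallback: bool = True) -> set[tuple[str, int, int, str]]:
        df = self.records if include_fallback else self.records[~self.records["fallback"]]
        return {(c, int(s), int(e), g) for c, s, e, g in zip(df.chrom, df.start, df.end, df.gene_id)}

    def to_tsv(self, path) -> None:
        df = self.records.copy()
        df["fallback"] = df["fallback"].map({True: "1", False: "0"})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: Optional[str] = None) -> "EnTDef":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        df["fallback"] = df["fallback"].astype(int).astype(bool)
        df["sources"] = df["sources"].fillna("")
        df["link_methods"] = df["link_methods"].fillna("")
        return cls(df, name=name)


@dataclasses.dataclass
class EnTDefStats:
    n_enhancers: int
    genes_per_enhancer_mean: float
    genes_per_enhancer_median: float
    enhancers_per_gene_mean: float
    enhancers_per_gene_median: float
    genome_coverage_fraction: float
    distal_peak_catch_fraction: Optional[float] = None


# ---------------------------------------------------------------------------
# region assembly
# ---------------------------------------------------------------------------


def trim_promoter_windows(
    regions: Iterable[GenomicInterval], registry: GeneRegistry, window: int = 5000
) -> list[GenomicInterval]:
    """Remove bases within `window` bp of any TSS (distal constraint)."""
    if window <= 0:
        raise ValueError("promoter window must be positive")
    return subtract_intervals(regions, registry.promoter_windows(window))


def extend_enhancers(
    regions: Iterable[GenomicInterval],
    registry: GeneRegistry,
    target_len: int = 1000,
    window: int = 5000,
) -> list[GenomicInterval]:
    """Grow regions shorter than target_len to target_len around their midpoint.

    Regions already >= target_len pass through unchanged.  Extension is
    clamped to chromosome bounds and promoter trimming is re-applied so the
    distal invariant still holds (extended pieces may shrink back or split).
    """
    if target_len % 2:
        raise ValueError("target_len must be even")
    half = target_len // 2
    out: list[GenomicInterval] = []
    for iv in regions:
        if iv.length >= target_len:
            out.append(iv)
        else:
            mid = iv.midpoint
            start = max(0, mid - half)
            end = min(registry.sizes[iv.chrom], mid + half)
            out.append(GenomicInterval(iv.chrom, start, end))
    return trim_promoter_windows(out, registry, window)


def _interval_trees(ivs: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, iv in enumerate(ivs):
        trees[iv.chrom].addi(iv.start, iv.end, idx)
    return trees


# ---------------------------------------------------------------------------
# link derivation (each op returns a list of (enhancer_idx, gene_id) pairs,
# deduplicated, referring to indices into the built enhancer list)
# ---------------------------------------------------------------------------

Link = tuple[int, str]


def import_pair_links(
    pairs: Iterable[tuple[GenomicInterval, str]],
    enhancers: Sequence[GenomicInterval],
    registry: GeneRegistry,
) -> list[Link]:
    """A link (E, g) for every built enhancer E overlapping a pair's interval >= 1 bp."""
    trees = _interval_trees(enhancers)
    links: set[Link] = set()
    n_skipped = 0
    for iv, gene_id in pairs:
        if gene_id not in registry:
            n_skipped += 1
            continue
        for hit in trees[iv.chrom].overlap(iv.start, iv.end):
            links.add((hit.data, gene_id))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} pair(s) with gene ids absent from the registry")
    return sorted(links)


def map_anchor_pairs_to_links(
    anchors: Iterable[tuple[GenomicInterval, GenomicInterval]],
    enhancers: Sequence[GenomicInterval],
    registry: GeneRegistry,
    promoter_window: int = 5000,
) -> list[Link]:
    """Interaction anchors: one end over an enhancer, the other over a promoter window.

    Both orientations are tested; a promoter anchor spanning several genes'
    windows links the enhancer to all of them.  Inter-chromosomal pairs are
    skipped.
    """
    enh_trees = _interval_trees(enhancers)
    windows = registry.promoter_windows(promoter_window)
    win_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g, w in zip(registry.genes, windows):
        win_trees[w.chrom].addi(w.start, w.end, g.gene_id)
    links: set[Link] = set()
    for a1, a2 in anchors:
        if a1.chrom != a2.chrom:
            continue
        for enh_anchor, prom_anchor in ((a1, a2), (a2, a1)):
            enh_hits = enh_trees[enh_anchor.chrom].overlap(enh_anchor.start, enh_anchor.end)
            if not enh_hits:
                continue
            gene_hits = win_trees[prom_anchor.chrom].overlap(prom_anchor.start, prom_anchor.end)
            for eh in enh_hits:
                for gh in gene_hits:
                    links.add((eh.data, gh.data))
    return sorted(links)


def links_from_loops(
    loops: Iterable[GenomicInterval],
    enhancers: Sequence[GenomicInterval],
    registry: GeneRegistry,
    max_genes: int,
) -> list[Link]:
    """Loop linking: genes with TSS inside the loop span; if 1 <= |G| <= max_genes,
    every enhancer overlapping the span (>= 1 bp) links to every gene in G."""
    if max_genes < 1:
        raise ValueError("max_genes must be >= 1")
    enh_trees = _interval_trees(enhancers)
    tss_by_chrom = {
        chrom: (np.array([g.tss for g in registry.by_chrom(chrom)]),
                [g.gene_id for g in registry.by_chrom(chrom)])
        for chrom in registry.chroms()
    }
    links: set[Link] = set()
    for loop in loops:
        tss, ids = tss_by_chrom.get(loop.chrom, (np.array([]), []))
        lo = int(np.searchsorted(tss, loop.start, side="left"))
        hi = int(np.searchsorted(tss, loop.end, side="left"))
        genes_in = ids[lo:hi]
        if not (1 <= len(genes_in) <= max_genes):
            continue
        for hit in enh_trees[loop.chrom].overlap(loop.start, loop.end):
            for gid in genes_in:
                links.add((hit.data, gid))
    return sorted(links)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _source_labels_for(
    enhancers: Sequence[GenomicInterval], sources: Sequence[EnhancerSource]
) -> list[str]:
    """Comma-joined source names overlapping each built enhancer (>= 1 bp)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for src in sources:
        for iv in src.regions:
            trees[iv.chrom].addi(iv.start, iv.end, src.name)
    labels = []
    for iv in enhancers:
        names = {h.data for h in trees[iv.chrom].overlap(iv.start, iv.end)}
        labels.append(",".join(sorted(names)))
    return labels


def nearest_tss_fallback_records(
    covered: Iterable[GenomicInterval], registry: GeneRegistry, window: int
) -> pd.DataFrame:
    """Partition the complement of (promoter windows + covered loci) by nearest TSS."""
    blocked = list(covered) + registry.promoter_windows(window)
    free = complement_intervals(blocked, registry.sizes)
    rows = []
    for chrom in registry.chroms():
        if not registry.by_chrom(chrom):
            warnings.warn(f"chromosome {chrom!r} has no genes; its distal bases stay unassigned")
    territory = nearest_tss_partition(registry)
    terr_by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = defaultdict(list)
    for iv, gid in territory:
        terr_by_chrom[iv.chrom].append((iv, gid))
    for piece in free:
        for terr, gid in terr_by_chrom.get(piece.chrom, []):
            s, e = max(piece.start, terr.start), min(piece.end, terr.end)
            if s < e:
                rows.append((piece.chrom, s, e, gid, "", "nearest_all", True))
    return pd.DataFrame(rows, columns=_ENTDEF_COLS)


def add_nearest_all(entdef: EnTDef, registry: GeneRegistry) -> EnTDef:
    window = entdef.config.promoter_window if entdef.config else 5000
    fallback = nearest_tss_fallback_records(entdef.loci(), registry, window)
    records = pd.concat([entdef.records, fallback], ignore_index=True)
    cfg = dataclasses.replace(entdef.config, nearest_all=True) if entdef.config else None
    return EnTDef(records, config=cfg, name=entdef.name)


def assemble_entdef(
    config: EnTDefConfig,
    sources: Sequence[EnhancerSource],
    evidence: Sequence[LinkEvidence],
    registry: GeneRegistry,
) -> EnTDef:
    """Build one EnTDef: union+merge sources -> trim promoters -> optional
    extension (re-trimmed) -> derive links from each selected evidence ->
    union links -> optional nearest-TSS fallback.

    Deterministic: a pure function of (config, inputs).
    """
    src_by_name = {s.name: s for s in sources}
    ev_by_name = {e.name: e for e in evidence}
    for name in config.enhancer_sources:
        if name not in src_by_name:
            raise ValueError(f"unknown enhancer source {name!r}")
    for name in config.link_methods:
        if name not in ev_by_name:
            raise ValueError(f"unknown link evidence {name!r}")
    selected_sources = [src_by_name[n] for n in config.enhancer_sources]

    regions = [iv for s in selected_sources for iv in s.regions]
    enhancers = trim_promoter_windows(merge_intervals(regions), registry, config.promoter_window)
    if config.extend:
        enhancers = extend_enhancers(
            enhancers, registry, config.extension_target, config.promoter_window
        )
    enhancers = sort_intervals(enhancers)

    links_by_method: dict[str, list[Link]] = {}
    for name in config.link_methods:
        ev = ev_by_name[name]
        if ev.method == "pair_table":
            links_by_method[name] = import_pair_links(ev.payload, enhancers, registry)
        elif ev.method == "anchor_pairs":
            links_by_method[name] = map_anchor_pairs_to_links(
                ev.payload, enhancers, registry, config.promoter_window
            )
        else:
            raise ValueError(f"evidence {name!r} has method {ev.method!r}; loops are "
                             "selected via loop_variant")
    if config.loop_variant is not None:
        loop_ev = [e for e in evidence if e.method == "loops"]
        if not loop_ev:
            raise ValueError("config requests a loop variant but no loop evidence supplied")
        loop_links: set[Link] = set()
        for ev in loop_ev:
            loop_links.update(
                links_from_loops(ev.payload, enhancers, registry, config.loop_variant)
            )
        links_by_method[f"L{config.loop_variant}"] = sorted(loop_links)

    methods_per_link: dict[Link, set[str]] = defaultdict(set)
    for method, links in links_by_method.items():
        for link in links:
            methods_per_link[link].add(method)

    src_labels = _source_labels_for(enhancers, selected_sources)
    rows = []
    for (enh_idx, gene_id), methods in sorted(methods_per_link.items()):
        iv = enhancers[enh_idx]
        rows.append(
            (iv.chrom, iv.start, iv.end, gene_id, src_labels[enh_idx],
             ",".join(sorted(methods)), False)
        )
    records = pd.DataFrame(rows, columns=_ENTDEF_COLS)
    entdef = EnTDef(records, config=config)
    if config.nearest_all:
        fallback = nearest_tss_fallback_records(
            entdef.loci(), registry, config.promoter_window
        )
        entdef = EnTDef(pd.concat([records, fallback], ignore_index=True), config=config)
    return entdef


# ---------------------------------------------------------------------------
# enumeration of definition configurations
# ---------------------------------------------------------------------------


def enumerate_definitions(
    source_names: Sequence[str] = ("ChromHMM", "DNase", "FANTOM5", "Thurman"),
    nonloop_link_names: Sequence[str] = ("ChIA", "Thurman", "FANTOM5"),
    loop_variants: Sequence[int] = (1, 2, 3),
    toggles: bool = True,
    ct_mode: bool = False,
    interaction_name: str = "ChIA",
    **config_kwargs,
) -> list[EnTDefConfig]:
    """Enumerate all distinct definition configurations.

    General mode: every non-empty source subset x every link combination
    (non-empty non-loop subsets, each of those plus one loop variant, and
    each loop variant alone) x extension toggle x fallback toggle:
    (2^s - 1) x [(2^k - 1)(1 + v) + v] x 2 x 2.

    CT mode restricts link combinations to the interaction method and/or a
    single loop variant: {interaction}, {Lx}, {interaction, Lx} for each of
    the v variants, i.e. 1 + 2v combos.

    With the study's counts (s=4, k=3, v=3) this yields 15 x 31 x 2 x 2 =
    1860 configurations, 465 with both toggles off, and 15 x 7 x 2 x 2 =
    420 in CT mode.
    """
    source_subsets = [
        tuple(c)
        for r in range(1, len(source_names) + 1)
        for c in itertools.combinations(source_names, r)
    ]
    link_combos: list[tuple[tuple[str, ...], Optional[int]]] = []
    if ct_mode:
        link_combos.append(((interaction_name,), None))
        for v in loop_variants:
            link_combos.append(((), v))
            link_combos.append(((interaction_name,), v))
    else:
        nonloop_subsets = [
            tuple(c)
            for r in range(1, len(nonloop_link_names) + 1)
            for c in itertools.combinations(nonloop_link_names, r)
        ]
        for subset in nonloop_subsets:
            link_combos.append((subset, None))
        for subset in nonloop_subsets:
            for v in loop_variants:
                link_combos.append((subset, v))
        for v in loop_variants:
            link_combos.append(((), v))
    toggle_space = [(False, False)] if not toggles else list(
        itertools.product((False, True), (False, True))
    )
    configs = []
    for srcs in source_subsets:
        for links, variant in link_combos:
            for extend, nearest in toggle_space:
                configs.append(
                    EnTDefConfig(
                        enhancer_sources=srcs,
                        link_methods=links,
                        loop_variant=variant,
                        extend=extend,
                        nearest_all=nearest,
                        ct_mode=ct_mode,
                        **config_kwargs,
                    )
                )
    return configs


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def entdef_stats(
    entdef: EnTDef, registry: GeneRegistry, peaks: Optional[PeakSet] = None,
    window: int = 5000,
) -> EnTDefStats:
    df = entdef.records[~entdef.records["fallback"]]
    enh_keys = df[["chrom", "start", "end"]].apply(tuple, axis=1) if len(df) else pd.Series([], dtype=object)
    genes_per_enh = df.groupby(enh_keys)["gene_id"].nunique() if len(df) else pd.Series([], dtype=float)
    enh_per_gene = df.groupby("gene_id").size() if len(df) else pd.Series([], dtype=float)

    coverage = total_bp(entdef.loci()) / registry.sizes.total_bp

    catch: Optional[float] = None
    if peaks is not None:
        windows = merge_intervals(registry.promoter_windows(window))
        loci = merge_intervals(entdef.loci())
        win_trees = _interval_trees(windows)
        loci_trees = _interval_trees(loci)
        n_distal = n_caught = 0
        for p in peaks.peaks:
            mid = p.midpoint
            if win_trees[p.chrom].at(mid):
                continue  # within `window` of a TSS
            n_distal += 1
            if loci_trees[p.chrom].at(mid):
                n_caught += 1
        catch = (n_caught / n_distal) if n_distal else float("nan")

    return EnTDefStats(
        n_enhancers=int(genes_per_enh.shape[0]),
        genes_per_enhancer_mean=float(genes_per_enh.mean()) if len(genes_per_enh) else float("nan"),
        genes_per_enhancer_median=float(genes_per_enh.median()) if len(genes_per_enh) else float("nan"),
        enhancers_per_gene_mean=float(enh_per_gene.mean()) if len(enh_per_gene) else float("nan"),
        enhancers_per_gene_median=float(enh_per_gene.median()) if len(enh_per_gene) else float("nan"),
        genome_coverage_fraction=coverage,
        distal_peak_catch_fraction=catch,
    )
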