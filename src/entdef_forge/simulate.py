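"""Deterministic synthetic fixtures: toy genomes, ontologies, enhancer and
link evidence, and TF peak sets with planted signal.

The generator emulates the statistical structure the evaluation relies on:
TFs tend to bind enhancers linked to genes of the processes they are
annotated to.  Each synthetic TF is annotated to a handful of terms, and a
configurable fraction of its peaks falls inside enhancers linked to genes
of those terms; the remainder is uniform background.  A link-shuffled decoy
definition preserves all marginals while destroying the enhancer-gene
correspondence, giving a ground-truth recovery target for the ranking
pipeline.
"""

from __future__ import annotations

import dataclasses
import zlib
from collections import defaultdict
from typing import Optional

import numpy as np
import pandas as pd

from .build import (
    EnhancerSource,
    EnTDef,
    EnTDefConfig,
    LinkEvidence,
    _ENTDEF_COLS,
    trim_promoter_windows,
)
from .core import ChromSizes, Gene, GeneRegistry, GenomicInterval, PeakSet, merge_intervals
from .ontology import GeneSetCollection


@dataclasses.dataclass
class SimulationSpec:
    chrom_length: int = 10_000_000
    n_chroms: int = 1
    n_genes: int = 300
    min_tss_spacing: int = 12000
    n_terms: int = 120
    dag_depth: int = 4
    n_enhancers_per_source: int = 400
    n_sources: int = 3
    enhancer_len_range: tuple[int, int] = (200, 2000)
    link_radius: int = 300_000
    n_tfs: int = 3
    terms_per_tf: tuple[int, int] = (3, 8)
    peaks_per_tf: int = 2000
    peak_len_range: tuple[int, int] = (100, 500)
    enhancer_signal_fraction: float = 0.6
    theta: float = 5.0  # background NB dispersion for count-level simulations
    false_link_rate: float = 0.05  # epsilon: spurious evidence links
    link_drop_rate: float = 0.10  # delta: true links missing from evidence
    promoter_window: int = 5000
    seed: int = 0

    def __post_init__(self):
        for field in ("chrom_length", "n_genes", "n_terms", "n_enhancers_per_source",
                      "n_tfs", "peaks_per_tf"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        for field in ("enhancer_signal_fraction", "false_link_rate", "link_drop_rate"):
            if not 0 <= getattr(self, field) <= 1:
                raise ValueError(f"{field} must lie in [0, 1]")

    def rng(self, label: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(label.encode()) % (2**31)])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def make_toy_genome(spec: SimulationSpec) -> GeneRegistry:
    """Seeded registry: TSSs roughly uniform with a minimum spacing, gene
    bodies 2-100 kb containing the TSS."""
    rng = spec.rng("genome")
    sizes = ChromSizes({f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)})
    per_chrom = spec.n_genes // spec.n_chroms
    if per_chrom * spec.min_tss_spacing > spec.chrom_length:
        raise ValueError("min TSS spacing infeasible for this chromosome length")
    genes: list[Gene] = []
    gid = 0
    for chrom in sorted(sizes):
        n = per_chrom + (spec.n_genes % spec.n_chroms if chrom == sorted(sizes)[-1] else 0)
        slot = spec.chrom_length // n
        jitter_room = max(1, slot - spec.min_tss_spacing)
        tss = np.arange(n) * slot + spec.min_tss_spacing // 2 + rng.integers(
            0, jitter_room, size=n
        )
        tss = np.clip(tss, 1, spec.chrom_length - 2)
        strands = rng.choice(["+", "-"], size=n)
        lengths = np.exp(rng.uniform(np.log(2_000), np.log(100_000), size=n)).astype(int)
        for t, s, L in zip(tss, strands, lengths):
            t = int(t)
            if s == "+":
                body = GenomicInterval(chrom, t, min(spec.chrom_length, t + int(L)))
            else:
                body = GenomicInterval(chrom, max(0, t + 1 - int(L)), t + 1)
            genes.append(Gene(f"g{gid:04d}", chrom, str(s), t, body))
            gid += 1
    return GeneRegistry(genes, sizes)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------


def make_toy_ontology(spec: SimulationSpec, registry: GeneRegistry) -> GeneSetCollection:
    """DAG-structured term collection: leaf terms get random gene sets,
    internal terms are unions of their children plus a few extras."""
    rng = spec.rng("ontology")
    gene_ids = np.array(registry.gene_ids())
    depth = max(2, spec.dag_depth)
    # geometric-ish level sizes summing to n_terms, roots smallest
    weights = np.array([2.0**lvl for lvl in range(depth)])
    level_sizes = np.maximum(1, (spec.n_terms * weights / weights.sum()).astype(int))
    level_sizes[-1] += spec.n_terms - level_sizes.sum()
    levels: list[list[str]] = []
    t = 0
    for size in level_sizes:
        levels.append([f"T{t + i:04d}" for i in range(size)])
        t += size
    dag: dict[str, list[str]] = {}
    for lvl in range(1, depth):
        for term in levels[lvl]:
            n_par = 1 + int(rng.random() < 0.3)
            parents = rng.choice(levels[lvl - 1], size=min(n_par, len(levels[lvl - 1])),
                                 replace=False)
            dag[term] = [str(p) for p in parents]
    term_genes: dict[str, set[str]] = {}
    for term in levels[-1]:
        size = int(np.exp(rng.uniform(np.log(10), np.log(100))))
        term_genes[term] = set(rng.choice(gene_ids, size=min(size, gene_ids.size),
                                          replace=False))
    children: dict[str, list[str]] = defaultdict(list)
    for child, parents in dag.items():
        for p in parents:
            children[p].append(child)
    for lvl in range(depth - 2, -1, -1):
        for term in levels[lvl]:
            genes: set[str] = set()
            for c in children.get(term, []):
                genes |= term_genes.get(c, set())
            extras = rng.choice(gene_ids, size=min(8, gene_ids.size), replace=False)
            genes |= set(str(g) for g in extras)
            term_genes[term] = genes
    return GeneSetCollection(term_genes, dag, namespace="BP")


# ---------------------------------------------------------------------------
# regulome: enhancers, links, evidence, TF annotations
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ToyRegulome:
    sources: list[EnhancerSource]
    evidence: list[LinkEvidence]
    collection: GeneSetCollection
    annotations: dict[str, set[str]]  # tf -> assigned term ids
    truth: EnTDef  # the planted link map on trimmed merged enhancers
    # per TF: annotated-term gene -> enhancers linked to it (the planted binding sites)
    tf_enhancers: dict[str, dict[str, list[GenomicInterval]]]


def _planted_truth(
    spec: SimulationSpec,
    registry: GeneRegistry,
    enhancers: list[GenomicInterval],
    collection: GeneSetCollection,
    annotations: dict[str, set[str]],
    rng: np.random.Generator,
) -> tuple[dict[int, set[str]], dict[str, list[int]]]:
    """Link each enhancer to 1-2 nearby genes; bias a designated subset of
    enhancers toward each TF's term genes so planted peaks carry signal."""
    tss_by_chrom = {
        chrom: (np.array([g.tss for g in registry.by_chrom(chrom)]),
                [g.gene_id for g in registry.by_chrom(chrom)])
        for chrom in registry.chroms()
    }
    links: dict[int, set[str]] = defaultdict(set)
    candidates: list[list[str]] = []
    for idx, enh in enumerate(enhancers):
        tss, ids = tss_by_chrom[enh.chrom]
        mid = enh.midpoint
        near = np.flatnonzero(np.abs(tss - mid) <= spec.link_radius)
        cand = [ids[i] for i in near]
        candidates.append(cand)
        if not cand:
            continue
        dist = np.abs(tss[near] - mid).astype(float)
        w = 1.0 / (1.0 + dist / 50_000.0)
        w /= w.sum()
        k = 1 + int(rng.random() < 0.15)
        chosen = rng.choice(len(cand), size=min(k, len(cand)), replace=False, p=w)
        for c in chosen:
            links[idx].add(cand[c])

    tf_enh_idx: dict[str, dict[str, list[int]]] = {}
    for tf, terms in annotations.items():
        term_genes: set[str] = set()
        for t in terms:
            term_genes |= collection.genes(t)
        by_gene: dict[str, list[int]] = {
            g: [i for i, gs in links.items() if g in gs] for g in sorted(term_genes)
        }
        # every annotated-term gene gets at least one linked enhancer so the
        # planted binding covers the TF's whole program
        for g in sorted(term_genes):
            if by_gene[g]:
                continue
            eligible = [i for i, cand in enumerate(candidates) if g in cand]
            if not eligible:
                continue
            i = int(rng.choice(eligible))
            links[i].add(g)
            by_gene[g] = [i]
        tf_enh_idx[tf] = {g: idxs for g, idxs in by_gene.items() if idxs}
    return links, tf_enh_idx


def make_toy_regulome(spec: SimulationSpec, registry: GeneRegistry) -> ToyRegulome:
    rng = spec.rng("regulome")
    L = spec.chrom_length
    chroms = registry.chroms()

    lo, hi = spec.enhancer_len_range
    n_master = int(1.5 * spec.n_enhancers_per_source)
    master: list[GenomicInterval] = []
    for _ in range(n_master):
        chrom = str(rng.choice(chroms))
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, L - length))
        master.append(GenomicInterval(chrom, start, start + length))

    sources = []
    for s in range(spec.n_sources):
        take = rng.random(n_master) < (spec.n_enhancers_per_source / n_master)
        regions = []
        for iv, keep in zip(master, take):
            if not keep:
                continue
            shift = int(rng.integers(-100, 101))
            start = max(0, iv.start + shift)
            end = min(L, iv.end + shift)
            if start < end:
                regions.append(GenomicInterval(iv.chrom, start, end))
        sources.append(EnhancerSource(f"src{s + 1}", regions))

    enhancers = trim_promoter_windows(
        merge_intervals([iv for s in sources for iv in s.regions]),
        registry,
        spec.promoter_window,
    )

    collection = make_toy_ontology(spec, registry)
    ann_rng = spec.rng("annotations")
    # annotate TFs to mid-sized terms so positives survive size filtering
    eligible_terms = [t for t in collection.term_ids() if 10 <= len(collection.genes(t)) <= 60]
    annotations: dict[str, set[str]] = {}
    for i in range(spec.n_tfs):
        k = int(ann_rng.integers(spec.terms_per_tf[0], spec.terms_per_tf[1] + 1))
        annotations[f"TF{i + 1}"] = set(
            str(t) for t in ann_rng.choice(eligible_terms, size=min(k, len(eligible_terms)),
                                           replace=False)
        )

    links, tf_enh_idx = _planted_truth(spec, registry, enhancers, collection, annotations, rng)

    rows = []
    for idx in sorted(links):
        iv = enhancers[idx]
        for gid in sorted(links[idx]):
            rows.append((iv.chrom, iv.start, iv.end, gid, "truth", "truth", False))
    truth = EnTDef(pd.DataFrame(rows, columns=_ENTDEF_COLS), name="truth")

    evidence = _evidence_from_truth(spec, registry, enhancers, links, rng)
    tf_enhancers = {
        tf: {g: [enhancers[i] for i in idxs] for g, idxs in by_gene.items()}
        for tf, by_gene in tf_enh_idx.items()
    }
    return ToyRegulome(sources, evidence, collection, annotations, truth, tf_enhancers)


def _evidence_from_truth(
    spec: SimulationSpec,
    registry: GeneRegistry,
    enhancers: list[GenomicInterval],
    links: dict[int, set[str]],
    rng: np.random.Generator,
) -> list[LinkEvidence]:
    """Pair-table, anchor-pair and loop evidence consistent with the planted
    links, with links dropped at rate delta and false links added at rate
    epsilon."""
    flat = [(i, g) for i in sorted(links) for g in sorted(links[i])]
    gene_ids = registry.gene_ids()
    L = spec.chrom_length

    def sampled_links(label: str) -> list[tuple[int, str]]:
        r = spec.rng(f"evidence-{label}")
        kept = [lk for lk in flat if r.random() >= spec.link_drop_rate]
        n_false = int(spec.false_link_rate * len(flat))
        for _ in range(n_false):
            kept.append((int(r.integers(len(enhancers))), str(r.choice(gene_ids))))
        return kept

    pair_tables = []
    for name in ("corr", "cage"):
        payload = [(enhancers[i], g) for i, g in sampled_links(name)]
        pair_tables.append(LinkEvidence("pair_table", name, payload))

    anchors = []
    r = spec.rng("evidence-chia")
    for i, g in sampled_links("chia"):
        enh = enhancers[i]
        a_len = int(r.integers(500, 2001))
        a_start = max(0, enh.midpoint - a_len // 2)
        anchor1 = GenomicInterval(enh.chrom, a_start, min(L, a_start + a_len))
        tss = registry.get(g).tss
        anchor2 = GenomicInterval(enh.chrom, max(0, tss - 1000), min(L, tss + 1000))
        anchors.append((anchor1, anchor2))
    chia = LinkEvidence("anchor_pairs", "chia", anchors)

    loops = []
    tss_sorted = {
        chrom: np.array([g.tss for g in registry.by_chrom(chrom)]) for chrom in registry.chroms()
    }
    r = spec.rng("evidence-loop")
    for i, g in sampled_links("loop"):
        enh = enhancers[i]
        tss = registry.get(g).tss
        margin = int(r.integers(500, 5000))
        start = max(0, min(enh.start, tss) - margin)
        end = min(L, max(enh.end, tss + 1) + margin)
        arr = tss_sorted[enh.chrom]
        n_genes_in = int(np.searchsorted(arr, end) - np.searchsorted(arr, start))
        if n_genes_in <= 3:
            loops.append(GenomicInterval(enh.chrom, start, end))
    loop = LinkEvidence("loops", "loop", loops)

    return pair_tables + [chia, loop]


# ---------------------------------------------------------------------------
# TF peaks with planted enhancer signal
# ---------------------------------------------------------------------------


def make_tf_peaks(
    spec: SimulationSpec,
    registry: GeneRegistry,
    regulome: ToyRegulome,
    tf_id: str,
) -> PeakSet:
    """peaks_per_tf peaks: with probability enhancer_signal_fraction the peak
    midpoint falls inside an enhancer linked to a gene of the TF's annotated
    terms (target gene drawn uniformly, then one of its enhancers);
    otherwise uniformly in the genome."""
    if tf_id not in regulome.tf_enhancers or not regulome.tf_enhancers[tf_id]:
        raise ValueError(f"TF {tf_id!r} has no linked enhancers")
    rng = spec.rng(f"peaks-{tf_id}")
    by_gene = regulome.tf_enhancers[tf_id]
    target_genes = sorted(by_gene)
    chroms = registry.chroms()
    lo, hi = spec.peak_len_range
    peaks = []
    for _ in range(spec.peaks_per_tf):
        width = int(rng.integers(lo, hi + 1))
        if rng.random() < spec.enhancer_signal_fraction:
            gene = target_genes[int(rng.integers(len(target_genes)))]
            enhs = by_gene[gene]
            enh = enhs[int(rng.integers(len(enhs)))]
            mid = int(rng.integers(enh.start, enh.end))
            chrom = enh.chrom
        else:
            chrom = str(rng.choice(chroms))
            mid = int(rng.integers(0, registry.sizes[chrom]))
        size = registry.sizes[chrom]
        mid = int(np.clip(mid, width, size - width - 1))
        start = mid - width // 2
        end = start + width
        peaks.append(GenomicInterval(chrom, start, end))
    return PeakSet(name=f"{tf_id}_peaks", peaks=peaks, tf=tf_id)


# ---------------------------------------------------------------------------
# decoy
# ---------------------------------------------------------------------------


def shuffle_links(entdef: EnTDef, seed: int = 0, name: Optional[str] = None) -> EnTDef:
    """Permute gene assignments among non-fallback records: marginals (loci,
    per-gene link counts) are preserved, the enhancer-gene correspondence is
    destroyed."""
    rng = np.random.default_rng(seed)
    records = entdef.records.copy()
    mask = ~records["fallback"].to_numpy()
    genes = records.loc[mask, "gene_id"].to_numpy()
    records.loc[mask, "gene_id"] = rng.permutation(genes)
    return EnTDef(records.drop_duplicates(ignore_index=True), config=None,
                  name=name or f"{entdef.name}_shuffled")
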