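"""Benchmarking a definition against labeled enhancer-gene pairs.

Pairs carry a positive/negative label (BENGI-style).  A pair is "predicted
positive" under a definition when some definition locus overlaps the pair's
enhancer by >= 1 bp and is linked to the pair's gene.  Confusion counts and
the standard rates follow; an overlap coefficient compares two pair datasets
(shared pairs / size of the smaller set).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .build import EnTDef
from .core import GeneRegistry, GenomicInterval, merge_intervals, subtract_intervals


@dataclasses.dataclass
class BenchmarkPair:
    enhancer: GenomicInterval
    gene_id: str
    label: str  # "positive" | "negative"

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


@dataclasses.dataclass
class BenchmarkPairSet:
    pairs: list[BenchmarkPair]
    name: str = "benchmark"
    ratio_mode: str = "natural"  # or "fixed_1_to_4"

    def __len__(self) -> int:
        return len(self.pairs)

    def positives(self) -> list[BenchmarkPair]:
        return [p for p in self.pairs if p.label == "positive"]

    def negatives(self) -> list[BenchmarkPair]:
        return [p for p in self.pairs if p.label == "negative"]


@dataclasses.dataclass
class BenchmarkScore:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if (self.TN + self.FP) else 0.0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.TP + self.FP + self.FN
        return 2 * self.TP / denom if denom else 0.0


def drop_ambiguous_pairs(
    pairs: Sequence[BenchmarkPair], registry: GeneRegistry, margin: int = 2000
) -> list[BenchmarkPair]:
    """Drop pairs whose enhancer ends lie within `margin` bp of the TSSs of
    multiple genes (optional 'removeAmbiguousPairs'-style filter)."""
    tss_by_chrom = {
        chrom: np.array([g.tss for g in registry.by_chrom(chrom)])
        for chrom in registry.chroms()
    }
    kept = []
    for p in pairs:
        tss = tss_by_chrom.get(p.enhancer.chrom, np.array([]))
        n_near = 0
        for endpoint in (p.enhancer.start, p.enhancer.end):
            n_near = max(n_near, int(np.sum(np.abs(tss - endpoint) <= margin)))
        if n_near < 2:
            kept.append(p)
    return kept


def preprocess_pairs(
    pairs: Sequence[BenchmarkPair],
    registry: GeneRegistry,
    window: int = 5000,
) -> list[BenchmarkPair]:
    """Trim enhancers by promoter windows and merge overlapping enhancers
    within the dataset, carrying gene links (and labels) through.

    A pair whose enhancer vanishes inside a promoter window is dropped.  Two
    overlapping enhancers linked to different genes become one merged
    enhancer with two pairs.
    """
    windows = registry.promoter_windows(window)
    trimmed: list[tuple[GenomicInterval, str, str]] = []
    for p in pairs:
        for piece in subtract_intervals([p.enhancer], windows):
            trimmed.append((piece, p.gene_id, p.label))
    merged = merge_intervals([t[0] for t in trimmed])
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in merged:
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    out: dict[tuple[GenomicInterval, str, str], None] = {}
    for piece, gene_id, label in trimmed:
        for hit in trees[piece.chrom].overlap(piece.start, piece.end):
            out[(hit.data, gene_id, label)] = None
    return [BenchmarkPair(iv, g, lab) for (iv, g, lab) in out]


def fix_negative_ratio(
    bench: BenchmarkPairSet, ratio: int = 4, seed: int = 0
) -> BenchmarkPairSet:
    """Subsample negatives to ratio x #positives (uniform, seeded).  If there
    are not enough negatives, keep all with a warning."""
    pos, neg = bench.positives(), bench.negatives()
    want = ratio * len(pos)
    if len(neg) < want:
        warnings.warn(
            f"{bench.name}: only {len(neg)} negatives for {len(pos)} positives; keeping all"
        )
        return BenchmarkPairSet(pos + neg, bench.name, "fixed_1_to_4")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(neg), size=want, replace=False)
    return BenchmarkPairSet(pos + [neg[i] for i in sorted(idx)], bench.name, "fixed_1_to_4")


def call_pairs(
    entdef: EnTDef,
    bench: BenchmarkPairSet,
    registry: Optional[GeneRegistry] = None,
) -> BenchmarkScore:
    """Confusion counts over all benchmark pairs.

    Pairs whose gene is absent from the registry (when given) are dropped
    with a warning (they cannot be called).
    """
    if not len(bench):
        raise ValueError("empty benchmark")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for c, s, e, g in zip(
        entdef.records.chrom, entdef.records.start, entdef.records.end, entdef.records.gene_id
    ):
        trees[c].addi(int(s), int(e), g)
    tp = fp = tn = fn = 0
    n_dropped = 0
    for pair in bench.pairs:
        if registry is not None and pair.gene_id not in registry:
            n_dropped += 1
            continue
        genes_hit = {
            h.data for h in trees[pair.enhancer.chrom].overlap(pair.enhancer.start, pair.enhancer.end)
        }
        predicted = pair.gene_id in genes_hit
        if pair.label == "positive":
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} pair(s) with genes absent from the registry")
    return BenchmarkScore(TP=tp, FP=fp, TN=tn, FN=fn)


def _pair_matched(
    pair: tuple[GenomicInterval, str], trees: dict[str, IntervalTree]
) -> bool:
    iv, gene = pair
    return any(h.data == gene for h in trees[iv.chrom].overlap(iv.start, iv.end))


def overlap_coefficient(
    a: Sequence[tuple[GenomicInterval, str]], b: Sequence[tuple[GenomicInterval, str]]
) -> float:
    """Shared pairs / size of the smaller set.

    A pair of the smaller set is shared when some pair of the larger set has
    the same gene and an enhancer overlapping by >= 1 bp.  Both inputs should
    be preprocessed (promoter-trimmed, merged).
    """
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty pair sets")
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv, gene in large:
        trees[iv.chrom].addi(iv.start, iv.end, gene)
    shared = sum(1 for pair in small if _pair_matched(pair, trees))
    return shared / len(small)
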