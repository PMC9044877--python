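"""Domain types and genomic-interval set algebra.

All coordinates are 0-based, half-open (BED convention), everywhere:
an interval [start, end) covers bases start .. end-1.  Touching intervals
(end == start) merge, because the algebra has coverage semantics, not
record semantics.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class ChromSizes(dict):
    """Map chromosome name -> length in bp."""

    def __init__(self, sizes: dict[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for name, length in self.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def total_bp(self) -> int:
        return sum(self.values())


def validate_interval(iv: GenomicInterval, sizes: Optional[ChromSizes] = None) -> None:
    if not (0 <= iv.start < iv.end):
        raise ValueError(f"invalid interval {iv.chrom}:{iv.start}-{iv.end} (need 0 <= start < end)")
    if sizes is not None:
        if iv.chrom not in sizes:
            raise ValueError(f"chromosome {iv.chrom!r} not in chrom sizes")
        if iv.end > sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {sizes[iv.chrom]}"
            )


@dataclasses.dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(f"gene {self.gene_id}: tss {self.tss} outside body {self.body}")
        if self.body.chrom != self.chrom:
            raise ValueError(f"gene {self.gene_id}: body chromosome differs from gene chromosome")


class GeneRegistry:
    """All genes of a (toy or real) genome, with TSS anchors and chrom sizes."""

    def __init__(self, genes: Sequence[Gene], sizes: ChromSizes):
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in sizes:
                raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom!r} not in sizes")
            validate_interval(g.body, sizes)
        self.genes: tuple[Gene, ...] = tuple(genes)
        self.sizes = sizes
        self._by_id = {g.gene_id: g for g in self.genes}
        self._by_chrom: dict[str, list[Gene]] = defaultdict(list)
        for g in self.genes:
            self._by_chrom[g.chrom].append(g)
        # deterministic per-chromosome order: by (tss, gene_id)
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda g: (g.tss, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def by_chrom(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def chroms(self) -> list[str]:
        return sorted(self.sizes)

    def promoter_window(self, gene: Gene, window: int) -> GenomicInterval:
        start = max(0, gene.tss - window)
        end = min(self.sizes[gene.chrom], gene.tss + window)
        return GenomicInterval(gene.chrom, start, end)

    def promoter_windows(self, window: int) -> list[GenomicInterval]:
        """One (possibly overlapping) +-window/-window interval per gene."""
        return [self.promoter_window(g, window) for g in self.genes]


@dataclasses.dataclass
class PeakSet:
    name: str
    peaks: list[GenomicInterval]
    tf: Optional[str] = None
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.peaks):
                raise ValueError("weights length must match number of peaks")

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# interval set algebra
# ---------------------------------------------------------------------------


def _group_by_chrom(ivs: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in ivs:
        out[iv.chrom].append(iv)
    return out


def sort_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the same bases.

    Touching intervals (end == next start) are merged.
    """
    grouped = _group_by_chrom(ivs)
    out: list[GenomicInterval] = []
    for chrom in sorted(grouped):
        group = sorted(grouped[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = group[0].start, group[0].end
        for iv in group[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def _subtract_one(iv: GenomicInterval, blockers: list[GenomicInterval]) -> list[GenomicInterval]:
    """Subtract a merged, sorted, same-chromosome blocker list from one interval."""
    pieces: list[GenomicInterval] = []
    cursor = iv.start
    for b in blockers:
        if b.end <= cursor:
            continue
        if b.start >= iv.end:
            break
        if b.start > cursor:
            pieces.append(GenomicInterval(iv.chrom, cursor, min(b.start, iv.end)))
        cursor = max(cursor, b.end)
        if cursor >= iv.end:
            break
    if cursor < iv.end:
        pieces.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return pieces


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of a not covered by b; duplicates in a are preserved, empty remnants dropped."""
    b_merged = _group_by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in sort_intervals(a):
        out.extend(_subtract_one(iv, b_merged.get(iv.chrom, [])))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases covered by both merged(a) and merged(b)."""
    a_m = merge_intervals(a)
    b_m = _group_by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in a_m:
        for blocker in b_m.get(iv.chrom, []):
            s, e = max(iv.start, blocker.start), min(iv.end, blocker.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return sort_intervals(out)


def complement_intervals(
    ivs: Iterable[GenomicInterval], sizes: ChromSizes
) -> list[GenomicInterval]:
    """Bases of the genome not covered by ivs."""
    whole = [GenomicInterval(chrom, 0, length) for chrom, length in sorted(sizes.items())]
    return subtract_intervals(whole, ivs)


def total_bp(ivs: Iterable[GenomicInterval]) -> int:
    """Covered bases (after merging)."""
    return sum(iv.length for iv in merge_intervals(ivs))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def nearest_tss_partition(registry: GeneRegistry) -> list[tuple[GenomicInterval, str]]:
    """Tile each chromosome into one territory per gene, split at TSS midpoints.

    For adjacent TSSs t_left < t_right the boundary is
    (t_left + t_right + 1) // 2: bases strictly closer to the left TSS go
    left, and a base exactly equidistant belongs to the right gene.
    Chromosomes with no genes yield no pieces.
    """
    out: list[tuple[GenomicInterval, str]] = []
    for chrom in registry.chroms():
        genes = registry.by_chrom(chrom)
        if not genes:
            continue
        length = registry.sizes[chrom]
        bounds = [0]
        for left, right in zip(genes[:-1], genes[1:]):
            bounds.append((left.tss + right.tss + 1) // 2)
        bounds.append(length)
        for g, s, e in zip(genes, bounds[:-1], bounds[1:]):
            if s < e:
                out.append((GenomicInterval(chrom, s, e), g.gene_id))
    return out
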