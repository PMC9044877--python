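"""Readers and writers for the plain-text formats the tool touches.

Formats: BED3/BED6 (first 3 columns used), narrowPeak (first 3 columns),
BEDPE (6 coordinate columns + optional extras), GMT, 2-column parent-child
TSV (`child<TAB>parent`), gene-registry TSV
(`gene_id chrom strand tss body_start body_end`), chrom-sizes TSV
(`chrom length`), EnTDef / locus-definition TSV, benchmark-pair TSV.

All coordinates are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

from .core import ChromSizes, Gene, GeneRegistry, GenomicInterval, validate_interval
from .ontology import GeneSetCollection

PathLike = Union[str, Path]


class ParseError(ValueError):
    pass


def _rows(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _int(field: str, path: PathLike, lineno: int) -> int:
    try:
        return int(field)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate {field!r}") from None


def read_chrom_sizes(path: PathLike) -> ChromSizes:
    sizes: dict[str, int] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns (chrom, length)")
        chrom, length = fields[0], _int(fields[1], path, lineno)
        if chrom in sizes:
            raise ParseError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        sizes[chrom] = length
    return ChromSizes(sizes)


def read_bed(path: PathLike, sizes: Optional[ChromSizes] = None) -> list[GenomicInterval]:
    """Read BED3+/narrowPeak; returns intervals sorted by (chrom, start, end).

    Duplicate records are retained (collapsed only by merge_intervals).
    """
    out: list[GenomicInterval] = []
    for lineno, fields in _rows(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        iv = GenomicInterval(fields[0], _int(fields[1], path, lineno), _int(fields[2], path, lineno))
        try:
            validate_interval(iv, sizes)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        out.append(iv)
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(path: PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedpe(
    path: PathLike, sizes: Optional[ChromSizes] = None
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Read BEDPE anchor pairs; both intra- and inter-chromosomal accepted."""
    out: list[tuple[GenomicInterval, GenomicInterval]] = []
    for lineno, fields in _rows(path):
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected >=6 coordinate columns")
        a = GenomicInterval(fields[0], _int(fields[1], path, lineno), _int(fields[2], path, lineno))
        b = GenomicInterval(fields[3], _int(fields[4], path, lineno), _int(fields[5], path, lineno))
        try:
            validate_interval(a, sizes)
            validate_interval(b, sizes)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        out.append((a, b))
    return out


def write_bedpe(path: PathLike, pairs: Iterable[tuple[GenomicInterval, GenomicInterval]]) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


_REGISTRY_COLS = ("gene_id", "chrom", "strand", "tss", "body_start", "body_end")


def read_gene_registry(path: PathLike, sizes_path: PathLike) -> GeneRegistry:
    sizes = read_chrom_sizes(sizes_path)
    genes: list[Gene] = []
    for lineno, fields in _rows(path):
        if fields[: len(_REGISTRY_COLS)] == list(_REGISTRY_COLS):
            continue  # header
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns {_REGISTRY_COLS}")
        gene_id, chrom, strand = fields[0], fields[1], fields[2]
        tss = _int(fields[3], path, lineno)
        body = GenomicInterval(chrom, _int(fields[4], path, lineno), _int(fields[5], path, lineno))
        try:
            genes.append(Gene(gene_id, chrom, strand, tss, body))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return GeneRegistry(genes, sizes)


def write_gene_registry(path: PathLike, registry: GeneRegistry, sizes_path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REGISTRY_COLS) + "\n")
        for g in registry.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.body.start}\t{g.body.end}\n")
    with open(sizes_path, "w") as fh:
        for chrom, length in sorted(registry.sizes.items()):
            fh.write(f"{chrom}\t{length}\n")


def read_gene_sets(
    gmt_path: PathLike, dag_path: Optional[PathLike] = None, namespace: str = "BP"
) -> GeneSetCollection:
    """GMT lines: term_id <TAB> description <TAB> gene ids...; DAG TSV: child <TAB> parent."""
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, fields in _rows(gmt_path):
        if len(fields) < 2:
            raise ParseError(f"{gmt_path}:{lineno}: expected term_id, description, genes...")
        term_id = fields[0]
        if term_id in terms:
            raise ParseError(f"{gmt_path}:{lineno}: duplicate term {term_id!r}")
        descriptions[term_id] = fields[1]
        terms[term_id] = {g for g in fields[2:] if g}
    dag: dict[str, list[str]] = {}
    if dag_path is not None:
        for lineno, fields in _rows(dag_path):
            if len(fields) < 2:
                raise ParseError(f"{dag_path}:{lineno}: expected child<TAB>parent")
            dag.setdefault(fields[0], []).append(fields[1])
    return GeneSetCollection(terms, dag, namespace=namespace, descriptions=descriptions)


def write_gene_sets(
    gmt_path: PathLike, collection: GeneSetCollection, dag_path: Optional[PathLike] = None
) -> None:
    with open(gmt_path, "w") as fh:
        for term in collection.term_ids():
            desc = collection.descriptions.get(term, term)
            genes = "\t".join(sorted(collection.genes(term)))
            fh.write(f"{term}\t{desc}" + (f"\t{genes}" if genes else "") + "\n")
    if dag_path is not None:
        with open(dag_path, "w") as fh:
            for child in sorted(collection.dag_parents):
                for parent in collection.dag_parents[child]:
                    fh.write(f"{child}\t{parent}\n")


def read_benchmark_pairs(
    path: PathLike, sizes: Optional[ChromSizes] = None
) -> list[tuple[GenomicInterval, str, str]]:
    """Benchmark TSV: chrom start end gene_id label, label in {positive, negative}."""
    out = []
    for lineno, fields in _rows(path):
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected chrom start end gene_id label")
        iv = GenomicInterval(fields[0], _int(fields[1], path, lineno), _int(fields[2], path, lineno))
        try:
            validate_interval(iv, sizes)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        label = fields[4]
        if label not in ("positive", "negative"):
            raise ParseError(f"{path}:{lineno}: label must be positive/negative, got {label!r}")
        out.append((iv, fields[3], label))
    return out


def validate_file(path: PathLike, fmt: str, sizes: Optional[ChromSizes] = None) -> int:
    """Parse a file strictly; returns the number of records (CLI `validate`)."""
    if fmt == "bed":
        return len(read_bed(path, sizes))
    if fmt == "bedpe":
        return len(read_bedpe(path, sizes))
    if fmt == "gmt":
        return len(read_gene_sets(path))
    if fmt == "registry":
        if sizes is None:
            raise ValueError("registry validation requires chrom sizes")
        import tempfile, os

        with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as tmp:
            for chrom, length in sizes.items():
                tmp.write(f"{chrom}\t{length}\n")
        try:
            return len(read_gene_registry(path, tmp.name))
        finally:
            os.unlink(tmp.name)
    raise ValueError(f"unknown format {fmt!r}")
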