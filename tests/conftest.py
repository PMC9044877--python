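"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from entdef_forge import (
    ChromSizes,
    Gene,
    GeneRegistry,
    GenomicInterval,
    GeneSetCollection,
)

# ---------------------------------------------------------------------------
# per-base boolean-array oracles (independent of the interval implementation)
# ---------------------------------------------------------------------------


def coverage_mask(intervals, chrom: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray, chrom: str):
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append(GenomicInterval(chrom, start, i))
            start = None
    if start is not None:
        out.append(GenomicInterval(chrom, start, len(mask)))
    return out


def random_intervals(rng, chrom: str, length: int, n: int, max_len: int = 200):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, length - 1))
        e = min(length, s + 1 + int(rng.integers(0, max_len)))
        out.append(GenomicInterval(chrom, s, e))
    return out


# ---------------------------------------------------------------------------
# exact signed-rank oracle: brute-force enumeration of all sign assignments
# ---------------------------------------------------------------------------


def brute_force_signed_rank_p(d: np.ndarray) -> float:
    """Two-sided Pratt signed-rank p by enumerating all 2^n sign flips of the
    non-zero differences (feasible for n <= 12)."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    nz = d != 0
    r = ranks[nz]
    signs = np.sign(d[nz])
    n = r.size
    if n == 0:
        return 1.0
    w_obs = r[signs > 0].sum()
    sums = []
    for flips in itertools.product((0, 1), repeat=n):
        sums.append(sum(ri for ri, f in zip(r, flips) if f))
    sums = np.array(sums)
    total = sums.size
    p_le = np.sum(sums <= w_obs + 1e-9) / total
    p_ge = np.sum(sums >= w_obs - 1e-9) / total
    return min(1.0, 2 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# small genomes
# ---------------------------------------------------------------------------


@pytest.fixture
def toy_sizes():
    return ChromSizes({"chr1": 100_000})


@pytest.fixture
def two_gene_registry(toy_sizes):
    genes = [
        Gene("geneA", "chr1", "+", 10_000, GenomicInterval("chr1", 10_000, 14_000)),
        Gene("geneB", "chr1", "-", 30_000, GenomicInterval("chr1", 26_000, 30_001)),
    ]
    return GeneRegistry(genes, toy_sizes)


@pytest.fixture
def five_gene_registry():
    sizes = ChromSizes({"chr1": 200_000})
    genes = [
        Gene(f"g{i}", "chr1", "+", tss, GenomicInterval("chr1", tss, tss + 5_000))
        for i, tss in enumerate([15_000, 52_000, 90_000, 131_000, 170_000])
    ]
    return GeneRegistry(genes, sizes)


@pytest.fixture
def chain_collection():
    """A <- B <- C <- D chain (D deepest leaf) with gene sets of varied size."""
    genes = [f"g{i}" for i in range(60)]
    terms = {
        "A": set(genes[:50]),
        "B": set(genes[:35]),
        "C": set(genes[:20]),
        "D": set(genes[:16]),
    }
    dag = {"B": ["A"], "C": ["B"], "D": ["C"]}
    return GeneSetCollection(terms, dag)


@pytest.fixture(scope="session")
def default_sim():
    """One shared default-parameter simulation (seed 1): registry + regulome."""
    from entdef_forge import SimulationSpec, make_toy_genome, make_toy_regulome

    spec = SimulationSpec(seed=1)
    registry = make_toy_genome(spec)
    regulome = make_toy_regulome(spec, registry)
    return spec, registry, regulome
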