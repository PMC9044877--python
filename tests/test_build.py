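"""Definition assembly: trimming, extension, link derivation, fallback
partition, enumeration closed forms, and summary statistics."""

import numpy as np
import pytest

from entdef_forge import (
    ChromSizes,
    EnhancerSource,
    EnTDefConfig,
    Gene,
    GeneRegistry,
    GenomicInterval,
    LinkEvidence,
    PeakSet,
    assemble_entdef,
    entdef_stats,
    enumerate_definitions,
    extend_enhancers,
    import_pair_links,
    links_from_loops,
    map_anchor_pairs_to_links,
    merge_intervals,
    subtract_intervals,
    total_bp,
    trim_promoter_windows,
)
from entdef_forge.build import nearest_tss_fallback_records

from conftest import coverage_mask, mask_to_intervals, random_intervals

IV = GenomicInterval


@pytest.fixture
def one_gene_registry():
    sizes = ChromSizes({"chr1": 200_000})
    genes = [Gene("geneA", "chr1", "+", 100_000, IV("chr1", 100_000, 110_000))]
    return GeneRegistry(genes, sizes)


class TestTrimPromoterWindows:
    def test_partial_overlap(self, one_gene_registry):
        # window [95000, 105000); the region keeps only its distal tail
        out = trim_promoter_windows([IV("chr1", 97_000, 107_000)], one_gene_registry, 5000)
        assert out == [IV("chr1", 105_000, 107_000)]

    def test_wholly_inside_dropped(self, one_gene_registry):
        assert trim_promoter_windows([IV("chr1", 96_000, 104_000)], one_gene_registry) == []

    def test_overlapping_windows_match_oracle(self, two_gene_registry):
        rng = np.random.default_rng(1)
        length = 100_000
        regions = random_intervals(rng, "chr1", length, 60, max_len=4000)
        out = trim_promoter_windows(regions, two_gene_registry, 5000)
        win_mask = np.zeros(length, dtype=bool)
        for g in two_gene_registry.genes:
            win_mask[max(0, g.tss - 5000) : g.tss + 5000] = True
        expected = coverage_mask(regions, "chr1", length) & ~win_mask
        assert merge_intervals(out) == mask_to_intervals(expected, "chr1")

    def test_requires_positive_window(self, one_gene_registry):
        with pytest.raises(ValueError):
            trim_promoter_windows([], one_gene_registry, 0)


class TestExtendEnhancers:
    def test_short_region_recentred(self, one_gene_registry):
        out = extend_enhancers([IV("chr1", 1000, 1400)], one_gene_registry, 1000)
        assert out == [IV("chr1", 700, 1700)]

    def test_long_region_unchanged(self, one_gene_registry):
        out = extend_enhancers([IV("chr1", 0, 2000)], one_gene_registry, 1000)
        assert out == [IV("chr1", 0, 2000)]

    def test_odd_target_rejected(self, one_gene_registry):
        with pytest.raises(ValueError):
            extend_enhancers([], one_gene_registry, 999)

    def test_extension_retrimmed_near_promoter(self, one_gene_registry):
        # short region just distal of the window; extension would invade it
        out = extend_enhancers([IV("chr1", 105_100, 105_300)], one_gene_registry, 1000)
        assert out == [IV("chr1", 105_000, 105_700)]
        # per-base oracle on random regions
        rng = np.random.default_rng(2)
        regions = random_intervals(rng, "chr1", 200_000, 50, max_len=1500)
        regions = trim_promoter_windows(regions, one_gene_registry)
        out = extend_enhancers(regions, one_gene_registry, 1000)
        win = np.zeros(200_000, dtype=bool)
        win[95_000:105_000] = True
        expected = np.zeros(200_000, dtype=bool)
        for iv in regions:
            if iv.length >= 1000:
                expected[iv.start : iv.end] = True
            else:
                mid = (iv.start + iv.end) // 2
                expected[max(0, mid - 500) : min(200_000, mid + 500)] = True
        expected &= ~win
        assert merge_intervals(out) == mask_to_intervals(expected, "chr1")


class TestLinkDerivation:
    def test_pair_overlap_rule(self, two_gene_registry):
        enhancers = [IV("chr1", 150, 400), IV("chr1", 1000, 1100)]
        links = import_pair_links([(IV("chr1", 100, 200), "geneA")], enhancers, two_gene_registry)
        assert links == [(0, "geneA")]

    def test_pair_without_overlap_or_gene(self, two_gene_registry):
        enhancers = [IV("chr1", 1000, 1100)]
        assert import_pair_links([(IV("chr1", 100, 200), "geneA")], enhancers, two_gene_registry) == []
        with pytest.warns(UserWarning, match="absent"):
            out = import_pair_links([(IV("chr1", 1000, 1100), "nope")], enhancers, two_gene_registry)
        assert out == []

    def test_pair_spanning_two_fragments_links_both(self, two_gene_registry):
        enhancers = [IV("chr1", 100, 200), IV("chr1", 300, 400)]
        links = import_pair_links([(IV("chr1", 150, 350), "geneB")], enhancers, two_gene_registry)
        assert links == [(0, "geneB"), (1, "geneB")]

    def test_pair_links_match_all_pairs_scan(self, five_gene_registry):
        rng = np.random.default_rng(3)
        enhancers = random_intervals(rng, "chr1", 200_000, 40, max_len=2000)
        gene_ids = five_gene_registry.gene_ids()
        pairs = [
            (iv, gene_ids[int(rng.integers(len(gene_ids)))])
            for iv in random_intervals(rng, "chr1", 200_000, 60, max_len=2000)
        ]
        links = set(import_pair_links(pairs, enhancers, five_gene_registry))
        expected = {
            (i, g)
            for piv, g in pairs
            for i, e in enumerate(enhancers)
            if e.start < piv.end and piv.start < e.end
        }
        assert links == expected

    def test_anchor_pairs(self, two_gene_registry):
        enhancers = [IV("chr1", 18_000, 19_000)]
        # anchor2 covers geneB's TSS at 30000
        anchors = [(IV("chr1", 18_200, 18_400), IV("chr1", 29_500, 30_500))]
        links = map_anchor_pairs_to_links(anchors, enhancers, two_gene_registry, 5000)
        assert links == [(0, "geneB")]
        # swapped orientation also works
        links = map_anchor_pairs_to_links(
            [(a2, a1) for a1, a2 in anchors], enhancers, two_gene_registry, 5000
        )
        assert links == [(0, "geneB")]

    def test_anchor_away_from_tss_no_link(self, two_gene_registry):
        enhancers = [IV("chr1", 18_000, 19_000)]
        anchors = [(IV("chr1", 18_200, 18_400), IV("chr1", 60_000, 60_200))]
        assert map_anchor_pairs_to_links(anchors, enhancers, two_gene_registry, 5000) == []

    def test_anchor_spanning_two_windows_links_both(self):
        sizes = ChromSizes({"chr1": 100_000})
        genes = [
            Gene("gA", "chr1", "+", 40_000, IV("chr1", 40_000, 42_000)),
            Gene("gB", "chr1", "+", 47_000, IV("chr1", 47_000, 49_000)),
        ]
        registry = GeneRegistry(genes, sizes)
        enhancers = [IV("chr1", 10_000, 11_000)]
        anchors = [(IV("chr1", 10_100, 10_300), IV("chr1", 42_500, 43_000))]
        # [42500,43000) lies in both [35000,45000) and [42000,52000)
        links = map_anchor_pairs_to_links(anchors, enhancers, registry, 5000)
        assert links == [(0, "gA"), (0, "gB")]

    def test_loop_gene_budget(self, two_gene_registry):
        enhancers = [IV("chr1", 18_000, 19_000)]
        loop = [IV("chr1", 5_000, 35_000)]  # spans both TSSs
        assert links_from_loops(loop, enhancers, two_gene_registry, 1) == []
        assert links_from_loops(loop, enhancers, two_gene_registry, 2) == [
            (0, "geneA"),
            (0, "geneB"),
        ]

    def test_loops_match_triple_scan(self, five_gene_registry):
        rng = np.random.default_rng(4)
        enhancers = random_intervals(rng, "chr1", 200_000, 30, max_len=2000)
        loops = random_intervals(rng, "chr1", 200_000, 10, max_len=80_000)
        for max_genes in (1, 2, 3):
            got = set(links_from_loops(loops, enhancers, five_gene_registry, max_genes))
            expected = set()
            for loop in loops:
                genes_in = [
                    g.gene_id
                    for g in five_gene_registry.genes
                    if loop.start <= g.tss < loop.end
                ]
                if not (1 <= len(genes_in) <= max_genes):
                    continue
                for i, e in enumerate(enhancers):
                    if e.start < loop.end and loop.start < e.end:
                        expected.update((i, g) for g in genes_in)
            assert got == expected


class TestNearestAllFallback:
    def test_midpoint_boundary_and_excision(self, two_gene_registry):
        fallback = nearest_tss_fallback_records(
            [IV("chr1", 12_000, 13_000)], two_gene_registry, 5000
        )
        recs = {(r.start, r.end, r.gene_id) for r in fallback.itertuples()}
        # geneA territory [0,20000) minus promoter [5000,15000) and the enhancer
        assert (0, 5_000, "geneA") in recs
        assert (20_000, 25_000, "geneB") in recs
        assert not any(s < 13_000 < e or s < 12_500 < e for s, e, _ in recs if s >= 12_000 and e <= 13_000)

    def test_partition_matches_per_base_argmin(self, five_gene_registry):
        rng = np.random.default_rng(5)
        covered = random_intervals(rng, "chr1", 200_000, 25, max_len=3000)
        fallback = nearest_tss_fallback_records(covered, five_gene_registry, 5000)
        length = 200_000
        blocked = coverage_mask(covered, "chr1", length)
        for g in five_gene_registry.genes:
            blocked[max(0, g.tss - 5000) : g.tss + 5000] = True
        tss = np.array([g.tss for g in five_gene_registry.genes])
        ids = [g.gene_id for g in five_gene_registry.genes]
        owner = np.full(length, -1)
        for r in fallback.itertuples():
            owner[r.start : r.end] = ids.index(r.gene_id)
        for base in range(0, length, 509):
            if blocked[base]:
                assert owner[base] == -1
            else:
                dist = np.abs(tss - base)
                assert owner[base] == np.flatnonzero(dist == dist.min())[-1]


def _mini_setup():
    sizes = ChromSizes({"chr1": 100_000})
    genes = [
        Gene("gA", "chr1", "+", 20_000, IV("chr1", 20_000, 24_000)),
        Gene("gB", "chr1", "+", 70_000, IV("chr1", 70_000, 74_000)),
    ]
    registry = GeneRegistry(genes, sizes)
    sources = [
        EnhancerSource("s1", [IV("chr1", 40_000, 41_000), IV("chr1", 50_000, 50_400)]),
        EnhancerSource("s2", [IV("chr1", 40_500, 42_000)]),
    ]
    evidence = [
        LinkEvidence("pair_table", "p1", [(IV("chr1", 40_200, 40_800), "gA")]),
        LinkEvidence("pair_table", "p2", [(IV("chr1", 50_000, 50_100), "gB")]),
        LinkEvidence("loops", "loop", [IV("chr1", 39_000, 75_000)]),
    ]
    return registry, sources, evidence


class TestAssemble:
    def test_composition_identity_single_pair_table(self):
        registry, sources, evidence = _mini_setup()
        cfg = EnTDefConfig(enhancer_sources=("s1",), link_methods=("p1",))
        d = assemble_entdef(cfg, sources, evidence, registry)
        assert len(d) == 1
        rec = d.records.iloc[0]
        assert (rec.chrom, rec.start, rec.end, rec.gene_id) == ("chr1", 40_000, 41_000, "gA")
        assert rec.link_methods == "p1" and not rec.fallback

    def test_merged_sources_inherit_labels(self):
        registry, sources, evidence = _mini_setup()
        cfg = EnTDefConfig(enhancer_sources=("s1", "s2"), link_methods=("p1",))
        d = assemble_entdef(cfg, sources, evidence, registry)
        rec = d.records.iloc[0]
        # s1 and s2 regions merge into [40000,42000); both labels carried
        assert (rec.start, rec.end) == (40_000, 42_000)
        assert rec.sources == "s1,s2"

    def test_unlinked_enhancers_dropped(self):
        registry, sources, evidence = _mini_setup()
        cfg = EnTDefConfig(enhancer_sources=("s1",), link_methods=("p1",))
        d = assemble_entdef(cfg, sources, evidence, registry)
        # the [50000,50400) enhancer has no p1 link and vanishes
        assert 50_000 not in set(d.records.start)

    def test_unknown_names_rejected(self):
        registry, sources, evidence = _mini_setup()
        with pytest.raises(ValueError):
            assemble_entdef(
                EnTDefConfig(enhancer_sources=("nope",), link_methods=("p1",)),
                sources, evidence, registry,
            )
        with pytest.raises(ValueError):
            assemble_entdef(
                EnTDefConfig(enhancer_sources=("s1",), link_methods=("nope",)),
                sources, evidence, registry,
            )

    def test_loop_variant_requires_loop_evidence(self):
        registry, sources, evidence = _mini_setup()
        cfg = EnTDefConfig(enhancer_sources=("s1",), link_methods=(), loop_variant=2)
        d = assemble_entdef(cfg, sources, evidence, registry)
        assert set(d.records.link_methods) == {"L2"}
        with pytest.raises(ValueError, match="no loop evidence"):
            assemble_entdef(cfg, sources, [e for e in evidence if e.method != "loops"], registry)

    def test_no_locus_in_promoter_window(self):
        registry, sources, evidence = _mini_setup()
        cfg = EnTDefConfig(
            enhancer_sources=("s1", "s2"), link_methods=("p1", "p2"),
            loop_variant=2, extend=True, nearest_all=True,
        )
        d = assemble_entdef(cfg, sources, evidence, registry)
        windows = registry.promoter_windows(5000)
        from entdef_forge import intersect_intervals

        assert intersect_intervals(d.loci(), windows) == []

    def test_nearest_all_covers_all_distal_bases(self):
        registry, sources, evidence = _mini_setup()
        cfg = EnTDefConfig(
            enhancer_sources=("s1", "s2"), link_methods=("p1", "p2"), nearest_all=True
        )
        d = assemble_entdef(cfg, sources, evidence, registry)
        windows = registry.promoter_windows(5000)
        distal = 100_000 - total_bp(windows)
        assert total_bp(d.loci()) == distal

    def test_deterministic_and_monotone(self):
        registry, sources, evidence = _mini_setup()
        cfg = EnTDefConfig(enhancer_sources=("s1", "s2"), link_methods=("p1",))
        d1 = assemble_entdef(cfg, sources, evidence, registry)
        d2 = assemble_entdef(cfg, sources, evidence, registry)
        assert d1.records.equals(d2.records)
        # adding evidence never removes links
        cfg2 = EnTDefConfig(enhancer_sources=("s1", "s2"), link_methods=("p1", "p2"))
        d3 = assemble_entdef(cfg2, sources, evidence, registry)
        assert d1.link_pairs() <= d3.link_pairs()

    def test_tsv_round_trip(self, tmp_path):
        registry, sources, evidence = _mini_setup()
        cfg = EnTDefConfig(enhancer_sources=("s1",), link_methods=("p1",), nearest_all=True)
        d = assemble_entdef(cfg, sources, evidence, registry)
        path = tmp_path / "d.tsv"
        d.to_tsv(path)
        from entdef_forge import EnTDef

        again = EnTDef.from_tsv(path)
        assert again.records[["chrom", "start", "end", "gene_id", "fallback"]].equals(
            d.records[["chrom", "start", "end", "gene_id", "fallback"]]
        )


class TestEnumeration:
    def test_closed_form_for_arbitrary_counts(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            s = int(rng.integers(1, 5))
            k = int(rng.integers(1, 4))
            v = int(rng.integers(1, 4))
            configs = enumerate_definitions(
                [f"S{i}" for i in range(s)],
                [f"M{i}" for i in range(k)],
                list(range(1, v + 1)),
                toggles=True,
            )
            expected = (2**s - 1) * ((2**k - 1) * (1 + v) + v) * 4
            assert len(configs) == expected
            assert len(set(configs)) == expected  # all distinct

    def test_ct_mode_closed_form(self):
        for s, v in [(4, 3), (2, 1), (3, 2)]:
            configs = enumerate_definitions(
                [f"S{i}" for i in range(s)], ["ChIA"], list(range(1, v + 1)),
                toggles=True, ct_mode=True, interaction_name="ChIA",
            )
            assert len(configs) == (2**s - 1) * (1 + 2 * v) * 4

    def test_toy_workflow_count(self):
        # 2 sources, 2 non-loop links, 1 loop variant: 3 x 7 x 4 = 84
        configs = enumerate_definitions(["a", "b"], ["x", "y"], [1], toggles=True)
        assert len(configs) == 84


class TestStats:
    def test_coverage_fraction(self, two_gene_registry):
        import pandas as pd
        from entdef_forge import EnTDef

        rec = pd.DataFrame(
            [("chr1", 0, 90_000, "geneA", "s", "m", False)],
            columns=["chrom", "start", "end", "gene_id", "sources", "link_methods", "fallback"],
        )
        st = entdef_stats(EnTDef(rec), two_gene_registry)
        assert st.genome_coverage_fraction == pytest.approx(0.9)
        assert st.n_enhancers == 1

    def test_distal_peak_catch(self, two_gene_registry):
        import pandas as pd
        from entdef_forge import EnTDef

        rec = pd.DataFrame(
            [("chr1", 40_000, 60_000, "geneA", "s", "m", False)],
            columns=["chrom", "start", "end", "gene_id", "sources", "link_methods", "fallback"],
        )
        peaks = PeakSet(
            "p",
            [
                IV("chr1", 45_000, 45_200),  # distal, caught
                IV("chr1", 80_000, 80_200),  # distal, missed
                IV("chr1", 10_000, 10_200),  # promoter-proximal: excluded
            ],
        )
        st = entdef_stats(EnTDef(rec), two_gene_registry, peaks)
        assert st.distal_peak_catch_fraction == pytest.approx(0.5)
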