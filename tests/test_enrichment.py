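"""Hypergeometric windows, region calling and cluster overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import hypergeom_tail_exact, recount_window
from bgcscan.io import ClusterInterval, ContigRecord, GeneAnnotation, GeneModel, build_layout
from bgcscan.enrichment import (
    EnrichedRegion,
    ScanParams,
    WindowScanResult,
    assign_genes,
    call_regions,
    hypergeom_upper_tail,
    overlap_with_clusters,
    scan,
)
from bgcscan.simulate import (
    PlantedRegion,
    SimulationConfig,
    plant_label_enrichment,
    simulate_annotation,
    simulate_genome,
)


class TestHypergeomUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 10, 50) == 1.0

    def test_all_labeled_is_one(self):
        assert hypergeom_upper_tail(3, 3, 10, 10) == pytest.approx(1.0)

    def test_matches_enumeration_example(self):
        # N=20, K=5, n=5, k=3: direct combinatorial sum
        assert hypergeom_upper_tail(3, 5, 5, 20) == pytest.approx(
            hypergeom_tail_exact(3, 5, 5, 20), abs=1e-14
        )

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(6, 5, 5, 20)  # k > n
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 5, 25, 20)  # K > N
        with pytest.raises(ValueError):
            hypergeom_upper_tail(-1, 5, 5, 20)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_enumeration(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(
            hypergeom_tail_exact(k, n, K, N), abs=1e-12
        )

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_k(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ps = [hypergeom_upper_tail(k, n, K, N) for k in range(min(n, K) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


def _uniform_annotation(contig_len: int, spacing: int, n: int) -> GeneAnnotation:
    genes = []
    for i in range(n):
        s = 1 + i * spacing
        e = s + 99
        genes.append(GeneModel(f"g{i:04d}", "c1", s, e, "+", ((s, e),)))
    return GeneAnnotation(genes)


class TestAssignGenes:
    def test_midpoint_anchor(self):
        layout = build_layout([ContigRecord("c1", 200_000)])
        ann = GeneAnnotation([GeneModel("g", "c1", 101, 200, "+", ((101, 200),))])
        (a,) = assign_genes(layout, ann, {"g": "CAZy"})
        assert a.global_pos == (101 + 200) // 2 - 1  # 0-based
        assert a.labeled

    def test_start_anchor_uses_offset(self):
        layout = build_layout(
            [ContigRecord("big", 300_000), ContigRecord("small", 150_000)]
        )
        ann = GeneAnnotation([GeneModel("g", "small", 5, 104, "+", ((5, 104),))])
        (a,) = assign_genes(layout, ann, {}, ScanParams(gene_anchor="start"))
        assert a.global_pos == 300_000 + 5 - 1

    def test_genes_on_excluded_contigs_dropped(self):
        layout = build_layout(
            [ContigRecord("big", 300_000), ContigRecord("tiny", 50_000)]
        )
        ann = GeneAnnotation(
            [
                GeneModel("g1", "big", 1, 100, "+", ((1, 100),)),
                GeneModel("g2", "tiny", 1, 100, "+", ((1, 100),)),
            ]
        )
        anchors = assign_genes(layout, ann, {})
        assert [a.gene_id for a in anchors] == ["g1"]


class TestScan:
    def test_window_start_arithmetic(self):
        layout = build_layout([ContigRecord("c1", 250_000)])
        ann = _uniform_annotation(250_000, 1000, 200)
        labels = {"g0000": "CAZy"}
        res = scan(layout, ann, labels, ScanParams())
        starts = [r.global_start for r in res]
        assert starts == list(range(0, 250_000, 10_000))
        # trailing windows truncate at the contig end
        assert res[-1].global_end == 250_000
        assert res[0].global_end == 100_000

    def test_all_labeled_gives_p_one(self):
        layout = build_layout([ContigRecord("c1", 250_000)])
        ann = _uniform_annotation(250_000, 1000, 200)
        labels = {g.id: "CAZy" for g in ann}
        res = scan(layout, ann, labels, ScanParams())
        assert all(r.p_value == pytest.approx(1.0) for r in res if r.n > 0)

    def test_no_labeled_genes_is_error(self):
        layout = build_layout([ContigRecord("c1", 250_000)])
        ann = _uniform_annotation(250_000, 1000, 200)
        with pytest.raises(ValueError, match="no labeled genes"):
            scan(layout, ann, {}, ScanParams())

    def test_empty_windows_report_p_one(self):
        layout = build_layout([ContigRecord("c1", 400_000)])
        # genes only in the first 100 kb
        ann = _uniform_annotation(400_000, 1000, 100)
        res = scan(layout, ann, {"g0000": "CAZy"}, ScanParams())
        empty = [r for r in res if r.n == 0]
        assert empty and all(r.p_value == 1.0 for r in empty)

    def test_disjoint_tiling_conserves_counts(self):
        # step == window: each gene in exactly one window
        layout = build_layout([ContigRecord("c1", 500_000)])
        ann = _uniform_annotation(500_000, 777, 600)
        labels = {g.id: "CAZy" for i, g in enumerate(ann) if i % 7 == 0}
        res = scan(
            layout, ann, labels, ScanParams(window_size=50_000, step=50_000)
        )
        assert sum(r.n for r in res) == len(ann)
        assert sum(r.k for r in res) == len(labels)

    def test_counts_match_exhaustive_recount(self):
        cfg = SimulationConfig(
            seed=42,
            contig_lengths=(1_200_000, 400_000),
            planted_regions=(PlantedRegion("contig001", 500_000, 600_000, 10.0),),
        )
        contigs = simulate_genome(cfg, with_sequence=False)
        ann = simulate_annotation(contigs, cfg)
        labels, _ = plant_label_enrichment(ann, cfg)
        layout = build_layout(contigs)
        params = ScanParams()
        anchors = assign_genes(layout, ann, labels, params)
        res = scan(layout, ann, labels, params)
        for r in res[::7]:  # spot-check a deterministic subset
            k, n = recount_window(anchors, r.global_start, r.global_end)
            assert (r.k, r.n) == (k, n)
            assert r.p_value == pytest.approx(
                hypergeom_tail_exact(k, n, r.K, r.N), abs=1e-12
            )

    def test_minimum_p_window_overlaps_planted_region(self):
        cfg = SimulationConfig(
            seed=5,
            contig_lengths=(3_000_000,),
            mean_bp_per_gene=3000.0,
            planted_regions=(PlantedRegion("contig001", 1_000_000, 1_100_000, 10.0),),
        )
        contigs = simulate_genome(cfg, with_sequence=False)
        ann = simulate_annotation(contigs, cfg)
        labels, _ = plant_label_enrichment(ann, cfg)
        layout = build_layout(contigs)
        res = scan(layout, ann, labels, ScanParams())
        best = min(res, key=lambda r: r.p_value)
        assert best.global_start < 1_100_000 and best.global_end > 1_000_000


def _w(contig, start, end, p):
    return WindowScanResult(contig, start, end, 1, 10, 50, 1000, p)


class TestCallRegions:
    def test_no_significant_windows(self):
        assert call_regions([_w("c", 0, 100_000, 0.5)], 0.01) == []

    def test_overlapping_windows_merge(self):
        res = [
            _w("c", 0, 100_000, 0.001),
            _w("c", 10_000, 110_000, 0.005),
            _w("c", 20_000, 120_000, 0.0001),
        ]
        (region,) = call_regions(res, 0.01)
        assert (region.global_start, region.global_end) == (0, 120_000)
        assert region.n_windows == 3
        assert region.min_p == 0.0001

    def test_regions_never_span_contigs(self):
        res = [_w("c1", 0, 100_000, 0.001), _w("c2", 100_000, 200_000, 0.001)]
        assert len(call_regions(res, 0.01)) == 2

    def test_threshold_is_strict(self):
        assert call_regions([_w("c", 0, 100_000, 0.01)], 0.01) == []

    def test_disjoint_significant_windows_stay_separate(self):
        res = [_w("c", 0, 100_000, 0.001), _w("c", 200_000, 300_000, 0.001)]
        regions = call_regions(res, 0.01)
        assert [(r.global_start, r.global_end) for r in regions] == [
            (0, 100_000),
            (200_000, 300_000),
        ]


class TestOverlapWithClusters:
    def _layout(self):
        return build_layout([ContigRecord("c1", 500_000), ContigRecord("c2", 300_000)])

    def test_single_bp_overlap_counts(self):
        layout = self._layout()
        regions = [EnrichedRegion("c1", 0, 120_000, 3, 1e-4)]
        clusters = [ClusterInterval("cl1", "c1", 120_000, 130_000)]
        rep = overlap_with_clusters(regions, clusters, layout)
        assert rep.pairs[0][2] == 1
        assert rep.n_regions_overlapping == 1

    def test_different_contigs_do_not_overlap(self):
        layout = self._layout()
        regions = [EnrichedRegion("c1", 0, 120_000, 3, 1e-4)]
        clusters = [ClusterInterval("cl1", "c2", 1, 130_000)]
        rep = overlap_with_clusters(regions, clusters, layout)
        assert rep.pairs == () and rep.n_regions_overlapping == 0

    def test_counts_deduplicate(self):
        layout = self._layout()
        regions = [
            EnrichedRegion("c1", 0, 120_000, 3, 1e-4),
            EnrichedRegion("c1", 200_000, 300_000, 2, 1e-3),
            EnrichedRegion("c2", 0, 50_000, 1, 1e-3),
        ]
        clusters = [
            ClusterInterval("cl1", "c1", 1, 10_000),
            ClusterInterval("cl2", "c1", 50_000, 60_000),
        ]
        rep = overlap_with_clusters(regions, clusters, layout)
        assert rep.n_regions_overlapping == 1
        assert rep.n_clusters_overlapping == 2

    def test_cluster_on_excluded_contig_skipped(self, caplog):
        layout = build_layout(
            [ContigRecord("c1", 500_000), ContigRecord("tiny", 50_000)]
        )
        regions = [EnrichedRegion("c1", 0, 120_000, 3, 1e-4)]
        clusters = [ClusterInterval("cl1", "tiny", 1, 10_000)]
        with caplog.at_level("WARNING"):
            rep = overlap_with_clusters(regions, clusters, layout)
        assert rep.n_clusters == 0
        assert "excluded" in caplog.text
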