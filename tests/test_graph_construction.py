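"""Graph assembly: promoter spans, probe clustering, linking and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossomics.graphs import (CpGCluster, GeneRecord, MirnaTargetRecord,
                               ProbeRecord, RELATION_GC, RELATION_MG,
                               assemble_graph, build_graph, cluster_probes,
                               dedup_by_variance, define_promoter_spans,
                               degree_preserving_rewire, filter_mirna_targets,
                               link_cpg_to_genes, summarize_cluster_methylation)


def gene(gene_id="G1", strand="+", tss=(10_000,), chrom="chr1"):
    return GeneRecord(gene_id=gene_id, symbol=gene_id, chrom=chrom,
                      strand=strand, tss_positions=list(tss))


class TestPromoterSpans:
    @pytest.mark.parametrize("strand,tss,first,last", [
        ("+", 10_000, 8_000, 10_500),   # 2000 upstream .. 500 downstream
        ("-", 10_000, 9_500, 12_000),   # strand-mirrored window
    ])
    def test_window_is_strand_aware(self, strand, tss, first, last):
        (span,) = define_promoter_spans([gene(strand=strand, tss=(tss,))])
        assert (span.start, span.end - 1) == (first, last)
        assert span.end - span.start == 2501  # 2000 + TSS + 500 positions

    def test_clipping_at_chromosome_start(self):
        (span,) = define_promoter_spans([gene(tss=(100,))])
        assert span.start == 0 and span.end == 601

    def test_multi_tss_gene_yields_one_span_per_tss(self):
        spans = define_promoter_spans([gene(tss=(10_000, 20_000, 30_000))])
        assert len(spans) == 3
        assert {s.source_tss for s in spans} == {10_000, 20_000, 30_000}

    def test_unknown_strand_rejected_with_warning(self, caplog):
        spans = define_promoter_spans([gene(strand="?")])
        assert spans == [] and "unknown strand" in caplog.text

    @given(tss=st.integers(min_value=0, max_value=10**8),
           up=st.integers(min_value=1, max_value=10_000),
           down=st.integers(min_value=1, max_value=10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_span_length_without_clipping(self, tss, up, down):
        (span,) = define_promoter_spans([gene(tss=(tss,))], upstream=up,
                                        downstream=down)
        if tss - up >= 0:
            assert span.end - span.start == up + down + 1


class TestProbeClustering:
    def probes(self, positions, chrom="chr1", missing=0.0):
        return [ProbeRecord(probe_id=f"p{i}", chrom=chrom, pos=pos,
                            missing_fraction=missing)
                for i, pos in enumerate(positions)]

    def test_chain_breaks_beyond_gap(self):
        # 550-100=450 <= 500 joins; 1200-550=650 > 500 starts a new chain,
        # which stays a dropped singleton
        clusters = cluster_probes(self.probes([100, 550, 1200]))
        assert len(clusters) == 1
        assert clusters[0].member_probe_ids == ["p0", "p1"]

    def test_gap_threshold_is_inclusive(self):
        clusters = cluster_probes(self.probes([0, 500, 1000]))
        assert len(clusters) == 1 and len(clusters[0].member_probe_ids) == 3

    def test_high_missingness_probe_removed_before_chaining(self):
        probes = self.probes([100, 550])
        probes.append(ProbeRecord(probe_id="bad", chrom="chr1", pos=300,
                                  missing_fraction=0.2))
        clusters = cluster_probes(probes)
        assert all("bad" not in c.member_probe_ids for c in clusters)

    def test_empty_input_gives_empty_output(self):
        assert cluster_probes([]) == []

    @given(st.lists(st.integers(min_value=0, max_value=50_000),
                    min_size=0, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_permutation_invariance_and_member_gaps(self, positions):
        probes = self.probes(positions)
        shuffled = list(reversed(probes))
        a = cluster_probes(probes)
        b = cluster_probes(shuffled)
        assert [c.cluster_id for c in a] == [c.cluster_id for c in b]
        pos = {p.probe_id: p.pos for p in probes}
        for c in a:
            assert len(c.member_probe_ids) >= 2
            ordered = sorted(pos[pid] for pid in c.member_probe_ids)
            assert all(b2 - a2 <= 500 for a2, b2 in zip(ordered, ordered[1:]))
            assert c.span_start <= c.representative_pos <= c.span_end

    def test_idempotent_on_own_members(self):
        probes = self.probes([0, 400, 800, 5_000, 5_300, 9_999])
        clusters = cluster_probes(probes)
        retained = {pid for c in clusters for pid in c.member_probe_ids}
        again = cluster_probes([p for p in probes if p.probe_id in retained])
        assert [c.member_probe_ids for c in again] == \
               [c.member_probe_ids for c in clusters]


class TestClusterMethylation:
    def test_mean_of_member_probes(self):
        cluster = CpGCluster("c1", "chr1", ["p0", "p1"], 0, 100, 50)
        beta = np.array([[0.2, 0.4]])
        out = summarize_cluster_methylation(beta, ["p0", "p1"], [cluster])
        assert out[0, 0] == pytest.approx(0.3)

    def test_three_probe_mean(self):
        cluster = CpGCluster("c1", "chr1", ["p0", "p1", "p2"], 0, 100, 50)
        out = summarize_cluster_methylation(np.array([[0.1, 0.2, 0.9]]),
                                            ["p0", "p1", "p2"], [cluster])
        assert out[0, 0] == pytest.approx(0.4)

    def test_constant_betas_preserved(self):
        cluster = CpGCluster("c1", "chr1", ["p0", "p1"], 0, 100, 50)
        out = summarize_cluster_methylation(np.full((3, 2), 0.7),
                                            ["p0", "p1"], [cluster])
        assert np.allclose(out, 0.7)

    def test_missing_probe_is_an_error_naming_it(self):
        cluster = CpGCluster("c1", "chr1", ["p0", "absent"], 0, 100, 50)
        with pytest.raises(KeyError, match="absent"):
            summarize_cluster_methylation(np.zeros((1, 1)), ["p0"], [cluster])


class TestPromoterLinking:
    def test_containment_and_exclusion(self):
        spans = define_promoter_spans([gene(tss=(10_000,))])
        inside = CpGCluster("cin", "chr1", ["a", "b"], 8_900, 9_100, 9_000)
        outside = CpGCluster("cout", "chr1", ["c", "d"], 6_900, 7_100, 7_000)
        pairs = link_cpg_to_genes([inside, outside], spans)
        assert pairs == [("cin", "G1")]

    def test_overlapping_promoters_give_many_to_many(self):
        genes = [gene("G1", tss=(10_000,)), gene("G2", tss=(10_400,))]
        spans = define_promoter_spans(genes)
        cluster = CpGCluster("c", "chr1", ["a", "b"], 8_900, 9_100, 9_000)
        assert link_cpg_to_genes([cluster], spans) == [("c", "G1"), ("c", "G2")]

    def test_multi_tss_duplicates_collapse(self):
        spans = define_promoter_spans([gene(tss=(10_000, 10_200))])
        cluster = CpGCluster("c", "chr1", ["a", "b"], 8_900, 9_300, 9_100)
        assert link_cpg_to_genes([cluster], spans) == [("c", "G1")]

    def test_equals_brute_force_double_loop(self, fixture_graph):
        spans = define_promoter_spans(fixture_graph["genes"])
        clusters = fixture_graph["clusters"]
        expected = set()
        for c in clusters:
            for s in spans:
                if c.chrom == s.chrom and s.start <= c.representative_pos < s.end:
                    expected.add((c.cluster_id, s.gene_id))
        assert set(link_cpg_to_genes(clusters, spans)) == expected


class TestTargetFilter:
    @pytest.mark.parametrize("score,kept", [(-0.35, True), (-0.2, True),
                                            (-0.1, False)])
    def test_threshold_is_inclusive(self, score, kept):
        rec = MirnaTargetRecord("miR-1", "G1", score)
        assert bool(filter_mirna_targets([rec])) is kept

    def test_duplicates_collapse_and_universe_restriction(self):
        recs = [MirnaTargetRecord("miR-1", "G1", -0.5),
                MirnaTargetRecord("miR-1", "G1", -0.3),
                MirnaTargetRecord("miR-1", "G9", -0.5)]
        pairs = filter_mirna_targets(recs, gene_universe={"G1"})
        assert pairs == [("miR-1", "G1")]


class TestDedupByVariance:
    def test_highest_variance_wins(self):
        out = dedup_by_variance([("f", "a", 0.1), ("f", "b", 0.7)])
        assert out == {"f": "b"}

    def test_single_candidate_identity(self):
        assert dedup_by_variance([("f", "a", 0.0)]) == {"f": "a"}

    def test_tie_breaks_lexicographically(self):
        out = dedup_by_variance([("f", "zeta", 0.5), ("f", "alpha", 0.5)])
        assert out == {"f": "alpha"}


class TestAssembly:
    def test_unknown_edge_endpoint_is_error(self):
        genes = [gene("G1")]
        clusters = [CpGCluster("c1", "chr1", ["a", "b"], 0, 100, 50)]
        with pytest.raises(KeyError, match="ghost"):
            assemble_graph(genes, clusters, [("ghost", "G1")], [])

    def test_stage_counts_monotone_for_filtered_entities(self, fixture_graph):
        stages = fixture_graph["graph"].stage_counts
        raw = next(s for s in stages if s["stage"] == "raw")
        final = next(s for s in stages if s["stage"] == "final")
        assert final["genes"] <= raw["genes"]
        assert final["cpg_clusters"] <= raw["probes"]

    def test_graph_invariants(self, fixture_graph):
        g = fixture_graph["graph"]
        for rel in (RELATION_GC, RELATION_MG):
            e = g.edges[rel]
            assert len({tuple(r) for r in e.tolist()}) == len(e)

    def test_rewiring_preserves_degree_sequences(self, fixture_graph):
        g = fixture_graph["graph"]
        rewired = degree_preserving_rewire(g, np.random.default_rng(0))
        for rel in (RELATION_GC, RELATION_MG):
            a, b = g.edges[rel], rewired.edges[rel]
            assert len(a) == len(b)
            for col in (0, 1):
                assert np.array_equal(np.bincount(a[:, col]),
                                      np.bincount(b[:, col]))
        assert rewired.fingerprint() != g.fingerprint()
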