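"""Segment graphs, derivative walks, transcript explanation, dup motif."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from nrgfusion.reconstruction import (
    DerivativeModel,
    build_segment_graph,
    detect_dup_with_inverted_insertion,
    enumerate_walks,
    explain_transcript,
    to_dot,
    validate_walk,
)
from nrgfusion.sv_integration import LEFT, RIGHT, Breakend, SvJunction
from nrgfusion.synthetic_data import apply_rearrangement, get_preset

EXTENTS = {"chr8": 200_000, "chr11": 200_000}


def _j(jid, c1, p1, r1, c2, p2, r2):
    return SvJunction(id=jid, end_a=Breakend(c1, p1, r1), end_b=Breakend(c2, p2, r2))


class TestGraphConstruction:
    def test_single_deletion_gives_three_segments_one_variant_adjacency(self):
        deletion = _j("D", "chr8", 1_000, LEFT, "chr8", 5_000, RIGHT)
        graph = build_segment_graph([deletion], {"chr8": 10_000})
        assert len(graph.segments) == 3
        assert len(graph.breakpoints["chr8"]) == 2
        variants = [a for a in graph.adjacencies if a.kind == "variant"]
        assert len(variants) == 1
        # the variant adjacency joins segment 0's right end to segment 2's left
        assert {variants[0].a, variants[0].b} == {(0, "R"), (2, "L")}

    def test_inversion_junction_joins_like_ends(self):
        inv = _j("I", "chr8", 2_000, LEFT, "chr8", 6_000, LEFT)
        graph = build_segment_graph([inv], {"chr8": 10_000})
        variants = [a for a in graph.adjacencies if a.kind == "variant"]
        assert variants[0].a[1] == variants[0].b[1] == "R"

    def test_out_of_extent_breakend_rejected(self):
        j = _j("X", "chr8", 50_000, LEFT, "chr8", 60_000, RIGHT)
        with pytest.raises(ValueError, match="extent"):
            build_segment_graph([j], {"chr8": 10_000})

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 9_999),
                st.sampled_from([LEFT, RIGHT]),
                st.integers(1, 9_999),
                st.sampled_from([LEFT, RIGHT]),
            ),
            max_size=10,
        )
    )
    def test_segment_count_is_breakpoints_plus_one_per_chromosome(self, specs):
        junctions = [
            _j(f"J{i}", "chr8", p1, r1, "chr8", p2, r2)
            for i, (p1, r1, p2, r2) in enumerate(specs)
        ]
        graph = build_segment_graph(junctions, {"chr8": 10_000})
        n_segments = sum(1 for s in graph.segments if s.chrom == "chr8")
        assert n_segments == len(graph.breakpoints["chr8"]) + 1
        variants = [a for a in graph.adjacencies if a.kind == "variant"]
        assert len(variants) == len(junctions)


class TestWalks:
    def test_deletion_walk_skips_middle_segment(self):
        deletion = _j("D", "chr8", 1_000, LEFT, "chr8", 5_000, RIGHT)
        graph = build_segment_graph([deletion], {"chr8": 10_000})
        walks = enumerate_walks(graph, start_segment=0, max_length=3)
        target = ((0, "+"), (2, "+"))
        assert any(w.walk == target for w in walks)
        assert all(validate_walk(graph, w) for w in walks)

    def test_inversion_walk_requires_orientation_flip(self):
        # the variant adjacency joins two right ends, so following it from
        # segment 0 enters segment 1 reversed
        inv = _j("I", "chr8", 2_000, LEFT, "chr8", 6_000, LEFT)
        graph = build_segment_graph([inv], {"chr8": 10_000})
        walks = enumerate_walks(graph, start_segment=0, max_length=3)
        assert any(w.walk[:2] == ((0, "+"), (1, "-")) for w in walks)
        assert not any(w.walk[:2] == ((0, "+"), (2, "+")) for w in walks)

    def test_graph_without_variants_yields_only_reference_walks(self):
        graph = build_segment_graph([], {"chr8": 10_000})
        walks = enumerate_walks(graph, max_length=4)
        assert all(len(w.walk) == 1 for w in walks)  # single segment, no joins

    def test_every_enumerated_walk_passes_independent_checker(self):
        case = get_preset("mda175")
        graph = build_segment_graph(case.junctions, EXTENTS)
        walks = enumerate_walks(graph, start_segment=0, max_length=5)
        assert walks
        assert all(validate_walk(graph, w) for w in walks)


class TestExplainTranscript:
    @pytest.fixture()
    def truth_setup(self, toy):
        case = get_preset("mda175")
        _, _, truth = apply_rearrangement(toy.genome, case.walk, name="der")
        graph = build_segment_graph(truth, EXTENTS)
        start = graph.segment_at("chr11", 0)
        walks = enumerate_walks(graph, start_segment=start.id, max_length=6)
        return graph, walks

    def test_truth_walk_explains_all_observed_junctions(self, toy, truth_setup):
        graph, walks = truth_setup
        observed = [
            ("PPP6R3:1", "TENM4:3"),
            ("TENM4:12", "TENM4:int15"),
            ("TENM4:int15", "NRG1:3"),
            ("TENM4:12", "NRG1:3"),
        ]
        full = [
            w
            for w in walks
            if all(explain_transcript(w, graph, toy.genes, d, a) for d, a in observed[:3])
        ]
        assert full, "no walk explains the planted double fusion"
        assert all(validate_walk(graph, w) for w in full)

    def test_walk_without_inverted_fragment_cannot_explain_cryptic_junction(self, toy):
        # a derivative with a direct middle-gene -> 3'-gene join (no inverted
        # insert) explains the canonical junction but never the cryptic-exon
        # junction: the antisense exon is in reverse sense on that walk
        no_insert_walk = [
            ("chr11", 0, 6_000, "+"),
            ("chr11", 45_999, 86_000, "+"),
            ("chr8", 65_999, 200_000, "+"),
        ]
        _, _, truth = apply_rearrangement(toy.genome, no_insert_walk, name="alt")
        graph = build_segment_graph(truth, EXTENTS)
        start = graph.segment_at("chr11", 0)
        walks = enumerate_walks(graph, start_segment=start.id, max_length=6)
        direct = [
            w for w in walks if explain_transcript(w, graph, toy.genes, "TENM4:12", "NRG1:3")
        ]
        assert direct
        for w in walks:
            assert not explain_transcript(w, graph, toy.genes, "TENM4:int15", "NRG1:3")

    def test_empty_walk_explains_nothing(self, toy, truth_setup):
        graph, _ = truth_setup
        empty = DerivativeModel(walk=())
        assert not explain_transcript(empty, graph, toy.genes, "TENM4:12", "NRG1:3")


class TestRoundTrip:
    def test_derivative_built_from_walk_is_recovered(self, toy):
        # synthetic derivative -> truth junctions -> graph -> a walk that
        # explains the planted transcripts, with multiplicity 1 per segment
        case = get_preset("mda175")
        _, seq, truth = apply_rearrangement(toy.genome, case.walk, name="der")
        graph = build_segment_graph(truth, EXTENTS)
        start = graph.segment_at("chr11", 0)
        walks = enumerate_walks(graph, start_segment=start.id, max_length=6)
        good = [
            w
            for w in walks
            if explain_transcript(w, graph, toy.genes, "TENM4:int15", "NRG1:3")
        ]
        assert good
        mult = good[0].multiplicities()
        assert all(v >= 1 for v in mult.values())


class TestDupInvInsertMotif:
    def test_motif_spans_recovered_from_junctions(self, toy):
        case = get_preset("dup_inv_insert")
        motif = detect_dup_with_inverted_insertion(case.junctions, gene=toy.genes["NRG1"])
        assert motif is not None
        assert motif.dup_span == 57_000
        assert motif.insert_span == 24_000

    def test_plain_tandem_duplication_does_not_match(self):
        dup_only = [
            _j("T", "chr8", 127_000, LEFT, "chr8", 70_001, RIGHT),
            _j("X1", "chr8", 1_000, LEFT, "chr11", 2_000, RIGHT),
            _j("X2", "chr8", 3_000, LEFT, "chr11", 4_000, RIGHT),
        ]
        assert detect_dup_with_inverted_insertion(dup_only) is None

    def test_any_single_side_flip_destroys_signature(self, toy):
        case = get_preset("dup_inv_insert")
        motif_junctions = [j for j in case.junctions if j.id in ("ZD1", "ZD2")]
        other = [j for j in case.junctions if j.id not in ("ZD1", "ZD2")]
        flip = {LEFT: RIGHT, RIGHT: LEFT}
        for idx in range(2):
            for end in ("end_a", "end_b"):
                mutated = []
                for i, j in enumerate(motif_junctions):
                    if i == idx:
                        be = getattr(j, end)
                        new_be = Breakend(be.chrom, be.pos, flip[be.retained])
                        j = SvJunction(
                            id=j.id,
                            end_a=new_be if end == "end_a" else j.end_a,
                            end_b=new_be if end == "end_b" else j.end_b,
                        )
                    mutated.append(j)
                motif = detect_dup_with_inverted_insertion(mutated + other, gene=toy.genes["NRG1"])
                assert motif is None or set(motif.junction_ids) != {"ZD1", "ZD2"}


def test_dot_export_mentions_every_segment():
    deletion = _j("D", "chr8", 1_000, LEFT, "chr8", 5_000, RIGHT)
    graph = build_segment_graph([deletion], {"chr8": 10_000})
    dot = to_dot(graph)
    for seg in graph.segments:
        assert f"s{seg.id}" in dot
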