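"""Breakend VCF decoding, somatic filtering and fusion-candidate prediction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from nrgfusion.sv_integration import (
    LEFT,
    RIGHT,
    Breakend,
    SvJunction,
    VcfBreakendError,
    breakpoints_in_gene,
    decode_bnd_alt,
    encode_bnd_alt,
    filter_somatic,
    parse_breakend_vcf,
    predict_fusion_from_junction,
    write_breakend_vcf,
)
from nrgfusion.synthetic_data import CHROM_LENGTHS, get_preset


def _junction(p1, r1, p2, r2, jid="J", c1="chr8", c2="chr8", **kw):
    return SvJunction(id=jid, end_a=Breakend(c1, p1, r1), end_b=Breakend(c2, p2, r2), **kw)


class TestBracketDecoding:
    # the four bracket cases of the VCF 4.2 breakend convention,
    # hand-enumerated: t before the bracket retains the local left side,
    # t after retains the right; [ means the mate retains its right side,
    # ] its left.
    @pytest.mark.parametrize(
        "alt,local,mate",
        [
            ("N[chr8:32236901[", LEFT, RIGHT),
            ("N]chr8:32236901]", LEFT, LEFT),
            ("]chr8:32236901]N", RIGHT, LEFT),
            ("[chr8:32236901[N", RIGHT, RIGHT),
        ],
    )
    def test_four_bracket_cases(self, alt, local, mate):
        chrom, pos, local_ret, mate_ret, ins = decode_bnd_alt(alt)
        assert (chrom, pos) == ("chr8", 32236901)
        assert (local_ret, mate_ret) == (local, mate)
        assert ins == ""

    def test_inserted_sequence_extracted(self):
        _, _, _, _, ins = decode_bnd_alt("NTTAC[chr8:100[")
        assert ins == "TTAC"

    def test_encode_decode_roundtrip(self):
        for local in (LEFT, RIGHT):
            for mate_ret in (LEFT, RIGHT):
                mate = Breakend("chr11", 78500000, mate_ret)
                alt = encode_bnd_alt("N", local, mate)
                chrom, pos, lr, mr, _ = decode_bnd_alt(alt)
                assert (chrom, pos, lr, mr) == ("chr11", 78500000, local, mate_ret)

    def test_malformed_alt_rejected(self):
        with pytest.raises(VcfBreakendError):
            decode_bnd_alt("N[chr8:100]")


class TestVcfRoundTrip:
    def test_written_vcf_reparses_identically(self, tmp_path):
        junctions = [
            _junction(32236901, LEFT, 78500000, RIGHT, jid="F", c2="chr11",
                      tumour_support=9, normal_support=0),
            _junction(100, RIGHT, 5000, LEFT, jid="I", inserted_sequence="GATTACA"),
        ]
        path = tmp_path / "j.vcf"
        write_breakend_vcf(junctions, path, CHROM_LENGTHS)
        parsed = parse_breakend_vcf(path)
        assert len(parsed) == 2
        for orig, new in zip(sorted(junctions, key=lambda j: j.id), parsed):
            assert new.canonical() == orig.canonical()

    def test_vcf_without_bnd_records_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr8,length=200000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr8\t100\tsnv1\tA\tC\t.\tPASS\t.\n"
        )
        assert parse_breakend_vcf(path) == []

    def test_missing_mate_is_an_error_naming_the_record(self, tmp_path):
        path = tmp_path / "orphan.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr8,length=200000>\n'
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">\n'
            '##INFO=<ID=MATEID,Number=1,Type=String,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr8\t100\torphan_1\tN\tN[chr8:500[\t.\tPASS\tSVTYPE=BND;MATEID=orphan_2\n"
        )
        with pytest.raises(VcfBreakendError, match="orphan_1"):
            parse_breakend_vcf(path)


class TestSomaticFilter:
    def test_normal_support_removes_junction(self):
        germline = _junction(100, LEFT, 500, RIGHT, normal_support=1)
        assert filter_somatic([germline]) == []

    def test_mitochondrial_breakend_removes_junction(self):
        mito = _junction(100, LEFT, 500, RIGHT, c1="chrM")
        unassembled = _junction(100, LEFT, 500, RIGHT, c2="chrUn_gl000220")
        assert filter_somatic([mito, unassembled]) == []

    def test_panel_match_requires_same_orientation_within_tolerance(self):
        j = _junction(1000, LEFT, 5000, RIGHT)
        near_panel = _junction(1004, LEFT, 4994, RIGHT, jid="P")
        flipped_panel = _junction(1004, RIGHT, 4994, RIGHT, jid="P2")
        far_panel = _junction(1020, LEFT, 5000, RIGHT, jid="P3")
        assert filter_somatic([j], panel=[near_panel]) == []
        assert filter_somatic([j], panel=[flipped_panel]) == [j]
        assert filter_somatic([j], panel=[far_panel]) == [j]

    def test_clean_somatic_junction_retained(self):
        j = _junction(1000, LEFT, 5000, RIGHT)
        assert filter_somatic([j]) == [j]

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 10**6),
                st.sampled_from([LEFT, RIGHT]),
                st.integers(1, 10**6),
                st.sampled_from([LEFT, RIGHT]),
                st.integers(0, 2),
            ),
            max_size=12,
        )
    )
    def test_filter_is_idempotent_and_a_subset(self, specs):
        junctions = [
            _junction(p1, r1, p2, r2, jid=f"J{i}", normal_support=ns)
            for i, (p1, r1, p2, r2, ns) in enumerate(specs)
        ]
        once = filter_somatic(junctions)
        assert filter_somatic(once) == once
        assert all(j in junctions for j in once)


class TestBreakpointsInGene:
    def test_seven_breakend_fixture(self, toy, nrg1):
        case = get_preset("mda175")
        record = breakpoints_in_gene(case.junctions, nrg1)
        assert record.n_breakpoints == 7
        assert record.multi_breakpoint

    def test_no_breakends_in_span(self, nrg1):
        record = breakpoints_in_gene([_junction(100, LEFT, 500, RIGHT)], nrg1)
        assert record.n_breakpoints == 0
        assert not record.multi_breakpoint

    def test_exactly_two_breakends_is_multi(self, nrg1):
        j = _junction(65_000, LEFT, 70_000, RIGHT)
        record = breakpoints_in_gene([j], nrg1)
        assert record.n_breakpoints == 2
        assert record.multi_breakpoint


class TestFusionPrediction:
    def test_deletion_join_predicts_spliced_in_exon_3(self, toy, nrg1):
        j = _junction(26_000, LEFT, 67_000, RIGHT)
        cand = predict_fusion_from_junction(j, [toy.genes["WRN"]], nrg1)
        assert cand is not None
        assert cand.five_prime_gene == "WRN"
        assert cand.spliced_in_exon == 3
        assert cand.last_partner_exon == 2

    def test_exactly_one_of_four_side_combinations_is_sense(self, toy, nrg1):
        hits = 0
        for r1 in (LEFT, RIGHT):
            for r2 in (LEFT, RIGHT):
                j = _junction(26_000, r1, 67_000, r2)
                cand = predict_fusion_from_junction(j, [toy.genes["WRN"]], nrg1)
                if cand is not None and not cand.five_prime_end_only:
                    hits += 1
        assert hits == 1

    def test_five_prime_end_only_flagged(self, toy, nrg1):
        # breakend in the 3' gene past the receptor-binding exon, retaining
        # only the gene's 5' part
        j = _junction(100_500, LEFT, 150_000, RIGHT, c2="chr11")
        cand = predict_fusion_from_junction(j, [toy.genes["WRN"]], nrg1)
        assert cand is not None and cand.five_prime_end_only

    def test_lowest_numbered_acceptor_is_chosen(self, toy, nrg1):
        # a breakend upstream of the whole gene splices into exon 3, not a
        # later acceptor
        j = _junction(26_000, LEFT, 61_000, RIGHT)
        cand = predict_fusion_from_junction(j, [toy.genes["WRN"]], nrg1)
        assert cand.spliced_in_exon == 3
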