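"""Anchor indexing, read scanning, flank classification, junction summaries."""

import pytest

from nrgfusion.gene_models import Exon, GeneModel, GenomeAssembly, revcomp
from nrgfusion.junction_scan import (
    AnchorCollisionError,
    build_anchor_index,
    call_junctions,
    classify_flank,
    scan_reads,
    summarise_junctions,
)
from nrgfusion.synthetic_data import (
    SimulationConfig,
    get_preset,
    simulate_background_reads,
    simulate_junction_reads,
    write_fastq,
)


def _scan_summary(toy, index, reads, tmp_path, dedup=False, min_flank=12):
    tmp_path.mkdir(parents=True, exist_ok=True)
    fastq = tmp_path / "reads.fastq"
    write_fastq(reads, fastq)
    hits = scan_reads(fastq, index, min_flank=min_flank)
    calls = call_junctions(hits, index, min_flank=min_flank)
    return summarise_junctions(calls, dedup=dedup)


class TestIndex:
    def test_index_covers_both_boundaries_of_every_exon(self, toy, anchor_index):
        n_exons = sum(len(g.all_exons()) for g in toy.genes.values())
        assert len(anchor_index.anchors) == 2 * n_exons

    def test_colliding_anchors_rejected(self):
        # two exons sharing their first 20-mer collide at k=20
        seq = "ACGTAGCTAGGATCCGATCC" * 10
        genome = GenomeAssembly({"c": seq})
        exons = (
            Exon(gene="A", chrom="c", start=0, end=40, strand="+", number=1, name="1"),
            Exon(gene="B", chrom="c", start=80, end=120, strand="+", number=1, name="1"),
        )
        genes = [
            GeneModel(name="A", chrom="c", strand="+", exons=exons[:1]),
            GeneModel(name="B", chrom="c", strand="+", exons=exons[1:]),
        ]
        with pytest.raises(AnchorCollisionError, match="collision"):
            build_anchor_index(genes, genome, k=20)

    def test_revcomp_query_hits_same_boundary(self, toy, anchor_index, tmp_path):
        exon3 = toy.genes["NRG1"].exon_by_number(3)
        anchor = toy.genome.fetch("chr8", exon3.start, exon3.start + 20)
        read = revcomp("A" * 30 + anchor + "C" * 25)
        fastq = tmp_path / "rc.fastq"
        write_fastq([("r1", read)], fastq)
        hits = scan_reads(fastq, anchor_index)
        assert any(
            h.anchor.exon.label == "NRG1:3" and h.read_strand == "revcomp" for h in hits
        )


class TestScanAndClassify:
    def test_planted_junction_read_recovered_with_flank(self, toy, anchor_index, tmp_path):
        t12 = toy.genes["TENM4"].exon_by_number(12).sequence(toy.genome)
        n3 = toy.genes["NRG1"].exon_by_number(3).sequence(toy.genome)
        read = t12[-30:] + n3[:20]
        fastq = tmp_path / "one.fastq"
        write_fastq([("r1", read)], fastq)
        hits = scan_reads(fastq, anchor_index)
        acc_hits = [h for h in hits if h.anchor.exon.label == "NRG1:3" and h.anchor.side == "acceptor"]
        assert len(acc_hits) == 1
        assert acc_hits[0].flank_sequence == t12[-30:]
        call = classify_flank(acc_hits[0], anchor_index)
        assert (call.acceptor, call.donor) == ("NRG1:3", "TENM4:12")

    def test_reverse_complemented_read_gives_identical_call(self, toy, anchor_index, tmp_path):
        t12 = toy.genes["TENM4"].exon_by_number(12).sequence(toy.genome)
        n3 = toy.genes["NRG1"].exon_by_number(3).sequence(toy.genome)
        read = t12[-30:] + n3[:45]
        s_fwd = _scan_summary(toy, anchor_index, [("r1", read)], tmp_path)
        s_rev = _scan_summary(toy, anchor_index, [("r1", revcomp(read))], tmp_path)
        assert s_fwd.equals(s_rev)

    def test_read_without_anchor_yields_no_hits(self, toy, anchor_index, tmp_path):
        fastq = tmp_path / "none.fastq"
        write_fastq([("r1", "ACGT" * 19)], fastq)
        assert scan_reads(fastq, anchor_index) == []

    def test_short_flank_is_too_short_and_excluded(self, toy, anchor_index, tmp_path):
        n3 = toy.genes["NRG1"].exon_by_number(3).sequence(toy.genome)
        t12 = toy.genes["TENM4"].exon_by_number(12).sequence(toy.genome)
        read = t12[-6:] + n3[:60]  # 6 bp donor flank < min_flank=12
        fastq = tmp_path / "short.fastq"
        write_fastq([("r1", read)], fastq)
        hits = scan_reads(fastq, anchor_index)
        calls = call_junctions(hits, anchor_index, min_flank=12)
        assert all(c.donor_kind == "too_short" for c in calls)
        assert summarise_junctions(calls).empty

    def test_unmatched_flank_reported_novel_verbatim(self, toy, anchor_index, tmp_path):
        n3 = toy.genes["NRG1"].exon_by_number(3).sequence(toy.genome)
        novel = "ATATATATATATCGCGCGCG"
        read = novel + n3[:55]
        fastq = tmp_path / "novel.fastq"
        write_fastq([("r1", read)], fastq)
        calls = call_junctions(scan_reads(fastq, anchor_index), anchor_index)
        novel_calls = [c for c in calls if c.donor_kind == "novel"]
        assert novel_calls and novel in novel_calls[0].donor

    def test_one_mismatch_mode_rescues_sequencing_error(self, toy, anchor_index, tmp_path):
        t12 = toy.genes["TENM4"].exon_by_number(12).sequence(toy.genome)
        n3 = toy.genes["NRG1"].exon_by_number(3).sequence(toy.genome)
        anchor = n3[:20]
        mutated = ("A" if anchor[10] != "A" else "C") + anchor[11:]
        read = t12[-30:] + anchor[:10] + mutated
        fastq = tmp_path / "mm.fastq"
        write_fastq([("r1", read)], fastq)
        exact = scan_reads(fastq, anchor_index, max_mismatches=0)
        assert not any(h.anchor.exon.label == "NRG1:3" for h in exact)
        hits = scan_reads(fastq, anchor_index, max_mismatches=1)
        assert any(h.anchor.exon.label == "NRG1:3" for h in hits)

    def test_malformed_fastq_names_record_index(self, toy, anchor_index, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(ValueError, match="record at index"):
            scan_reads(bad, anchor_index)


class TestSummaries:
    def test_minor_donor_fraction_of_split_reads(self, toy, anchor_index, tmp_path, config):
        # 38 cryptic-exon reads vs 122 canonical-donor reads at one acceptor:
        # the cryptic donor accounts for 24% of the 160 split reads
        comp = {("TENM4:int15", "NRG1:3"): 38, ("TENM4:12", "NRG1:3"): 122}
        reads = simulate_junction_reads(toy, comp, config)
        summary = _scan_summary(toy, anchor_index, reads, tmp_path)
        row = summary[(summary.acceptor == "NRG1:3") & (summary.donor == "TENM4:int15")]
        assert int(row["count"].iloc[0]) == 38
        assert int(row["total_at_acceptor"].iloc[0]) == 160
        assert int(row["percent"].iloc[0]) == 24

    def test_single_donor_is_100_percent(self, toy, anchor_index, tmp_path, config):
        reads = simulate_junction_reads(toy, {("WRN:2", "NRG1:3"): 7}, config)
        summary = _scan_summary(toy, anchor_index, reads, tmp_path)
        assert summary["percent"].tolist() == [100]

    def test_single_read_donor_counted_once_among_many(self, toy, anchor_index, tmp_path, config):
        # 1 of 145 split reads at the middle gene's exon-3 acceptor carries
        # the gene's own exon-2 donor; the rest splice in from the 5' gene
        comp = {("PPP6R3:1", "TENM4:3"): 144, ("TENM4:2", "TENM4:3"): 1}
        reads = simulate_junction_reads(toy, comp, config)
        summary = _scan_summary(toy, anchor_index, reads, tmp_path)
        row = summary[(summary.acceptor == "TENM4:3") & (summary.donor == "TENM4:2")]
        assert int(row["count"].iloc[0]) == 1
        assert int(row["total_at_acceptor"].iloc[0]) == 145

    def test_percentages_per_acceptor_sum_to_100(self, toy, anchor_index, tmp_path, config):
        case = get_preset("mda175")
        reads = simulate_junction_reads(toy, case.rna_composition, config)
        summary = _scan_summary(toy, anchor_index, reads, tmp_path)
        for _, grp in summary.groupby("acceptor"):
            assert abs(grp["percent"].sum() - 100) <= 1

    def test_strand_invariance_of_whole_summary(self, toy, anchor_index, tmp_path, config):
        case = get_preset("mda175")
        reads = simulate_junction_reads(toy, case.rna_composition, config)
        flipped = [(rid, revcomp(seq)) for rid, seq in reads]
        s1 = _scan_summary(toy, anchor_index, reads, tmp_path / "f")
        s2 = _scan_summary(toy, anchor_index, flipped, tmp_path / "r")
        assert s1.equals(s2)

    def test_normal_transcripts_give_no_cross_gene_calls(self, toy, anchor_index, tmp_path, config):
        reads = []
        for gene, n in (("NRG1", 60), ("TENM4", 60), ("PPP6R3", 40)):
            labels = [e.label for e in toy.genes[gene].exons]
            reads += simulate_background_reads(toy, labels, n, config, prefix=gene)
        summary = _scan_summary(toy, anchor_index, reads, tmp_path)
        for _, row in summary.iterrows():
            acc_gene = row["acceptor"].partition(":")[0]
            don_gene = row["donor"].partition(":")[0]
            assert acc_gene == don_gene

    def test_every_planted_read_recovered(self, toy, anchor_index, tmp_path, config):
        comp = {("WRN:2", "NRG1:3"): 25, ("TENM4:12", "NRG1:3"): 13}
        reads = simulate_junction_reads(toy, comp, config)
        summary = _scan_summary(toy, anchor_index, reads, tmp_path)
        by_donor = dict(zip(summary["donor"], summary["count"]))
        assert by_donor == {"WRN:2": 25, "TENM4:12": 13}

    def test_dedup_collapses_identical_reads(self, toy, anchor_index, tmp_path):
        t12 = toy.genes["TENM4"].exon_by_number(12).sequence(toy.genome)
        n3 = toy.genes["NRG1"].exon_by_number(3).sequence(toy.genome)
        read = t12[-30:] + n3[:45]
        reads = [(f"r{i}", read) for i in range(5)] + [("rc", revcomp(read))]
        s_dup = _scan_summary(toy, anchor_index, reads, tmp_path / "a", dedup=False)
        s_dedup = _scan_summary(toy, anchor_index, reads, tmp_path / "b", dedup=True)
        assert int(s_dup["count"].iloc[0]) == 6
        assert int(s_dedup["count"].iloc[0]) == 1
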