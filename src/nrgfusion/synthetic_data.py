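"""Seeded synthetic inputs: toy genome, derivatives, RNA reads, SV calls.

Everything the pipeline consumes can be generated here so all stages are
testable without external data.  The toy genome carries five mini genes on
two ~200 kb chromosomes, shaped like the loci the analysis targets:

* ``PPP6R3`` — a 5' gene whose first exon is non-coding;
* ``TENM4`` — a 16-exon middle gene hosting a 78-nt antisense cryptic
  exon ("int15") within its intron 15;
* ``NRG1`` — an 18-exon 3' gene with genome-order numbering, the
  alpha/beta alternative exons {10, 11}, a beta3 extension of exon 11,
  transmembrane exon 12 and cytoplasmic-tail exons 13-18, Ig-like exons
  3-4 and the EGF-like receptor-binding exon 9;
* ``WRN`` — the gene immediately 5' of NRG1, the canonical deletion-
  fusion partner;
* ``ZNF704`` — a partner whose fusions splice from an unannotated exon.

Rearrangement presets assemble derivative chromosomes from oriented
segment walks; junction-spanning RNA reads are planted at exact
configured counts (deterministic compositions) so downstream fractions
are reproducible, with a stochastic mode available through the base
error rate and read placement.  Reads are 75 bp by default, matching the
cohort's RNA libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .gene_models import (
    Exon,
    GeneModel,
    GenomeAssembly,
    gene_splice_anchors,
    load_gene_models,
    revcomp,
)
from .sv_integration import LEFT, RIGHT, Breakend, SvJunction, write_breakend_vcf, write_panel_bedpe

CHROM_LENGTHS = {"chr11": 200_000, "chr8": 200_000}
READ_LENGTH_DEFAULT = 75

# gene tables: exon tuples are (0-based start, length, cds_length)
_GENE_DEFS = {
    "PPP6R3": {
        "chrom": "chr11",
        "exons": [(5_000, 200, 0), (8_000, 150, 120), (11_000, 150, 150), (14_000, 150, 150), (17_000, 400, 90)],
        "tss": [1],
    },
    "TENM4": {
        "chrom": "chr11",
        "exons": [(40_000 + i * 4_000, 121 if i == 11 else (400 if i == 15 else 120), 0 if i == 0 else (121 if i == 11 else 120)) for i in range(16)],
        "tss": [1],
    },
    "ZNF704": {
        "chrom": "chr8",
        "exons": [(5_000, 120, 0), (6_500, 120, 120), (8_800, 200, 100)],
        "tss": [1],
    },
    "WRN": {
        "chrom": "chr8",
        "exons": [(20_000, 151, 100), (24_000, 150, 150), (28_000, 151, 151), (32_000, 400, 99)],
        "tss": [],
    },
    "NRG1": {
        "chrom": "chr8",
        "exons": [
            (60_000, 120, 0),
            (64_000, 150, 100),
            (68_000, 120, 120),
            (72_000, 120, 120),
            (76_000, 120, 120),
            (80_000, 120, 120),
            (84_000, 120, 0),
            (88_000, 120, 0),
            (92_000, 120, 120),
            (96_000, 120, 120),
            (100_000, 120, 120),
            (104_000, 120, 120),
            (108_000, 120, 120),
            (112_000, 120, 120),
            (116_000, 120, 120),
            (120_000, 120, 120),
            (124_000, 120, 120),
            (128_000, 400, 150),
        ],
        "tss": [1, 2, 7, 8],
    },
}

_NRG1_TAGS = {
    1: ["transcription_start"],
    2: ["transcription_start"],
    3: ["Ig_like"],
    4: ["Ig_like"],
    7: ["transcription_start"],
    8: ["transcription_start"],
    9: ["EGF_like"],
    12: ["transmembrane"],
    **{n: ["cytoplasmic_tail"] for n in range(13, 19)},
}

INT15 = {"name": "int15", "chrom": "chr11", "start0": 98_000, "length": 78}
ZNF704_NOVEL_EXON = ("chr8", 7_400, 7_481, "+")  # unannotated donor exon


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulator; identical configs give byte-identical outputs."""

    seed: int = 0
    read_length: int = READ_LENGTH_DEFAULT
    min_flank: int = 12
    base_error_rate: float = 0.0
    tumour_support: int = 8
    normal_support_germline: int = 2
    window_bp: int = 1_000

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed * 100_003 + salt) % (2**31))


@dataclass
class ToyData:
    genome: GenomeAssembly
    genes: dict
    paths: dict = field(default_factory=dict)

    @property
    def models(self) -> Mapping[str, GeneModel]:
        return self.genes


def _random_chromosome(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _transcripts_for(gene: str, n_exons: int):
    """Transcript exon-number lists written to the toy GTF."""
    if gene == "NRG1":
        return {
            "NRG1_beta": [1, 2, 3, 4, 5, 6, 9, 11] + list(range(12, 19)),
            "NRG1_alpha": [2, 3, 4, 5, 6, 9, 10] + list(range(12, 19)),
            "NRG1_minor": [7, 8, 9, 10] + list(range(12, 19)),
        }
    return {f"{gene}_t1": list(range(1, n_exons + 1))}


def write_toy_gtf(path) -> None:
    lines = []
    for gene, gdef in _GENE_DEFS.items():
        chrom = gdef["chrom"]
        exons = gdef["exons"]
        for tx, numbers in _transcripts_for(gene, len(exons)).items():
            cum = 0
            for num in numbers:
                start0, length, cds = exons[num - 1]
                attrs = f'gene_id "{gene}"; gene_name "{gene}"; transcript_id "{tx}";'
                lines.append(
                    f"{chrom}\ttoy\texon\t{start0 + 1}\t{start0 + length}\t.\t+\t.\t{attrs}"
                )
                if cds > 0:
                    cds_start0 = start0 + (length - cds if gene in ("WRN", "NRG1") and num in (1, 2) else 0)
                    frame = (3 - cum % 3) % 3
                    lines.append(
                        f"{chrom}\ttoy\tCDS\t{cds_start0 + 1}\t{cds_start0 + cds}\t.\t+\t{frame}\t{attrs}"
                    )
                cum += cds
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_model_overrides(path) -> None:
    ov = {
        "genes": {
            "NRG1": {
                "alt_groups": [[10, 11]],
                "tail_exons": list(range(12, 19)),
                "beta3_extension": {"start": 100_121, "end": 100_420},
                "tags": {str(k): v for k, v in _NRG1_TAGS.items()},
            },
            "TENM4": {
                "tags": {"1": ["transcription_start"]},
                "cryptic_exons": [
                    {
                        "name": INT15["name"],
                        "chrom": INT15["chrom"],
                        "start": INT15["start0"] + 1,
                        "end": INT15["start0"] + INT15["length"],
                        "strand": "-",
                        "cds_len": INT15["length"],
                    }
                ],
            },
            "PPP6R3": {"tags": {"1": ["transcription_start"]}},
            "ZNF704": {"tags": {"1": ["transcription_start"]}},
            "WRN": {"tags": {}},
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(ov, fh, sort_keys=True)


def _anchors_unique(genome: GenomeAssembly, genes: Mapping[str, GeneModel], k: int = 20) -> bool:
    counts: dict[str, int] = {}
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    seen = set()
    for gene in genes.values():
        for anchor in gene_splice_anchors(genome, gene, k):
            fwd, rev = anchor.sequence, revcomp(anchor.sequence)
            if counts.get(fwd, 0) + counts.get(rev, 0) != 1:
                return False
            if fwd in seen or rev in seen:
                return False
            seen.add(fwd)
    return True


def make_toy_genome(config: SimulationConfig = SimulationConfig(), outdir=None, k: int = 20) -> ToyData:
    """Generate the toy genome + GTF + model overrides (and load them back).

    The genome is random sequence under the config seed; generation
    retries with a derived seed in the (vanishingly unlikely) event that
    any splice anchor is not unique genome-wide at the chosen k, so the
    anchor-index construction is collision-free by construction.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    tmpdir = outdir if outdir is not None else Path(_scratch_dir())
    gtf_path = tmpdir / "genes.gtf"
    yaml_path = tmpdir / "models.yaml"
    fasta_path = tmpdir / "genome.fa"
    write_toy_gtf(gtf_path)
    write_model_overrides(yaml_path)

    for attempt in range(10):
        rng = config.rng(salt=17 + attempt)
        genome = GenomeAssembly(
            {name: _random_chromosome(rng, length) for name, length in CHROM_LENGTHS.items()}
        )
        genes = load_gene_models(gtf_path, yaml_path)
        if _anchors_unique(genome, genes, k=k):
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not generate a genome with unique anchors")
    genome.to_fasta(fasta_path)
    paths = {"genome": fasta_path, "gtf": gtf_path, "models": yaml_path}
    return ToyData(genome=genome, genes=genes, paths=paths)


def _scratch_dir():
    import tempfile

    return tempfile.mkdtemp(prefix="nrgfusion_toy_")


# ---------------------------------------------------------------------------
# Derivative chromosomes


def apply_rearrangement(
    genome: GenomeAssembly, walk: Sequence[tuple[str, int, int, str]], name: str = "der"
) -> tuple[str, str, list[SvJunction]]:
    """Assemble a derivative sequence from an oriented segment walk.

    ``walk`` entries are (chrom, start0, end0, orientation).  Returns the
    derivative name, its sequence, and the truth junctions created at the
    seams (with retained sides following the join directions).
    """
    pieces = []
    junctions = []
    for i, (chrom, start, end, orient) in enumerate(walk):
        seq = genome.fetch(chrom, start, end)
        pieces.append(seq if orient == "+" else revcomp(seq))
        if i > 0:
            pc, ps, pe, po = walk[i - 1]
            exit_be = (
                Breakend(pc, pe, LEFT) if po == "+" else Breakend(pc, ps + 1, RIGHT)
            )
            entry_be = (
                Breakend(chrom, start + 1, RIGHT) if orient == "+" else Breakend(chrom, end, LEFT)
            )
            junctions.append(
                SvJunction(id=f"{name}_j{i}", end_a=exit_be, end_b=entry_be)
            )
    return name, "".join(pieces), junctions


# ---------------------------------------------------------------------------
# RNA read simulation


def _exon_seq(toy: ToyData, label: str) -> str:
    if label == "NOVEL_ZNF704":
        chrom, s, e, strand = ZNF704_NOVEL_EXON
        seq = toy.genome.fetch(chrom, s, e)
        return seq if strand == "+" else revcomp(seq)
    gene_name, _, exon_name = label.partition(":")
    exon = toy.genes[gene_name].exon_by_name(exon_name)
    return exon.sequence(toy.genome)


def simulate_junction_reads(
    toy: ToyData,
    composition: Mapping[tuple[str, str], int],
    config: SimulationConfig = SimulationConfig(),
) -> list[tuple[str, str]]:
    """Junction-spanning reads at exact configured counts.

    Each (donor_label, acceptor_label) -> count entry yields ``count``
    reads drawn across the spliced junction at seeded uniform offsets,
    with at least ``min_flank`` bases on each side; about half the reads
    are emitted reverse-complemented.  Optional uniform base errors.
    Returns (read_id, sequence) pairs.
    """
    rng = config.rng(salt=101)
    rl, mf = config.read_length, config.min_flank
    reads = []
    for (donor, acceptor), count in sorted(composition.items()):
        up = _exon_seq(toy, donor)
        down = _exon_seq(toy, acceptor)
        if len(up) < rl - mf or len(down) < rl - mf:
            raise ValueError(f"context too short for junction {donor}->{acceptor}")
        for i in range(count):
            o = int(rng.integers(mf, rl - mf + 1))  # upstream bases in read
            seq = up[len(up) - o :] + down[: rl - o]
            if config.base_error_rate > 0:
                seq = _add_errors(seq, config.base_error_rate, rng)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"sim:{donor.replace(':', '.')}-{acceptor.replace(':', '.')}:{i}"
            reads.append((rid, seq))
    return reads


def simulate_background_reads(
    toy: ToyData,
    transcript_exons: Sequence[str],
    n_reads: int,
    config: SimulationConfig = SimulationConfig(),
    prefix: str = "bg",
) -> list[tuple[str, str]]:
    """Uniformly placed reads from a spliced transcript (exon label list)."""
    rng = config.rng(salt=211)
    tx = "".join(_exon_seq(toy, lbl) for lbl in transcript_exons)
    rl = config.read_length
    if len(tx) < rl:
        raise ValueError("transcript shorter than read length")
    reads = []
    for i in range(n_reads):
        off = int(rng.integers(0, len(tx) - rl + 1))
        seq = tx[off : off + rl]
        if config.base_error_rate > 0:
            seq = _add_errors(seq, config.base_error_rate, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"{prefix}:{i}", seq))
    return reads


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(out)


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# SV call simulation


def simulate_sv_vcf(
    truth_junctions: Sequence[SvJunction],
    config: SimulationConfig,
    outdir,
    include_artefacts: bool = True,
) -> dict:
    """Emit tumour/normal paired VCF + panel BEDPE for a junction set.

    Truth junctions get tumour support and zero normal support.  With
    ``include_artefacts``, a germline junction (normal support present), a
    panel-of-normals junction, and a mitochondrial-contig junction are
    planted so every somatic filter is exercised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = dict(CHROM_LENGTHS)
    somatic = [
        replace(j, tumour_support=j.tumour_support or config.tumour_support)
        for j in truth_junctions
    ]
    extras: list[SvJunction] = []
    panel: list[SvJunction] = []
    if include_artefacts:
        germline = SvJunction(
            id="germline1",
            end_a=Breakend("chr11", 120_000, LEFT),
            end_b=Breakend("chr11", 125_000, RIGHT),
            tumour_support=4,
            normal_support=config.normal_support_germline,
        )
        panel_hit = SvJunction(
            id="panelhit1",
            end_a=Breakend("chr8", 40_000, LEFT),
            end_b=Breakend("chr8", 45_000, RIGHT),
            tumour_support=5,
        )
        contigs["chrM"] = 16_571
        mito = SvJunction(
            id="mito1",
            end_a=Breakend("chrM", 500, LEFT),
            end_b=Breakend("chr8", 70_000, RIGHT),
            tumour_support=3,
        )
        extras = [germline, panel_hit, mito]
        panel = [
            SvJunction(
                id="pon1",
                end_a=Breakend("chr8", 40_003, LEFT),
                end_b=Breakend("chr8", 45_002, RIGHT),
            )
        ]
    vcf_path = outdir / "tumour_normal.vcf"
    bedpe_path = outdir / "panel_of_normals.bedpe"
    write_breakend_vcf(somatic + extras, vcf_path, contigs)
    write_panel_bedpe(panel, bedpe_path)
    return {"vcf": vcf_path, "panel": bedpe_path, "junctions": somatic + extras, "panel_junctions": panel}


def simulate_depth_positions(
    region: tuple[str, int, int],
    cn_segments: Sequence[tuple[int, int, float]],
    mean_depth_per_window: float,
    config: SimulationConfig,
    salt: int = 307,
) -> tuple[np.ndarray, np.ndarray]:
    """Tumour and matched-normal read start positions over a region.

    ``cn_segments`` are (start0, end0, tumour_copy_ratio) covering the
    region; the normal is uniform.  Read counts scale with window copy
    ratio via Poisson sampling.
    """
    chrom, start, end = region
    rng = config.rng(salt=salt)
    n_windows = (end - start) // config.window_bp
    ref_positions = rng.integers(start, end, size=int(mean_depth_per_window * n_windows))
    tum = []
    for seg_start, seg_end, ratio in cn_segments:
        w = (seg_end - seg_start) / config.window_bp
        n = rng.poisson(mean_depth_per_window * w * ratio)
        tum.append(rng.integers(seg_start, seg_end, size=n))
    return np.sort(np.concatenate(tum)), np.sort(ref_positions)


# ---------------------------------------------------------------------------
# Rearrangement presets


@dataclass
class PresetCase:
    """One simulated rearrangement scenario with its planted truth."""

    name: str
    walk: list | None
    junctions: list
    rna_composition: dict
    expected_class: str | None
    cn_segments: list | None = None
    description: str = ""


def _j(jid, c1, p1, r1, c2, p2, r2, **kw) -> SvJunction:
    return SvJunction(id=jid, end_a=Breakend(c1, p1, r1), end_b=Breakend(c2, p2, r2), **kw)


def get_preset(name: str) -> PresetCase:
    """Named rearrangement scenarios used throughout the test-bench.

    ``mda175``: the double-fusion derivative — a 5'-gene/middle-gene
    deletion-type join, an inversion-type junction bringing in the
    inverted intron-15 fragment carrying the cryptic exon, a translocation
    into the 3' gene upstream of its exon 3, plus five passenger junctions
    so the gene carries 7 breakpoints in total.  ``simple_del``: in-frame
    deletion fusion from the immediately-5' gene.  ``dup_inv_insert``: a
    fusion from an unannotated partner exon plus the 57 kb tandem
    duplication with 24 kb inverted insertion.  ``inactivating``: a join
    retaining only the 5' end of the gene.  ``complex_multi``: multiple
    breakpoints, no orientation-consistent fusion, no RNA support.
    """
    if name == "mda175":
        walk = [
            ("chr11", 0, 6_000, "+"),
            ("chr11", 45_999, 86_000, "+"),
            ("chr11", 96_999, 99_000, "-"),
            ("chr8", 65_999, CHROM_LENGTHS["chr8"], "+"),
        ]
        junctions = [
            _j("D", "chr11", 6_000, LEFT, "chr11", 46_000, RIGHT),
            _j("E", "chr11", 86_000, LEFT, "chr11", 99_000, LEFT),
            _j("F", "chr11", 97_000, RIGHT, "chr8", 66_000, RIGHT),
            _j("A1", "chr8", 61_000, RIGHT, "chr11", 150_000, LEFT),
            _j("A2", "chr8", 61_200, LEFT, "chr11", 151_000, RIGHT),
            _j("B", "chr8", 61_400, RIGHT, "chr8", 63_000, LEFT),
            _j("C", "chr8", 61_600, LEFT, "chr11", 152_000, LEFT),
            _j("G", "chr8", 61_800, RIGHT, "chr11", 153_000, RIGHT),
        ]
        rna = {
            ("TENM4:12", "NRG1:3"): 122,
            ("TENM4:int15", "NRG1:3"): 38,
            ("TENM4:12", "TENM4:int15"): 10,
            ("PPP6R3:1", "TENM4:3"): 144,
            ("TENM4:2", "TENM4:3"): 1,
        }
        cn = [(60_000, 66_000, 1.0), (66_000, 90_000, 2.0)]
        return PresetCase(
            name=name,
            walk=walk,
            junctions=junctions,
            rna_composition=rna,
            expected_class="activating",
            cn_segments=cn,
            description="double fusion with cryptic inverted exon",
        )
    if name == "simple_del":
        walk = [("chr8", 0, 26_000, "+"), ("chr8", 66_999, CHROM_LENGTHS["chr8"], "+")]
        junctions = [_j("DEL1", "chr8", 26_000, LEFT, "chr8", 67_000, RIGHT)]
        rna = {("WRN:2", "NRG1:3"): 5}
        return PresetCase(
            name=name,
            walk=walk,
            junctions=junctions,
            rna_composition=rna,
            expected_class="activating",
            description="in-frame deletion fusion from the immediately-5' gene",
        )
    if name == "simple_del_oof":
        # out-of-frame variant: breakend in the partner's intron 3
        walk = [("chr8", 0, 30_000, "+"), ("chr8", 66_999, CHROM_LENGTHS["chr8"], "+")]
        junctions = [_j("DEL2", "chr8", 30_000, LEFT, "chr8", 67_000, RIGHT)]
        rna = {("WRN:3", "NRG1:3"): 2}
        return PresetCase(
            name=name,
            walk=walk,
            junctions=junctions,
            rna_composition=rna,
            expected_class="likely_inactivating",
            description="out-of-frame deletion fusion",
        )
    if name == "dup_inv_insert":
        junctions = [
            _j("ZF", "chr8", 8_000, LEFT, "chr8", 66_500, RIGHT),
            _j("ZD1", "chr8", 127_000, LEFT, "chr8", 159_000, LEFT),
            _j("ZD2", "chr8", 135_001, RIGHT, "chr8", 70_001, RIGHT),
        ]
        rna = {("NOVEL_ZNF704", "NRG1:3"): 2}
        return PresetCase(
            name=name,
            walk=None,
            junctions=junctions,
            rna_composition=rna,
            expected_class="indeterminate",
            description="fusion from unannotated partner exon; 57 kb dup with 24 kb inverted insert",
        )
    if name == "inactivating":
        junctions = [_j("IN1", "chr8", 100_500, LEFT, "chr11", 150_000, RIGHT)]
        return PresetCase(
            name=name,
            walk=None,
            junctions=junctions,
            rna_composition={},
            expected_class="likely_inactivating",
            description="join retaining only the 5' end of the 3' gene",
        )
    if name == "complex_multi":
        junctions = [
            _j("CM1", "chr8", 65_000, LEFT, "chr8", 101_000, LEFT),
            _j("CM2", "chr8", 72_000, RIGHT, "chr8", 110_000, RIGHT),
        ]
        return PresetCase(
            name=name,
            walk=None,
            junctions=junctions,
            rna_composition={},
            expected_class="indeterminate",
            description="multiple breakpoints, no consistent fusion, no RNA",
        )
    raise KeyError(f"unknown preset {name!r}")


PRESET_NAMES = ("mda175", "simple_del", "simple_del_oof", "dup_inv_insert", "inactivating", "complex_multi")


# ---------------------------------------------------------------------------
# Cohort emulation


@dataclass
class CohortCase:
    case_id: str
    in_dna_subset: bool
    junctions: list
    rna_composition: dict


def make_cohort(n_total: int = 571, n_dna_subset: int = 250) -> list[CohortCase]:
    """A breast-cancer-cohort-shaped case list.

    Four fusion-positive cases (two inside the DNA subset, two found by
    RNA search beyond it, with their DNA analysed individually): one
    in-frame deletion fusion, two out-of-frame fusions, one fusion from an
    unannotated partner exon with the duplication-with-inverted-insertion
    genomic motif.  Twenty further DNA-subset cases carry breakpoints in
    the gene without any fusion transcript, thirteen of them with
    multiple breakpoints.  All remaining cases are negative.
    """
    cases: list[CohortCase] = []
    cases.append(
        CohortCase("BC001", True, get_preset("simple_del_oof").junctions, {("WRN:3", "NRG1:3"): 2})
    )
    cases.append(
        CohortCase("BC002", True, get_preset("simple_del").junctions, {("WRN:2", "NRG1:3"): 6})
    )
    # 13 multi-breakpoint cases, 7 single-breakpoint cases
    multi, single = [], []
    for i in range(13):
        multi.append(
            CohortCase(
                f"BC{100 + i:03d}",
                True,
                [
                    _j(f"M{i}a", "chr8", 64_800 + 10 * i, LEFT, "chr11", 150_000 + 100 * i, RIGHT),
                    _j(f"M{i}b", "chr8", 71_800 + 10 * i, RIGHT, "chr8", 109_800 + 10 * i, RIGHT),
                ],
                {},
            )
        )
    for i in range(7):
        single.append(
            CohortCase(
                f"BC{200 + i:03d}",
                True,
                [_j(f"S{i}", "chr8", 65_500 + 10 * i, LEFT, "chr11", 155_000 + 100 * i, RIGHT)],
                {},
            )
        )
    cases.extend(multi)
    cases.extend(single)
    cases.append(
        CohortCase("BC301", False, [_j("AR1", "chr8", 30_010, LEFT, "chr8", 67_010, RIGHT)], {("WRN:3", "NRG1:3"): 1})
    )
    cases.append(CohortCase("BC302", False, get_preset("dup_inv_insert").junctions, {("NOVEL_ZNF704", "NRG1:3"): 2}))
    # negatives fill the remainder
    used = {c.case_id for c in cases}
    i = 0
    while len(cases) < n_total:
        cid = f"BCN{i:03d}"
        if cid not in used:
            in_dna = len([c for c in cases if c.in_dna_subset]) < n_dna_subset
            cases.append(CohortCase(cid, in_dna, [], {}))
        i += 1
    return cases
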