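"""Gene models, genome-order exon numbering and splice-boundary anchors.

The NRG1-style analysis works on a small set of genes of interest rather
than a full annotation.  Each gene is a list of exons numbered by *genome
order* (ascending genomic start, independent of which transcripts use an
exon), because fusion breakpoints are genomic events: the second exon of
most normal NRG1 transcripts is "exon 3" in this numbering.  Each exon
boundary exposes a splice *anchor*, the first (acceptor) or last (donor)
``k`` transcribed bases of the exon, read 5'->3' on the mRNA; these anchors
are what the raw-read text search looks for.

Coordinates are 0-based half-open internally.  All file I/O (GTF, YAML
overrides) and reports use the 1-based inclusive convention, so an interval
printed as ``start..end`` has length ``end - start + 1``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

#: exon role tags with defined meaning downstream
ROLE_TAGS = frozenset(
    {
        "transcription_start",
        "Ig_like",
        "EGF_like",
        "transmembrane",
        "cytoplasmic_tail",
        "beta3_extension",
        "cryptic",
    }
)


class AnnotationError(ValueError):
    """Raised for inconsistent gene annotation (e.g. overlapping exons)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (delegates to Bio.Seq)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeAssembly:
    """A toy genome: chromosome name -> uppercase A/C/G/T/N sequence."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"chromosome {name!r} has invalid bases {bad}")

    @classmethod
    def from_fasta(cls, path) -> "GenomeAssembly":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path) -> None:
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=n, description="") for n, s in self.sequences.items()]
        SeqIO.write(records, str(path), "fasta")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end]`` (0-based half-open)."""
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class Exon:
    """A genomic exon interval with coding phase and role tags.

    ``phase`` is the acceptor phase: the number of nucleotides of the
    codon split across the exon's acceptor boundary that are contributed
    by upstream exons (cumulative upstream CDS length mod 3).  ``None``
    for non-coding exons.  ``cds_len`` is the number of coding bases the
    exon itself contributes.
    """

    gene: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    number: int | None = None
    name: str | None = None
    phase: int | None = None
    cds_len: int = 0
    tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon {self.gene}:{self.name or self.number} has start >= end")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.phase is not None and self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0/1/2, got {self.phase}")
        if {"beta3_extension", "transmembrane"} <= set(self.tags):
            raise AnnotationError("an exon cannot be both beta3_extension and transmembrane")

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.name if self.name is not None else self.number}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome: GenomeAssembly) -> str:
        """Transcript-strand (5'->3' mRNA) sequence of the exon."""
        raw = genome.fetch(self.chrom, self.start, self.end)
        return raw if self.strand == "+" else revcomp(raw)


@dataclass(frozen=True)
class SpliceAnchor:
    """The first (acceptor) or last (donor) ``k`` transcribed bases of an exon."""

    exon: Exon
    side: str  # "acceptor" | "donor"
    k: int
    sequence: str
    ambiguous: bool = False  # contains N

    @property
    def label(self) -> str:
        return f"{self.exon.label}:{self.side}"


@dataclass(frozen=True)
class GeneModel:
    """A gene of interest: genome-order numbered exons plus isoform structure.

    ``alt_groups`` are mutually exclusive exon sets (e.g. the alpha/beta
    choice {10, 11}); ``tail_exons`` are the optional terminal exons
    (12-18 in the NRG1 case); ``beta3_extension`` is the genomic block
    appended to the last pre-tail exon when transcription terminates there
    (the beta3 isoforms); ``cryptic_exons`` are unannotated exons, possibly
    antisense within another gene's intron.
    """

    name: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    alt_groups: tuple[frozenset, ...] = ()
    tail_exons: frozenset = frozenset()
    beta3_extension: tuple[int, int] | None = None  # 0-based half-open
    cryptic_exons: tuple[Exon, ...] = ()

    def __post_init__(self) -> None:
        for grp in self.alt_groups:
            if len(grp) < 2:
                raise AnnotationError(f"{self.name}: alternative group {set(grp)} has < 2 members")
        for ce in self.cryptic_exons:
            if "cryptic" not in ce.tags:
                raise AnnotationError(f"{self.name}: cryptic exon {ce.label} lacks the cryptic tag")

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        end = max(e.end for e in self.exons)
        if self.beta3_extension:
            end = max(end, self.beta3_extension[1])
        return end

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def exon_by_number(self, number: int) -> Exon:
        for e in self.exons:
            if e.number == number:
                return e
        raise KeyError(f"{self.name} has no exon {number}")

    def exon_by_name(self, name: str) -> Exon:
        for e in self.all_exons():
            if (e.name or str(e.number)) == str(name):
                return e
        raise KeyError(f"{self.name} has no exon named {name!r}")

    def all_exons(self) -> tuple[Exon, ...]:
        return self.exons + self.cryptic_exons


def number_exons_by_genome_order(exons: Iterable[Exon]) -> dict[Exon, int]:
    """Assign exon numbers 1..n by ascending genomic start.

    Numbering follows coordinates, not transcript usage or strand, and is
    invariant to the input ordering of exons.  Overlapping exons are an
    annotation error (annotated alternatives such as 10/11 do not overlap;
    genuinely overlapping intervals indicate a malformed model).
    """
    ordered = sorted(exons, key=lambda e: (e.start, e.end))
    if not ordered:
        raise AnnotationError("gene has no exons")
    for a, b in itertools.pairwise(ordered):
        if b.start < a.end:
            raise AnnotationError(
                f"overlapping exons {a.label} ({a.start + 1}-{a.end}) and "
                f"{b.label} ({b.start + 1}-{b.end})"
            )
    return {e: i for i, e in enumerate(ordered, start=1)}


def renumber_gene(exons: Sequence[Exon]) -> tuple[Exon, ...]:
    """Return exons sorted and renumbered by genome order."""
    numbering = number_exons_by_genome_order(exons)
    out = []
    for exon, num in sorted(numbering.items(), key=lambda kv: kv[1]):
        name = exon.name if exon.name is not None else str(num)
        out.append(replace(exon, number=num, name=name))
    return tuple(out)


def extract_splice_anchor(
    genome: GenomeAssembly, exon: Exon, side: str, k: int = 20
) -> SpliceAnchor:
    """Extract the k-mer splice anchor at one boundary of an exon.

    The anchor reads 5'->3' on the transcript (coding) strand: the
    acceptor anchor is the first ``k`` transcribed bases of the exon, the
    donor anchor the last ``k``.  Anchors never pad into the intron, so
    ``k`` must not exceed the exon length.  Anchors containing N are
    flagged ambiguous with a warning.
    """
    if side not in ("acceptor", "donor"):
        raise ValueError(f"side must be acceptor or donor, got {side!r}")
    if k < 8:
        raise ValueError(f"anchor length k must be >= 8, got {k}")
    if k > exon.length:
        raise ValueError(
            f"anchor length {k} exceeds exon {exon.label} length {exon.length}"
        )
    if (side == "acceptor") == (exon.strand == "+"):
        raw = genome.fetch(exon.chrom, exon.start, exon.start + k)
    else:
        raw = genome.fetch(exon.chrom, exon.end - k, exon.end)
    seq = raw if exon.strand == "+" else revcomp(raw)
    ambiguous = "N" in seq
    if ambiguous:
        warnings.warn(f"anchor {exon.label}:{side} contains N; flagged ambiguous")
    return SpliceAnchor(exon=exon, side=side, k=k, sequence=seq, ambiguous=ambiguous)


def gene_splice_anchors(
    genome: GenomeAssembly, gene: GeneModel, k: int = 20
) -> list[SpliceAnchor]:
    """Acceptor and donor anchors for every exon of a gene, cryptic included."""
    anchors = []
    for exon in gene.all_exons():
        for side in ("acceptor", "donor"):
            anchors.append(extract_splice_anchor(genome, exon, side, k))
    return anchors


@dataclass(frozen=True)
class FusionIsoform:
    """One fusion transcript: ordered 5'->3' exon list plus terminal choice.

    ``beta3`` marks transcripts terminating in the extended last pre-tail
    exon (the beta3 terminus) instead of the transmembrane/tail exons.
    """

    exons: tuple[Exon, ...]
    beta3: bool = False

    @property
    def labels(self) -> tuple[str, ...]:
        labels = tuple(e.label for e in self.exons)
        if self.beta3:
            labels = labels + ("beta3_ext",)
        return labels

    def sort_key(self):
        exon_key = tuple(
            (e.gene, e.number if e.number is not None else 10**6, e.name or "")
            for e in self.exons
        )
        return (exon_key, int(self.beta3))


def enumerate_fusion_isoforms(
    five_prime_exons: Sequence[Exon],
    three_prime_gene: GeneModel,
    include_cryptic: bool = False,
    cryptic_exons: Sequence[Exon] | None = None,
) -> list[FusionIsoform]:
    """Enumerate fusion transcript isoforms by Cartesian expansion.

    The 3' gene contributes its constitutive fused exons (exons that are
    neither transcription-start exons, nor members of an alternative group,
    nor tail exons), one member per alternative group, and a terminal
    choice: either the beta3-extended terminus or the tail exons.  When
    ``include_cryptic`` is set, each optional cryptic exon (by default
    those of the genes supplying the 5' exons, plus the 3' gene's own) may
    be inserted at the fusion junction, doubling the isoform count per
    cryptic exon.  Output order is deterministic (lexicographic by exon
    numbering).
    """
    if not five_prime_exons:
        raise ValueError("five_prime_exons must be non-empty")
    gene = three_prime_gene
    alt_members = set().union(*gene.alt_groups) if gene.alt_groups else set()
    core = [
        e
        for e in gene.exons
        if "transcription_start" not in e.tags
        and e.number not in alt_members
        and e.number not in gene.tail_exons
    ]
    tail = [e for e in gene.exons if e.number in gene.tail_exons]
    if cryptic_exons is None and include_cryptic:
        # default to the 3' gene's own cryptic exons; cryptic exons hosted by
        # a 5' partner gene (the int15 situation) are passed in explicitly
        cryptic_exons = list(gene.cryptic_exons)
    cryptic_exons = list(cryptic_exons or [])

    alt_choices = [sorted(grp) for grp in gene.alt_groups] or [[None]]
    terminal_choices: list[tuple[str, list[Exon]]] = [("tail", tail)]
    if gene.beta3_extension is not None:
        terminal_choices = [("beta3", []), ("tail", tail)]
    cryptic_subsets = (
        [tuple(c) for r in range(len(cryptic_exons) + 1) for c in itertools.combinations(cryptic_exons, r)]
        if include_cryptic
        else [()]
    )

    isoforms = []
    for alt_combo in itertools.product(*alt_choices):
        alt_exs = [gene.exon_by_number(n) for n in alt_combo if n is not None]
        for term_kind, term_exs in terminal_choices:
            for cryptics in cryptic_subsets:
                body = sorted(core + alt_exs, key=lambda e: e.number)
                exons = tuple(five_prime_exons) + tuple(cryptics) + tuple(body) + tuple(term_exs)
                isoforms.append(FusionIsoform(exons=exons, beta3=(term_kind == "beta3")))
    isoforms.sort(key=lambda iso: iso.sort_key())
    return isoforms


# ---------------------------------------------------------------------------
# GTF + YAML model loading


def _phase_from_cumulative(cum: int) -> int:
    return cum % 3


def load_gene_models(
    gtf_path, overrides_path=None, genes: Iterable[str] | None = None
) -> dict[str, GeneModel]:
    """Load gene models from a GTF (exon/CDS features) plus a YAML side file.

    The GTF supplies exon intervals and coding regions; exons shared by
    several transcripts are collapsed on coordinates.  Acceptor phases are
    the cumulative CDS length upstream of each exon within the first
    transcript using it, mod 3.  The YAML overrides supply what GTF cannot
    express: alternative exon groups, tail-exon sets, the beta3 extension
    block, exon role tags, and unannotated cryptic exons (1-based inclusive
    coordinates).
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    ov: dict = {}
    if overrides_path is not None:
        with open(overrides_path) as fh:
            ov = yaml.safe_load(fh) or {}
    gene_ov = ov.get("genes", {})

    per_gene: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gname = feat.attributes.get("gene_name", feat.attributes.get("gene_id", [None]))[0]
        if gname is None:
            raise AnnotationError(f"feature at {feat.seqid}:{feat.start} lacks gene_name")
        if genes is not None and gname not in genes:
            continue
        tx = feat.attributes.get("transcript_id", ["?"])[0]
        g = per_gene.setdefault(
            gname, {"chrom": feat.seqid, "strand": feat.strand, "exons": {}, "cds": [], "tx_order": {}}
        )
        key = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            g["exons"][key] = True
            g["tx_order"].setdefault(tx, []).append(key)
        else:
            g["cds"].append(key)

    models: dict[str, GeneModel] = {}
    for gname, g in per_gene.items():
        tag_ov = {str(k): set(v) for k, v in gene_ov.get(gname, {}).get("tags", {}).items()}
        exon_list = [
            Exon(gene=gname, chrom=g["chrom"], start=s, end=e, strand=g["strand"])
            for (s, e) in sorted(g["exons"])
        ]
        exons = renumber_gene(exon_list)
        # per-exon CDS length: overlap of CDS features with each exon
        cds_intervals = sorted(set(g["cds"]))
        cds_by_exon: dict[int, int] = {}
        for exon in exons:
            length = 0
            for cs, ce in cds_intervals:
                length += max(0, min(ce, exon.end) - max(cs, exon.start))
            cds_by_exon[exon.number] = length
        # acceptor phase: cumulative CDS upstream within the first transcript
        # containing the exon, accumulated in transcript (5'->3') order.
        phase_by_exon: dict[int, int | None] = {n: None for n in cds_by_exon}
        for tx, keys in g["tx_order"].items():
            keys = sorted(keys, key=lambda k: k[0], reverse=(g["strand"] == "-"))
            cum = 0
            for s, e in keys:
                exon = next(x for x in exons if (x.start, x.end) == (s, e))
                if cds_by_exon[exon.number] > 0 and phase_by_exon[exon.number] is None:
                    phase_by_exon[exon.number] = _phase_from_cumulative(cum)
                cum += cds_by_exon[exon.number]
        exons = tuple(
            replace(
                e,
                cds_len=cds_by_exon[e.number],
                phase=phase_by_exon[e.number] if cds_by_exon[e.number] > 0 else None,
                tags=frozenset(tag_ov.get(str(e.number), set())),
            )
            for e in exons
        )
        gov = gene_ov.get(gname, {})
        alt_groups = tuple(frozenset(grp) for grp in gov.get("alt_groups", []))
        tail = frozenset(gov.get("tail_exons", []))
        b3 = gov.get("beta3_extension")
        beta3 = (b3["start"] - 1, b3["end"]) if b3 else None
        cryptics = []
        for ce in gov.get("cryptic_exons", []):
            cryptics.append(
                Exon(
                    gene=gname,
                    chrom=ce["chrom"],
                    start=ce["start"] - 1,
                    end=ce["end"],
                    strand=ce["strand"],
                    name=ce["name"],
                    cds_len=ce.get("cds_len", 0),
                    tags=frozenset(set(ce.get("tags", [])) | {"cryptic"}),
                )
            )
        models[gname] = GeneModel(
            name=gname,
            chrom=g["chrom"],
            strand=g["strand"],
            exons=exons,
            alt_groups=alt_groups,
            tail_exons=tail,
            beta3_extension=beta3,
            cryptic_exons=tuple(cryptics),
        )
    return models
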