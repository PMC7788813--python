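"""Breakend structural variants: parsing, somatic filtering, fusion candidates.

A rearrangement junction is an oriented adjacency between two genomic
breakends, each retaining the sequence on one side of its position (the
Fig-2-style convention: '-' after a coordinate means sequence to the right
of the junction is retained).  Junctions arrive as VCF 4.2 BND mate pairs;
each pair is collapsed into a single :class:`SvJunction`.

Somatic filtering mirrors the study design for tumour/normal pairs: drop
any junction with supporting reads in the matched normal, any junction
seen in a panel of normals, and any junction touching mitochondrial or
unassembled contigs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pysam

from .gene_models import GeneModel

LEFT = "left"  # sequence left of (and including) pos is retained
RIGHT = "right"  # sequence right of (and including) pos is retained

_BND_RE = re.compile(
    r"^(?P<head>[ACGTNacgtn]+)?(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<b2>[\[\]])(?P<tail>[ACGTNacgtn]+)?$"
)

#: contig-name patterns excluded from somatic analysis by default
_EXCLUDED_CONTIG_RE = re.compile(r"^(chrM|MT|chrMT)$|Un|random|^GL\d|^KI\d|^hs37d5|decoy", re.I)


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 1-based
    retained: str  # LEFT | RIGHT

    def __post_init__(self):
        if self.retained not in (LEFT, RIGHT):
            raise ValueError(f"retained must be left/right, got {self.retained!r}")
        if self.pos < 1:
            raise ValueError("breakend position must be >= 1")


@dataclass(frozen=True)
class SvJunction:
    """An oriented genomic adjacency with tumour/normal support evidence."""

    id: str
    end_a: Breakend
    end_b: Breakend
    tumour_support: int = 0
    normal_support: int = 0
    inserted_sequence: str = ""

    def __post_init__(self):
        if self.tumour_support < 0 or self.normal_support < 0:
            raise ValueError("support counts must be >= 0")

    @property
    def chroms(self) -> tuple[str, str]:
        return (self.end_a.chrom, self.end_b.chrom)

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.end_a, self.end_b)

    def canonical(self) -> "SvJunction":
        """Breakends in deterministic order, for comparisons."""
        a, b = self.end_a, self.end_b
        if (b.chrom, b.pos, b.retained) < (a.chrom, a.pos, a.retained):
            return replace(self, end_a=b, end_b=a)
        return self

    def same_adjacency(self, other: "SvJunction", tol: int = 0) -> bool:
        """True if both junctions describe the same oriented adjacency
        within ``tol`` bp at both ends."""
        for sa, sb in ((self.end_a, self.end_b), (self.end_b, self.end_a)):
            oa, ob = other.end_a, other.end_b
            if (
                sa.chrom == oa.chrom
                and sb.chrom == ob.chrom
                and sa.retained == oa.retained
                and sb.retained == ob.retained
                and abs(sa.pos - oa.pos) <= tol
                and abs(sb.pos - ob.pos) <= tol
            ):
                return True
        return False


class VcfBreakendError(ValueError):
    """Malformed or unpaired BND records."""


def decode_bnd_alt(alt: str) -> tuple[str, int, str, str, str]:
    """Decode a VCF 4.2 bracketed BND ALT.

    Returns (mate_chrom, mate_pos, local_retained, mate_retained,
    inserted_sequence).  With the replacement string ``t`` before the
    bracket the local breakend retains its left side; ``t`` after the
    bracket retains the right.  ``[`` brackets mean the mate retains its
    right side, ``]`` its left.
    """
    m = _BND_RE.match(alt)
    if not m or m.group("b1") != m.group("b2"):
        raise VcfBreakendError(f"cannot decode BND ALT {alt!r}")
    head, tail = m.group("head"), m.group("tail")
    if (head is None) == (tail is None):
        raise VcfBreakendError(f"BND ALT {alt!r} must have bases on exactly one side")
    local_retained = LEFT if head else RIGHT
    mate_retained = RIGHT if m.group("b1") == "[" else LEFT
    t = head if head else tail
    # first (or last) base is the REF base; the rest is inserted sequence
    ins = t[1:] if head else t[:-1]
    return m.group("chrom"), int(m.group("pos")), local_retained, mate_retained, ins.upper()


def encode_bnd_alt(ref: str, local_retained: str, mate: Breakend, ins: str = "") -> str:
    """Inverse of :func:`decode_bnd_alt` for one record of a mate pair."""
    bracket = "[" if mate.retained == RIGHT else "]"
    core = f"{bracket}{mate.chrom}:{mate.pos}{bracket}"
    if local_retained == LEFT:
        return f"{ref}{ins}{core}"
    return f"{core}{ins}{ref}"


def _sample_support(record, sample_names) -> dict[str, int]:
    """SR split-read support per sample; absent fields count as 0."""
    out = {}
    for name in sample_names:
        try:
            val = record.samples[name].get("SR", 0)
        except KeyError:
            val = 0
        if isinstance(val, tuple):
            val = val[-1] if val else 0
        out[name] = int(val or 0)
    return out


def parse_breakend_vcf(path) -> list[SvJunction]:
    """Parse BND records from a (tumour/normal paired) VCF into junctions.

    Mate pairs linked by MATEID are collapsed to one junction each, keyed
    on the lexically first record ID.  Non-BND records are skipped (their
    count is recorded on the returned list as ``.n_skipped`` is not — they
    are simply ignored); an unpaired mate is an error naming the record.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    normal = next((s for s in samples if s.upper().startswith("NORM")), samples[0] if samples else None)
    tumour = next(
        (s for s in samples if s.upper().startswith(("TUM", "TUMOR"))),
        samples[-1] if samples else None,
    )
    records = {}
    for rec in vf:
        try:
            svtype = rec.info.get("SVTYPE")
        except ValueError:  # record with no usable INFO definitions
            continue
        if svtype != "BND":
            continue
        if rec.id is None:
            raise VcfBreakendError(f"BND record at {rec.chrom}:{rec.pos} has no ID")
        records[rec.id] = rec
    junctions = []
    seen = set()
    for rid, rec in records.items():
        if rid in seen:
            continue
        mateid = rec.info.get("MATEID")
        if isinstance(mateid, tuple):
            mateid = mateid[0]
        if mateid is None or mateid not in records:
            raise VcfBreakendError(f"BND record {rid} has missing mate {mateid!r}")
        mate = records[mateid]
        seen.update({rid, mateid})
        first = rec if rid <= mateid else mate
        alt = first.alts[0]
        mate_chrom, mate_pos, local_ret, mate_ret, ins = decode_bnd_alt(alt)
        support = _sample_support(first, [s for s in (normal, tumour) if s])
        junction_id = first.id.rsplit("_", 1)[0] if first.id.endswith(("_1", "_2")) else first.id
        junctions.append(
            SvJunction(
                id=junction_id,
                end_a=Breakend(first.chrom, first.pos, local_ret),
                end_b=Breakend(mate_chrom, mate_pos, mate_ret),
                tumour_support=support.get(tumour, 0) if tumour else 0,
                normal_support=support.get(normal, 0) if normal else 0,
                inserted_sequence=ins,
            )
        )
    junctions.sort(key=lambda j: j.id)
    return junctions


def write_breakend_vcf(junctions: Sequence[SvJunction], path, contigs: dict) -> None:
    """Write junctions as paired BND records (NORMAL + TUMOUR SR counts).

    Plain VCF 4.2 text; REF bases are N (the toy workflows carry the
    genome separately).  Round-trips through :func:`parse_breakend_vcf`.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
        '##FORMAT=<ID=SR,Number=1,Type=Integer,Description="Split-read support">',
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOUR")
    for j in junctions:
        jc = j.canonical()
        for tag, this, other in (("_1", jc.end_a, jc.end_b), ("_2", jc.end_b, jc.end_a)):
            ins = jc.inserted_sequence if tag == "_1" else ""
            alt = encode_bnd_alt("N", this.retained, other, ins)
            mate = jc.id + ("_2" if tag == "_1" else "_1")
            lines.append(
                "\t".join(
                    [
                        this.chrom,
                        str(this.pos),
                        jc.id + tag,
                        "N",
                        alt,
                        ".",
                        "PASS",
                        f"SVTYPE=BND;MATEID={mate}",
                        "SR",
                        str(jc.normal_support),
                        str(jc.tumour_support),
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Somatic filtering


def default_contig_allowed(chrom: str) -> bool:
    return not _EXCLUDED_CONTIG_RE.search(chrom)


def filter_somatic(
    junctions: Sequence[SvJunction],
    panel: Sequence[SvJunction] = (),
    allowed_chroms: Iterable[str] | None = None,
    panel_tolerance: int = 10,
) -> list[SvJunction]:
    """Apply the somatic filters; order-preserving and idempotent.

    Drops junctions with any matched-normal support, junctions matching a
    panel-of-normals junction (same orientation, both ends within
    ``panel_tolerance`` bp), and junctions with either breakend on a
    disallowed contig (mitochondrial/unassembled by default).
    """
    if allowed_chroms is not None:
        allowed = set(allowed_chroms)
        chrom_ok = lambda c: c in allowed  # noqa: E731
    else:
        chrom_ok = default_contig_allowed
    out = []
    for j in junctions:
        if j.normal_support >= 1:
            continue
        if not all(chrom_ok(c) for c in j.chroms):
            continue
        if any(j.same_adjacency(p, tol=panel_tolerance) for p in panel):
            continue
        out.append(j)
    return out


def load_panel_bedpe(path) -> list[SvJunction]:
    """Panel of normals as BEDPE; strand '+' encodes left-retained, '-' right.

    Positions use the BEDPE convention (0-based start, end exclusive); the
    breakend coordinate is taken as ``end`` (== start+1 for point
    breakends), i.e. the 1-based position.
    """
    panel = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom1, start1, end1, chrom2, start2, end2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
            name = f[6] if len(f) > 6 else f"panel{i}"
            strand1 = f[8] if len(f) > 8 else "+"
            strand2 = f[9] if len(f) > 9 else "+"
            panel.append(
                SvJunction(
                    id=name,
                    end_a=Breakend(chrom1, end1, LEFT if strand1 == "+" else RIGHT),
                    end_b=Breakend(chrom2, end2, LEFT if strand2 == "+" else RIGHT),
                )
            )
    return panel


def write_panel_bedpe(panel: Sequence[SvJunction], path) -> None:
    with open(path, "w") as fh:
        for j in panel:
            a, b = j.end_a, j.end_b
            fh.write(
                "\t".join(
                    [
                        a.chrom,
                        str(a.pos - 1),
                        str(a.pos),
                        b.chrom,
                        str(b.pos - 1),
                        str(b.pos),
                        j.id,
                        ".",
                        "+" if a.retained == LEFT else "-",
                        "+" if b.retained == LEFT else "-",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Breakpoints within a gene, fusion candidates


@dataclass
class CaseRearrangementRecord:
    """Per-case record of rearrangement evidence at the gene of interest."""

    case_id: str
    junctions: list  # junctions with >=1 breakend in the gene span
    n_breakpoints: int
    multi_breakpoint: bool
    candidates: list = None  # FusionCandidate list (filled by the caller)
    fusion_calls: list = None  # integrated FusionCall list
    activation_class: str | None = None

    def __post_init__(self):
        if self.candidates is None:
            self.candidates = []
        if self.fusion_calls is None:
            self.fusion_calls = []


def breakpoints_in_gene(
    junctions: Sequence[SvJunction],
    gene: GeneModel,
    flank_bp: int = 0,
    case_id: str = "case",
) -> CaseRearrangementRecord:
    """Count junction breakends within the gene span (+- flank)."""
    lo = gene.start + 1 - flank_bp  # to 1-based
    hi = gene.end + flank_bp
    in_gene = []
    n = 0
    for j in junctions:
        k = sum(
            1 for be in j.breakends if be.chrom == gene.chrom and lo <= be.pos <= hi
        )
        if k:
            in_gene.append(j)
            n += k
    return CaseRearrangementRecord(
        case_id=case_id,
        junctions=in_gene,
        n_breakpoints=n,
        multi_breakpoint=n >= 2,
    )


@dataclass(frozen=True)
class FusionCandidate:
    """A DNA-predicted fusion: orientation-consistent join into the 3' gene.

    ``last_partner_exon`` is the highest-numbered 5'-partner exon upstream
    of the breakend on the partner's coding strand; ``spliced_in_exon`` the
    first acceptor exon of the 3' gene downstream of the other breakend.
    ``five_prime_end_only`` marks joins that retain only the 5' part of
    the 3' gene (breakend inside the gene, downstream of the receptor-
    binding exon, reading away from the remaining exons).
    """

    junction_id: str
    five_prime_gene: str | None
    three_prime_gene: str
    last_partner_exon: int | None
    spliced_in_exon: int | None
    five_prime_end_only: bool = False
    note: str = ""


def _promoter_side_retained(gene: GeneModel, be: Breakend) -> bool:
    """True if the retained side of a breakend inside ``gene`` covers the
    gene's promoter-proximal exons on its coding strand."""
    return be.retained == (LEFT if gene.strand == "+" else RIGHT)


def _acceptor_exons(gene: GeneModel):
    return [
        e
        for e in gene.exons
        if e.number is not None and e.number > 1 and "transcription_start" not in e.tags
    ]


def _first_acceptor_downstream(gene: GeneModel, be: Breakend) -> int | None:
    """Lowest-numbered acceptor exon of ``gene`` strictly downstream of the
    breakend in the direction the retained side reads."""
    if gene.strand == "+":
        if be.retained != RIGHT:
            return None
        cands = [e.number for e in _acceptor_exons(gene) if e.start + 1 > be.pos]
    else:
        if be.retained != LEFT:
            return None
        cands = [e.number for e in _acceptor_exons(gene) if e.end < be.pos]
    return min(cands) if cands else None


def predict_fusion_from_junction(
    junction: SvJunction,
    five_prime_candidates: Sequence[GeneModel],
    three_prime_gene: GeneModel,
    flank_bp: int = 0,
) -> FusionCandidate | None:
    """Propose an orientation-consistent genomic fusion, or None.

    A candidate needs one breakend inside a 5'-partner gene with the
    retained side covering that gene's promoter-proximal exons, and the
    other breakend upstream of a 3'-gene acceptor exon with the retained
    side reading into it, both on the genes' coding strands.  A breakend
    inside the 3' gene downstream of the receptor-binding exon that
    retains only the gene's 5' part is emitted flagged five_prime_end_only
    for interpretation downstream.
    """
    g3 = three_prime_gene
    egf = [e for e in g3.exons if "EGF_like" in e.tags]
    egf_end = max((e.end for e in egf), default=None)
    egf_start = min((e.start for e in egf), default=None)

    for be5, be3 in ((junction.end_a, junction.end_b), (junction.end_b, junction.end_a)):
        # sense-sense fusion: partner promoter side + 3' acceptor side
        if be3.chrom == g3.chrom and (g3.start + 1 - flank_bp) <= be3.pos <= (g3.end + flank_bp):
            spliced_in = _first_acceptor_downstream(g3, be3)
            if spliced_in is not None:
                for g5 in five_prime_candidates:
                    if g5.name == g3.name:
                        continue
                    lo, hi = g5.start + 1 - flank_bp, g5.end + flank_bp
                    if be5.chrom == g5.chrom and lo <= be5.pos <= hi and _promoter_side_retained(g5, be5):
                        if g5.strand == "+":
                            last = max(
                                (e.number for e in g5.exons if e.end <= be5.pos),
                                default=None,
                            )
                        else:
                            last = max(
                                (e.number for e in g5.exons if e.start + 1 >= be5.pos),
                                default=None,
                            )
                        return FusionCandidate(
                            junction_id=junction.id,
                            five_prime_gene=g5.name,
                            three_prime_gene=g3.name,
                            last_partner_exon=last,
                            spliced_in_exon=spliced_in,
                        )
        # 5'-end-only: breakend in the 3' gene past the receptor-binding exon,
        # retaining only the gene's 5' part
        if (
            egf_end is not None
            and be5.chrom == g3.chrom
            and g3.start + 1 <= be5.pos <= g3.end
        ):
            past_egf = be5.pos > egf_end if g3.strand == "+" else be5.pos <= egf_start
            keeps_5p = be5.retained == (LEFT if g3.strand == "+" else RIGHT)
            if past_egf and keeps_5p:
                return FusionCandidate(
                    junction_id=junction.id,
                    five_prime_gene=None,
                    three_prime_gene=g3.name,
                    last_partner_exon=None,
                    spliced_in_exon=None,
                    five_prime_end_only=True,
                    note="retains only the 5' part of the 3' gene",
                )
    return None
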