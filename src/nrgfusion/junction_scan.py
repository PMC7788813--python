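"""Raw-read splice-anchor scanning: the FASTQ text-search fusion detector.

The detector never aligns reads.  It indexes the splice acceptor and donor
anchor k-mers of the genes of interest (and their reverse complements) and
scans every read for exact occurrences.  Wherever an anchor occurs, the
sequence adjacent on the partner side of the junction — 5' of an acceptor
anchor, 3' of a donor anchor — is extracted and classified against the
complementary-side anchors of all modelled exons, cryptic exons included.
A flank matching no modelled exon is reported verbatim as novel; this is
what allows fusions from undocumented partner exons to be found at all.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .gene_models import GeneModel, GenomeAssembly, SpliceAnchor, gene_splice_anchors, revcomp

DONOR_KINDS = ("known", "cryptic", "novel", "too_short")


class AnchorCollisionError(ValueError):
    """Two distinct exon boundaries share an anchor k-mer at the chosen k."""


@dataclass(frozen=True)
class AnchorIndex:
    """Exact-match index over anchor k-mers and their reverse complements."""

    k: int
    kmers: dict  # kmer -> SpliceAnchor (transcript-strand anchors only)
    anchors: tuple[SpliceAnchor, ...]

    def acceptor_anchors(self) -> list[SpliceAnchor]:
        return [a for a in self.anchors if a.side == "acceptor"]

    def donor_anchors(self) -> list[SpliceAnchor]:
        return [a for a in self.anchors if a.side == "donor"]


def build_anchor_index(
    genes: Sequence[GeneModel], genome: GenomeAssembly, k: int = 20
) -> AnchorIndex:
    """Index every exon-boundary anchor of the given genes.

    Raises :class:`AnchorCollisionError` listing all collisions if two
    boundaries share a k-mer (in either orientation); the caller raises k.
    """
    anchors = []
    for gene in genes:
        anchors.extend(gene_splice_anchors(genome, gene, k))
    kmers: dict[str, SpliceAnchor] = {}
    collisions = []
    for anchor in anchors:
        for seq in {anchor.sequence, revcomp(anchor.sequence)}:
            prior = kmers.get(seq)
            if prior is not None and (prior.exon.label, prior.side) != (anchor.exon.label, anchor.side):
                collisions.append((prior.label, anchor.label, seq))
            elif prior is None:
                kmers[seq] = anchor
    # forward orientation wins in the dict; rebuild with forward sequences so
    # strand can be inferred at scan time
    if collisions:
        listing = "; ".join(f"{a} ~ {b} ({s})" for a, b, s in collisions)
        raise AnchorCollisionError(f"anchor collisions at k={k}: {listing}")
    return AnchorIndex(k=k, kmers={a.sequence: a for a in anchors}, anchors=tuple(anchors))


@dataclass(frozen=True)
class SplitReadHit:
    """An anchor occurrence in a read, with the partner-side flank.

    ``read_strand`` records whether the anchor was found in the read as
    sequenced ("as-is") or in its reverse complement ("revcomp"); the
    flank is always reported 5'->3' on the transcript strand.
    """

    read_id: str
    anchor: SpliceAnchor
    read_strand: str  # "as-is" | "revcomp"
    offset: int  # anchor start within the (strand-normalised) read
    flank_sequence: str
    read_sequence: str  # strand-normalised read

    @property
    def flank_length(self) -> int:
        return len(self.flank_sequence)


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path):
    """Yield (read_id, sequence) from plain or gzipped FASTQ, with record
    index attached to any parse error."""
    idx = 0
    with _open_maybe_gz(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq).upper()
                idx += 1
        except ValueError as err:
            raise ValueError(f"malformed FASTQ record at index {idx}: {err}") from err


def _expand_one_mismatch(kmers: dict) -> dict:
    """Neighbourhood-expanded index allowing one mismatch; ambiguous
    neighbours (reachable from two different anchors) are dropped."""
    expanded: dict[str, object] = {}
    ambiguous = set()
    for kmer, anchor in kmers.items():
        for i, base in enumerate(kmer):
            for alt in "ACGT":
                if alt == base:
                    continue
                neigh = kmer[:i] + alt + kmer[i + 1 :]
                prior = expanded.get(neigh)
                if prior is not None and prior is not anchor:
                    ambiguous.add(neigh)
                expanded[neigh] = anchor
    for kmer in ambiguous:
        expanded.pop(kmer, None)
    expanded.update(kmers)  # exact matches always win
    return expanded


def scan_reads(
    fastq_path,
    index: AnchorIndex,
    max_mismatches: int = 0,
    min_flank: int = 12,
) -> list[SplitReadHit]:
    """Scan a FASTQ file for anchor occurrences in both orientations.

    Anchors are matched anywhere within the read (junction position in a
    read is arbitrary); each occurrence yields one hit with whatever lies
    adjacent in the read as the flank.  Reads are scanned independently and
    output order is deterministic: file order, then offset.  ``min_flank``
    is not applied here — classification decides what is too short.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    lookup = index.kmers if max_mismatches == 0 else _expand_one_mismatch(index.kmers)
    k = index.k
    hits: list[SplitReadHit] = []
    for read_id, seq in iter_fastq(fastq_path):
        for strand, oriented in (("as-is", seq), ("revcomp", revcomp(seq))):
            if len(oriented) < k:
                continue
            for off in range(len(oriented) - k + 1):
                anchor = lookup.get(oriented[off : off + k])
                if anchor is None:
                    continue
                if anchor.side == "acceptor":
                    flank = oriented[:off]
                else:
                    flank = oriented[off + k :]
                hits.append(
                    SplitReadHit(
                        read_id=read_id,
                        anchor=anchor,
                        read_strand=strand,
                        offset=off,
                        flank_sequence=flank,
                        read_sequence=oriented,
                    )
                )
    return hits


@dataclass(frozen=True)
class JunctionCall:
    """One read's evidence for a splice junction: acceptor and donor labels.

    The *_kind fields classify each label: known/cryptic for a modelled
    exon, novel for an unmatched flank (literal sequence kept in the
    label), too_short for a flank below the classification threshold.
    """

    read_id: str
    acceptor: str
    donor: str
    acceptor_kind: str
    donor_kind: str
    anchored_side: str  # which side carried the matched anchor
    read_sequence: str


def _classify_partner(flank: str, candidates, suffix: bool, min_flank: int):
    if len(flank) < min_flank:
        return f"short({flank})", "too_short"
    matches = []
    for a in candidates:
        n = min(len(flank), a.k)
        if suffix:
            ok = flank.endswith(a.sequence[-n:])
        else:
            ok = flank.startswith(a.sequence[:n])
        if ok:
            matches.append(a)
    if len(matches) == 1:
        partner = matches[0]
        kind = "cryptic" if "cryptic" in partner.exon.tags else "known"
        return partner.exon.label, kind
    return f"novel({flank})", "novel"


def classify_flank(
    hit: SplitReadHit, index: AnchorIndex, min_flank: int = 12
) -> JunctionCall:
    """Classify the partner side of a hit against complementary-side anchors.

    For an acceptor-anchor hit the flank must end with a donor anchor (the
    anchor's suffix, when the flank is shorter than k); for a donor-anchor
    hit the flank must begin with an acceptor anchor.  A flank matching no
    modelled exon is novel, with the literal flank retained for reporting;
    flanks below ``min_flank`` are too_short and excluded from fraction
    denominators downstream.
    """
    anchor = hit.anchor
    own_kind = "cryptic" if "cryptic" in anchor.exon.tags else "known"
    if anchor.side == "acceptor":
        donor, donor_kind = _classify_partner(
            hit.flank_sequence, index.donor_anchors(), suffix=True, min_flank=min_flank
        )
        acceptor, acceptor_kind = anchor.exon.label, own_kind
    else:
        acceptor, acceptor_kind = _classify_partner(
            hit.flank_sequence, index.acceptor_anchors(), suffix=False, min_flank=min_flank
        )
        donor, donor_kind = anchor.exon.label, own_kind
    return JunctionCall(
        read_id=hit.read_id,
        acceptor=acceptor,
        donor=donor,
        acceptor_kind=acceptor_kind,
        donor_kind=donor_kind,
        anchored_side=anchor.side,
        read_sequence=hit.read_sequence,
    )


def call_junctions(
    hits: Iterable[SplitReadHit], index: AnchorIndex, min_flank: int = 12
) -> list[JunctionCall]:
    """Classify hits and collapse the two-sided evidence of each read.

    A read spanning a junction between two indexed exons carries both the
    donor anchor and the acceptor anchor; both hits describe the same
    junction, so calls are deduplicated per (read, acceptor, donor).  A
    read's too_short call is dropped when the same read yielded a fully
    classified call anchored on the same exon.
    """
    best: dict[tuple[str, str, str], JunctionCall] = {}
    order: list[tuple[str, str, str]] = []
    for hit in hits:
        call = classify_flank(hit, index, min_flank=min_flank)
        key = (call.read_id, call.acceptor, call.donor)
        if key not in best:
            best[key] = call
            order.append(key)
    def anchored_label(c: JunctionCall) -> str:
        return c.acceptor if c.anchored_side == "acceptor" else c.donor
    definite = {
        (c.read_id, anchored_label(c))
        for c in best.values()
        if "too_short" not in (c.acceptor_kind, c.donor_kind)
    }
    out = []
    for key in order:
        call = best[key]
        if "too_short" in (call.acceptor_kind, call.donor_kind) and (
            call.read_id,
            anchored_label(call),
        ) in definite:
            continue
        out.append(call)
    return out


def round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def summarise_junctions(calls: Sequence[JunctionCall], dedup: bool = False) -> pd.DataFrame:
    """Per-acceptor table of donor read counts and integer percentages.

    With ``dedup`` on, identical (strand-normalised) read sequences are
    collapsed before counting — the duplicate-removal convention used for
    cell-line libraries; cohort RNA is summarised with duplicates kept.
    Percentages are per acceptor over classifiable (non-too_short) calls,
    rounded half away from zero.
    """
    usable = [
        c
        for c in calls
        if c.acceptor_kind in ("known", "cryptic") and c.donor_kind != "too_short"
    ]
    if dedup:
        seen = set()
        kept = []
        for c in usable:
            sig = (c.acceptor, c.donor, min(c.read_sequence, revcomp(c.read_sequence)))
            if sig in seen:
                continue
            seen.add(sig)
            kept.append(c)
        usable = kept
    counts = Counter((c.acceptor, c.donor, c.donor_kind) for c in usable)
    rows = []
    totals = Counter()
    for (acceptor, donor, kind), n in counts.items():
        totals[acceptor] += n
    for (acceptor, donor, kind), n in sorted(counts.items()):
        rows.append(
            {
                "acceptor": acceptor,
                "donor": donor,
                "donor_kind": kind,
                "count": n,
                "total_at_acceptor": totals[acceptor],
                "percent": round_half_away(100.0 * n / totals[acceptor]),
            }
        )
    return pd.DataFrame(
        rows, columns=["acceptor", "donor", "donor_kind", "count", "total_at_acceptor", "percent"]
    )
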