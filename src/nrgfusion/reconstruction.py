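"""Derivative-chromosome reconstruction from rearrangement junctions.

Breakpoints partition each chromosome into maximal segments; each
junction induces one oriented adjacency between two segment extremities
(a breakend retaining its left side joins through the right end of the
segment ending there, and vice versa).  A derivative chromosome is a walk
over segments — each usable in either orientation — alternating segment
traversals with reference or variant adjacencies.  Walks are enumerated
exhaustively up to a length cap and deduplicated up to reverse
complement; the reconstruction reports all walks consistent with the
junctions rather than asserting one, and a walk "explains" an observed
fusion transcript when the transcript's exons occur along it intact, in
transcription order and in a consistent orientation.

The module also recognises the tandem-duplication-with-inverted-insertion
junction motif: a duplicated span whose internal junction is interrupted
by an inverted fragment leaves two inversion-type junctions (one
left/left, one right/right) whose coordinates give both spans directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .gene_models import Exon, GeneModel
from .sv_integration import LEFT, RIGHT, Breakend, SvJunction

L, R = "L", "R"  # segment ends


@dataclass(frozen=True)
class Segment:
    id: int
    chrom: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Adjacency:
    a: tuple[int, str]  # (segment id, end)
    b: tuple[int, str]
    junction_id: str
    kind: str  # "variant" | "reference"


@dataclass
class SegmentGraph:
    segments: tuple[Segment, ...]
    adjacencies: tuple[Adjacency, ...]
    breakpoints: dict  # chrom -> sorted boundary positions (0-based cut indices)

    def segment_at(self, chrom: str, pos0: int) -> Segment:
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos0 < seg.end:
                return seg
        raise KeyError(f"no segment at {chrom}:{pos0}")

    def neighbours(self, seg_id: int, end: str) -> list[tuple[Adjacency, tuple[int, str]]]:
        out = []
        for adj in self.adjacencies:
            if adj.a == (seg_id, end):
                out.append((adj, adj.b))
            if adj.b == (seg_id, end):
                out.append((adj, adj.a))
        return out


def _boundary(be: Breakend) -> int:
    """The 0-based cut index of a breakend: retained-left cuts after pos,
    retained-right cuts before pos."""
    return be.pos if be.retained == LEFT else be.pos - 1


def build_segment_graph(
    junctions: Sequence[SvJunction], chrom_extents: Mapping[str, int]
) -> SegmentGraph:
    """Segments and adjacencies induced by a filtered junction set.

    Per chromosome, segment count equals distinct breakpoint count + 1.
    Every junction contributes exactly one variant adjacency; consecutive
    segments of a chromosome are linked by reference adjacencies.
    """
    cuts: dict[str, set] = {c: set() for c in chrom_extents}
    for j in junctions:
        for be in j.breakends:
            if be.chrom not in chrom_extents:
                raise ValueError(f"junction {j.id} on unknown chromosome {be.chrom}")
            cut = _boundary(be)
            if not (0 <= cut <= chrom_extents[be.chrom]):
                raise ValueError(
                    f"junction {j.id} breakend {be.chrom}:{be.pos} outside chromosome extent"
                )
            cuts[be.chrom].add(cut)

    segments: list[Segment] = []
    seg_lookup: dict[tuple[str, int], Segment] = {}  # (chrom, start) -> segment
    ref_adjacencies: list[Adjacency] = []
    breakpoints = {}
    for chrom, length in chrom_extents.items():
        bounds = [0] + sorted(b for b in cuts[chrom] if 0 < b < length) + [length]
        breakpoints[chrom] = [b for b in bounds[1:-1]]
        prev = None
        for s, e in zip(bounds[:-1], bounds[1:]):
            seg = Segment(id=len(segments), chrom=chrom, start=s, end=e)
            segments.append(seg)
            seg_lookup[(chrom, s)] = seg
            if prev is not None:
                ref_adjacencies.append(
                    Adjacency(a=(prev.id, R), b=(seg.id, L), junction_id="", kind="reference")
                )
            prev = seg

    def end_of(be: Breakend) -> tuple[int, str]:
        cut = _boundary(be)
        if be.retained == LEFT:
            # segment ending at the cut
            for seg in segments:
                if seg.chrom == be.chrom and seg.end == cut:
                    return (seg.id, R)
        else:
            for seg in segments:
                if seg.chrom == be.chrom and seg.start == cut:
                    return (seg.id, L)
        raise ValueError(f"no segment extremity for breakend {be.chrom}:{be.pos}")

    var_adjacencies = [
        Adjacency(a=end_of(j.end_a), b=end_of(j.end_b), junction_id=j.id, kind="variant")
        for j in junctions
    ]
    return SegmentGraph(
        segments=tuple(segments),
        adjacencies=tuple(var_adjacencies + ref_adjacencies),
        breakpoints=breakpoints,
    )


@dataclass(frozen=True)
class DerivativeModel:
    """An ordered walk of oriented segments with implied multiplicities."""

    walk: tuple[tuple[int, str], ...]  # (segment id, "+"|"-")
    truncated: bool = False

    def multiplicities(self) -> Counter:
        return Counter(seg for seg, _ in self.walk)

    def reversed_model(self) -> "DerivativeModel":
        flipped = tuple((seg, "-" if o == "+" else "+") for seg, o in reversed(self.walk))
        return DerivativeModel(walk=flipped, truncated=self.truncated)

    def canonical(self) -> tuple:
        rev = self.reversed_model().walk
        return min(self.walk, rev)


def _exit_end(orient: str) -> str:
    return R if orient == "+" else L


def _entry_orient(end: str) -> str:
    return "+" if end == L else "-"


def enumerate_walks(
    graph: SegmentGraph,
    start_segment: int | None = None,
    end_segment: int | None = None,
    max_length: int = 12,
) -> list[DerivativeModel]:
    """Depth-first enumeration of walks, deduplicated up to reverse.

    Walks start at ``start_segment`` (any segment if None) in either
    orientation, and extend through adjacencies up to ``max_length``
    segment traversals; every prefix reaching ``end_segment`` (or every
    walk, if None) is emitted.  Walks longer than the cap are flagged
    truncated rather than silently dropped.
    """
    starts = (
        [(start_segment, "+"), (start_segment, "-")]
        if start_segment is not None
        else [(s.id, o) for s in graph.segments for o in "+-"]
    )
    results: dict[tuple, DerivativeModel] = {}

    def emit(path: list, truncated: bool) -> None:
        if end_segment is not None and path[-1][0] != end_segment:
            return
        model = DerivativeModel(walk=tuple(path), truncated=truncated)
        key = model.canonical()
        if key not in results:
            results[key] = model

    def dfs(path: list) -> None:
        seg, orient = path[-1]
        if len(path) >= max_length:
            emit(path, truncated=bool(graph.neighbours(seg, _exit_end(orient))))
            return
        emit(path, truncated=False)
        for _adj, (nseg, nend) in graph.neighbours(seg, _exit_end(orient)):
            dfs(path + [(nseg, _entry_orient(nend))])

    for start in starts:
        dfs([start])
    return sorted(results.values(), key=lambda m: (len(m.walk), m.walk))


def validate_walk(graph: SegmentGraph, model: DerivativeModel) -> bool:
    """Independent check that consecutive walk elements are connected by an
    adjacency with matching ends."""
    for (s1, o1), (s2, o2) in zip(model.walk[:-1], model.walk[1:]):
        exit_end = _exit_end(o1)
        entry_end = L if o2 == "+" else R
        ok = any(
            (adj.a == (s1, exit_end) and adj.b == (s2, entry_end))
            or (adj.b == (s1, exit_end) and adj.a == (s2, entry_end))
            for adj in graph.adjacencies
        )
        if not ok:
            return False
    return True


def transcribed_exons(
    model: DerivativeModel, graph: SegmentGraph, exons: Sequence[Exon]
) -> list[tuple[Exon, bool]]:
    """Exons encountered intact along the walk, with forward-sense flag."""
    seg_by_id = {s.id: s for s in graph.segments}
    out = []
    for seg_id, orient in model.walk:
        seg = seg_by_id[seg_id]
        contained = [
            e
            for e in exons
            if e.chrom == seg.chrom and seg.start <= e.start and e.end <= seg.end
        ]
        contained.sort(key=lambda e: e.start, reverse=(orient == "-"))
        for e in contained:
            forward = (e.strand == "+") == (orient == "+")
            out.append((e, forward))
    return out


def explain_transcript(
    model: DerivativeModel,
    graph: SegmentGraph,
    gene_models: Mapping[str, GeneModel],
    donor_label: str,
    acceptor_label: str,
) -> bool:
    """Does the walk explain an observed splice junction donor->acceptor?

    True iff the donor exon occurs before the acceptor exon along the
    walk, both transcribed forward, with no intervening exon of either
    gene in the opposing orientation.
    """
    if not model.walk:
        return False
    all_exons = [e for g in gene_models.values() for e in g.all_exons()]
    seq = transcribed_exons(model, graph, all_exons)
    genes_of_interest = {donor_label.partition(":")[0], acceptor_label.partition(":")[0]}
    donor_positions = [i for i, (e, fwd) in enumerate(seq) if e.label == donor_label and fwd]
    for i in donor_positions:
        for jdx in range(i + 1, len(seq)):
            exon, fwd = seq[jdx]
            if exon.label == acceptor_label and fwd:
                return True
            if exon.gene in genes_of_interest and not fwd:
                break
    return False


@dataclass(frozen=True)
class DupInvInsertMotif:
    """Tandem duplication whose internal junction carries an inverted insert."""

    dup_interval: tuple[str, int, int]  # chrom, 1-based start, end
    insert_interval: tuple[str, int, int]
    dup_span: int
    insert_span: int
    junction_ids: tuple[str, str]


def detect_dup_with_inverted_insertion(
    junctions: Sequence[SvJunction], gene: GeneModel | None = None
) -> DupInvInsertMotif | None:
    """Pattern-match the tandem-dup-with-inverted-insertion signature.

    The motif leaves two same-chromosome inversion-type junctions: a
    left/left junction joining the duplication end (p2) to the insert end
    (q2), and a right/right junction joining the insert start (q1) back
    to the duplication start (p1), with p1 < p2, q1 < q2 and disjoint
    intervals.  The two spans are symmetric in the junction evidence
    alone; when a gene is given, the assignment whose duplicated interval
    overlaps the gene is preferred (a duplication *of* the gene region is
    what the motif describes).  A plain tandem duplication (single
    junction) does not match: the insertion is required.
    """
    if len(junctions) < 3:
        return None
    ll = [
        j
        for j in junctions
        if j.end_a.chrom == j.end_b.chrom
        and j.end_a.retained == LEFT
        and j.end_b.retained == LEFT
    ]
    rr = [
        j
        for j in junctions
        if j.end_a.chrom == j.end_b.chrom
        and j.end_a.retained == RIGHT
        and j.end_b.retained == RIGHT
    ]
    candidates = []
    for j1 in ll:
        for j2 in rr:
            if j1.end_a.chrom != j2.end_a.chrom:
                continue
            chrom = j1.end_a.chrom
            for p2, q2 in ((j1.end_a.pos, j1.end_b.pos), (j1.end_b.pos, j1.end_a.pos)):
                for q1, p1 in ((j2.end_a.pos, j2.end_b.pos), (j2.end_b.pos, j2.end_a.pos)):
                    if not (p1 < p2 and q1 < q2):
                        continue
                    if not (p2 < q1 or q2 < p1):  # intervals must be disjoint
                        continue
                    motif = DupInvInsertMotif(
                        dup_interval=(chrom, p1, p2),
                        insert_interval=(chrom, q1, q2),
                        dup_span=p2 - p1 + 1,
                        insert_span=q2 - q1 + 1,
                        junction_ids=(j1.id, j2.id),
                    )
                    candidates.append(motif)
    if not candidates:
        return None
    if gene is not None:
        overlapping = [
            m
            for m in candidates
            if m.dup_interval[0] == gene.chrom
            and m.dup_interval[1] <= gene.end
            and m.dup_interval[2] >= gene.start + 1
        ]
        non_insert = [
            m
            for m in overlapping
            if not (
                m.insert_interval[1] <= gene.end and m.insert_interval[2] >= gene.start + 1
            )
        ]
        if non_insert:
            return non_insert[0]
        if overlapping:
            return overlapping[0]
    return candidates[0]


def to_dot(graph: SegmentGraph) -> str:
    """GraphViz DOT export of the segment graph."""
    lines = ["graph segments {", "  rankdir=LR;"]
    for seg in graph.segments:
        lines.append(
            f'  s{seg.id} [shape=box,label="{seg.chrom}:{seg.start + 1}-{seg.end}"];'
        )
    for adj in graph.adjacencies:
        style = "solid" if adj.kind == "variant" else "dotted"
        label = f',label="{adj.junction_id}"' if adj.junction_id else ""
        lines.append(
            f"  s{adj.a[0]} -- s{adj.b[0]} [style={style},taillabel={adj.a[1]},headlabel={adj.b[1]}{label}];"
        )
    lines.append("}")
    return "\n".join(lines)
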