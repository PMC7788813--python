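"""Fusion interpretation: reading frame, domain retention, activation class.

The interpretation rules are those used for NRG1-style fusions:

* a fusion is *activating* only if the transcript keeps the EGF-like
  receptor-binding domain of the 3' gene in frame (the autocrine-loop
  requirement), with the 5' partner either contributing coding sequence
  that preserves the codon phase at the junction or contributing only
  untranslated sequence (translation then initiates at the 3' gene's own
  start codon);
* rearrangements whose only candidates are out of frame, lose the
  EGF-like domain, retain only the 5' end of the gene, or splice in at or
  after the transmembrane exon are *likely inactivating*;
* complex cases (multiple breakpoints without RNA support) and fusions
  from undocumented partner exons with unknown partner frame are
  *indeterminate*.

Presence of the cytoplasmic tail is reported per isoform but never used
for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gene_models import FusionIsoform, GeneModel
from .junction_scan import round_half_away
from .sv_integration import CaseRearrangementRecord, FusionCandidate

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
UNKNOWN_PARTNER_EXON = "unknown_partner_exon"

ACTIVATING = "activating"
LIKELY_INACTIVATING = "likely_inactivating"
INDETERMINATE = "indeterminate"

DOMAIN_FLAGS = ("Ig_like", "EGF_like", "transmembrane", "cytoplasmic_tail", "beta3_terminus")


def frame_status(
    partner_cds_len: int | None,
    acceptor_phase: int,
    partner_contribution: str = "coding",
    three_prime_in_frame: bool | None = None,
) -> tuple[str, str]:
    """Reading-frame status of a fusion junction.

    ``acceptor_phase`` is the phase of the 3' gene's spliced-in exon (the
    number of nucleotides of the boundary-spanning codon contributed
    upstream in the native transcript, mod 3).  A coding partner preserves
    the frame iff its contributed CDS length is congruent to that phase
    mod 3.  A UTR-only partner is in frame by construction: translation
    initiates at the 3' gene's own start codon.  An unknown partner exon
    gives unknown_partner_exon; ``three_prime_in_frame`` then records the
    3'-side sub-check (whether the fused sequence reads through the 3'
    gene in frame) in the returned note.

    Returns (status, note).
    """
    if acceptor_phase not in (0, 1, 2):
        raise ValueError(f"acceptor_phase must be 0/1/2, got {acceptor_phase}")
    if partner_contribution == "utr_only":
        return IN_FRAME, "partner contributes only untranslated sequence"
    if partner_contribution == "unknown" or partner_cds_len is None:
        note = ""
        if three_prime_in_frame:
            note = "possible activating, partner frame unknown (3' side in frame)"
        return UNKNOWN_PARTNER_EXON, note
    if partner_cds_len < 0:
        raise ValueError("partner_cds_len must be >= 0")
    if partner_cds_len % 3 == acceptor_phase:
        return IN_FRAME, ""
    return OUT_OF_FRAME, ""


def cassette_frame(length_nt: int) -> tuple[bool, int]:
    """Frame effect of inserting a cassette exon of ``length_nt`` bases.

    The insertion preserves the downstream reading frame iff its length is
    a multiple of three, in which case it adds ``length_nt // 3`` residues.
    """
    if length_nt < 0:
        raise ValueError("cassette length must be >= 0")
    in_frame = length_nt % 3 == 0
    return in_frame, (length_nt // 3 if in_frame else 0)


def domain_retention(isoform: FusionIsoform, three_prime_gene: GeneModel) -> dict:
    """Domain flags for one isoform, from exon role tags.

    beta3_terminus and cytoplasmic_tail/transmembrane are mutually
    exclusive: a beta3-terminating transcript stops before the
    transmembrane exon.
    """
    g3 = three_prime_gene.name
    tags = set()
    for exon in isoform.exons:
        if exon.gene == g3:
            tags |= set(exon.tags)
    flags = {
        "Ig_like": "Ig_like" in tags,
        "EGF_like": "EGF_like" in tags,
        "transmembrane": "transmembrane" in tags and not isoform.beta3,
        "cytoplasmic_tail": "cytoplasmic_tail" in tags and not isoform.beta3,
        "beta3_terminus": isoform.beta3,
    }
    return flags


@dataclass
class FusionCall:
    """An integrated DNA+RNA fusion call."""

    case_id: str
    five_prime_gene: str  # gene name or "novel"
    three_prime_gene: str
    spliced_in_exon: int | None
    frame_status: str
    partner_contribution: str  # coding | utr_only | unknown
    domain_flags: dict = field(default_factory=dict)
    rna_split_reads: int = 0
    dna_junction_ids: tuple = ()
    activation_class: str | None = None
    note: str = ""

    def __post_init__(self):
        if self.activation_class == ACTIVATING:
            if not self.domain_flags.get("EGF_like", False):
                raise ValueError("activating call must retain the EGF-like domain")
            if self.frame_status == OUT_OF_FRAME:
                raise ValueError("activating call cannot be out of frame")


def classify_rearrangement(
    record: CaseRearrangementRecord,
    min_rna_support: int = 1,
    promote_unknown_partner: bool = False,
) -> str | None:
    """Activation class for a case from its integrated fusion calls.

    Precedence (fixed by the worked examples the rules come from):
    activating (in-frame or UTR-only partner, EGF-like retained, RNA
    support) first; then indeterminate for unknown-partner-frame calls
    with the 3' side in frame (reported as possible activating) and for
    multi-breakpoint cases without RNA support; remaining candidate-bearing
    or broken-gene cases are likely inactivating.  Returns None when the
    case has no rearrangement evidence at the gene.
    """
    calls: list[FusionCall] = list(record.fusion_calls)
    candidates: list[FusionCandidate] = list(record.candidates)

    for call in calls:
        ok_frame = call.frame_status == IN_FRAME or call.partner_contribution == "utr_only"
        supported = call.rna_split_reads >= min_rna_support
        if ok_frame and call.domain_flags.get("EGF_like", False) and supported:
            call.activation_class = ACTIVATING
            return ACTIVATING
        if (
            promote_unknown_partner
            and call.frame_status == UNKNOWN_PARTNER_EXON
            and "3' side in frame" in call.note
            and call.domain_flags.get("EGF_like", False)
            and supported
        ):
            call.activation_class = ACTIVATING
            return ACTIVATING

    for call in calls:
        if (
            call.frame_status == UNKNOWN_PARTNER_EXON
            and call.rna_split_reads >= min_rna_support
        ):
            call.activation_class = INDETERMINATE
            return INDETERMINATE

    has_rna = any(c.rna_split_reads >= min_rna_support for c in calls)
    if record.multi_breakpoint and not has_rna:
        return INDETERMINATE

    if candidates or record.n_breakpoints > 0:
        for call in calls:
            call.activation_class = LIKELY_INACTIVATING
        return LIKELY_INACTIVATING
    return None


@dataclass(frozen=True)
class CohortSummary:
    n_cases: int
    n_fusion_positive: int
    fusion_percent: float
    n_dna_subset: int
    n_breakpoint_cases: int
    breakpoint_percent: int
    n_multi_breakpoint: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def cohort_summary(
    cases: Sequence[CaseRearrangementRecord],
    n_total: int,
    n_dna_subset: int,
    fusion_positive: Iterable[str] | None = None,
) -> CohortSummary:
    """Cohort-level frequencies.

    A case is fusion-positive if any integrated call has RNA split-read
    support (the cohort's fusion count includes out-of-frame fusions: a
    fusion transcript was observed even if predicted non-activating).
    Breakpoint cases are DNA-subset cases with breakends in the gene but
    no fusion.  ``fusion_percent`` is reported to one decimal, rounded
    half away from zero; ``breakpoint_percent`` to the nearest integer.
    """
    if n_total < 0 or n_dna_subset < 0:
        raise ValueError("cohort sizes must be >= 0")
    if fusion_positive is not None:
        fusion_ids = set(fusion_positive)
    else:
        fusion_ids = {
            r.case_id
            for r in cases
            if any(c.rna_split_reads >= 1 for c in r.fusion_calls)
        }
    n_fus = len(fusion_ids)
    breakpoint_cases = [
        r for r in cases if r.n_breakpoints >= 1 and r.case_id not in fusion_ids
    ]
    n_bp = len(breakpoint_cases)
    n_multi = sum(1 for r in breakpoint_cases if r.multi_breakpoint)
    fus_pct = round_half_away(1000.0 * n_fus / n_total) / 10.0 if n_total else 0.0
    bp_pct = round_half_away(100.0 * n_bp / n_dna_subset) if n_dna_subset else 0
    return CohortSummary(
        n_cases=n_total,
        n_fusion_positive=n_fus,
        fusion_percent=fus_pct,
        n_dna_subset=n_dna_subset,
        n_breakpoint_cases=n_bp,
        breakpoint_percent=bp_pct,
        n_multi_breakpoint=n_multi,
    )


# ---------------------------------------------------------------------------
# DNA + RNA integration


def resolve_partner_chain(
    donor_label: str,
    summary: pd.DataFrame,
    genes: Mapping[str, GeneModel],
    max_depth: int = 4,
) -> list:
    """Walk RNA junction calls upstream from a donor exon.

    The fusion transcript may pass through several genes (the double-
    fusion situation): starting from the donor exon of the junction into
    the 3' gene, look for a junction call whose acceptor is an upstream
    exon of the same gene (taking the best-supported donor when several),
    and recurse into that donor's gene.  Returns the partner exon chain
    5'->3' as Exon objects.
    """
    chain = []
    label = donor_label
    for _ in range(max_depth):
        gene_name, _, exon_name = label.partition(":")
        gene = genes.get(gene_name)
        if gene is None:
            break
        exon = gene.exon_by_name(exon_name)
        upstream_num = exon.number if exon.number is not None else None
        if upstream_num is None:
            # cryptic exon: it is spliced in from the host gene's upstream
            # exons; find the call feeding it
            chain.insert(0, exon)
            feeders = summary[summary["acceptor"] == exon.label]
            if feeders.empty:
                break
            label = feeders.sort_values("count", ascending=False).iloc[0]["donor"]
            continue
        # exons of this gene from the entry acceptor up to the donor
        entries = summary[
            summary["acceptor"].str.startswith(f"{gene_name}:")
            & (summary["acceptor"] != exon.label)
        ]
        entry_num = None
        feeder_label = None
        if not entries.empty:
            def acc_num(lbl: str):
                try:
                    return genes[gene_name].exon_by_name(lbl.partition(":")[2]).number
                except KeyError:
                    return None
            entries = entries.assign(_num=[acc_num(a) for a in entries["acceptor"]])
            entries = entries[entries["_num"].notna() & (entries["_num"] <= upstream_num)]
            if not entries.empty:
                best = entries.sort_values(["count"], ascending=False).iloc[0]
                entry_num = int(best["_num"])
                feeder_label = best["donor"]
        start_num = entry_num if entry_num is not None else min(
            e.number for e in gene.exons
        )
        block = [e for e in gene.exons if start_num <= e.number <= upstream_num]
        chain = block + chain
        if feeder_label is None or feeder_label.startswith(("novel(", "short(")):
            break
        label = feeder_label
    return chain


def integrate_case(
    record: CaseRearrangementRecord,
    summary: pd.DataFrame | None,
    genes: Mapping[str, GeneModel],
    three_prime_gene: GeneModel,
) -> CaseRearrangementRecord:
    """Merge DNA candidates with RNA junction calls into FusionCalls.

    Every RNA junction call into a 3'-gene acceptor becomes a FusionCall:
    the partner chain is resolved through upstream RNA junctions, its CDS
    contribution accumulated for the frame call, and domain retention
    evaluated over the enumerated isoforms (EGF retention reduces to
    "spliced in at or before the receptor-binding exon").  DNA candidates
    with no RNA support are retained on the record for classification but
    yield no call.
    """
    from .gene_models import enumerate_fusion_isoforms

    g3 = three_prime_gene
    calls: list[FusionCall] = []
    acceptor_phase_by_num = {e.number: e.phase for e in g3.exons if e.phase is not None}
    egf_nums = [e.number for e in g3.exons if "EGF_like" in e.tags]
    first_egf = min(egf_nums) if egf_nums else None

    if summary is not None and not summary.empty:
        into_g3 = summary[
            summary["acceptor"].str.startswith(f"{g3.name}:")
            & summary["donor_kind"].isin(["known", "cryptic", "novel"])
        ]
        for _, row in into_g3.iterrows():
            # a donor from the 3' gene's own annotated exons is normal
            # splicing, not a fusion junction (cryptic donors still count)
            if row["donor"].startswith(f"{g3.name}:") and row["donor_kind"] == "known":
                continue
            exon_name = row["acceptor"].partition(":")[2]
            acceptor_exon = g3.exon_by_name(exon_name)
            spliced_in = acceptor_exon.number
            donor = row["donor"]
            if row["donor_kind"] == "novel":
                partner_contribution = "unknown"
                partner_cds = None
                # DNA candidate naming a partner gene makes the call concrete
                named = next(
                    (c for c in record.candidates if c.five_prime_gene), None
                )
                five_prime = named.five_prime_gene if named else "novel"
            else:
                chain = resolve_partner_chain(donor, summary, genes)
                donor_gene = donor.partition(":")[0]
                if not chain:
                    chain_gene = genes.get(donor_gene)
                    chain = list(chain_gene.exons) if chain_gene else []
                partner_cds = sum(e.cds_len for e in chain)
                partner_contribution = "utr_only" if partner_cds == 0 else "coding"
                five_prime = chain[0].gene if chain else donor_gene
            phase = acceptor_phase_by_num.get(spliced_in, 0)
            status, note = frame_status(
                partner_cds,
                phase,
                partner_contribution=partner_contribution,
                three_prime_in_frame=True if partner_contribution == "unknown" else None,
            )
            egf_retained = first_egf is not None and spliced_in <= first_egf
            # aggregate domain flags across isoforms of this fusion
            isoforms = enumerate_fusion_isoforms([acceptor_exon], g3, include_cryptic=False)
            any_flags = {k: False for k in DOMAIN_FLAGS}
            for iso in isoforms:
                fl = domain_retention(iso, g3)
                for k in DOMAIN_FLAGS:
                    any_flags[k] = any_flags[k] or fl[k]
            any_flags["EGF_like"] = egf_retained
            any_flags["Ig_like"] = any_flags["Ig_like"] and spliced_in <= min(
                (e.number for e in g3.exons if "Ig_like" in e.tags), default=spliced_in
            )
            calls.append(
                FusionCall(
                    case_id=record.case_id,
                    five_prime_gene=five_prime,
                    three_prime_gene=g3.name,
                    spliced_in_exon=spliced_in,
                    frame_status=status,
                    partner_contribution=partner_contribution,
                    domain_flags=any_flags,
                    rna_split_reads=int(row["count"]),
                    dna_junction_ids=tuple(j.id for j in record.junctions),
                    note=note,
                )
            )
    record.fusion_calls = calls
    return record


def fusion_call_table(calls: Sequence[FusionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "case_id": c.case_id,
            "five_prime_gene": c.five_prime_gene,
            "three_prime_gene": c.three_prime_gene,
            "spliced_in_exon": c.spliced_in_exon,
            "frame_status": c.frame_status,
            "partner_contribution": c.partner_contribution,
            "rna_split_reads": c.rna_split_reads,
            "dna_junctions": ",".join(c.dna_junction_ids),
            "activation_class": c.activation_class,
            "note": c.note,
        }
        row.update({f"retains_{k}": v for k, v in c.domain_flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)
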