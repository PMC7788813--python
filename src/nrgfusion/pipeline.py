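"""End-to-end orchestration helpers shared by the CLI, tests and scripts.

These functions wire the stages together for one case: simulate (or load)
inputs, scan RNA reads, filter DNA junctions, integrate, classify.  They
operate on in-memory objects plus a working directory for file artifacts.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fusion_annotation import classify_rearrangement, integrate_case
from .junction_scan import build_anchor_index, call_junctions, scan_reads, summarise_junctions
from .sv_integration import (
    breakpoints_in_gene,
    filter_somatic,
    load_panel_bedpe,
    parse_breakend_vcf,
    predict_fusion_from_junction,
)
from .synthetic_data import (
    SimulationConfig,
    ToyData,
    get_preset,
    make_cohort,
    simulate_junction_reads,
    simulate_sv_vcf,
    write_fastq,
)

PARTNER_GENES = ("PPP6R3", "TENM4", "WRN", "ZNF704")
TARGET_GENE = "NRG1"


def scan_composition(
    toy: ToyData,
    composition: dict,
    config: SimulationConfig,
    workdir,
    dedup: bool = False,
    index=None,
) -> pd.DataFrame:
    """Simulate junction reads for a composition, scan them, summarise."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    fastq = workdir / "reads.fastq"
    write_fastq(simulate_junction_reads(toy, composition, config), fastq)
    if index is None:
        index = build_anchor_index(list(toy.genes.values()), toy.genome, k=20)
    hits = scan_reads(fastq, index, min_flank=config.min_flank)
    calls = call_junctions(hits, index, min_flank=config.min_flank)
    return summarise_junctions(calls, dedup=dedup)


def analyse_junctions(toy: ToyData, junctions, summary, case_id: str = "case"):
    """Filter-stage output -> per-case record with candidates, calls, class."""
    nrg1 = toy.genes[TARGET_GENE]
    partners = [toy.genes[g] for g in PARTNER_GENES]
    record = breakpoints_in_gene(junctions, nrg1, case_id=case_id)
    for j in junctions:
        cand = predict_fusion_from_junction(j, partners, nrg1)
        if cand:
            record.candidates.append(cand)
    record = integrate_case(record, summary, toy.genes, nrg1)
    record.activation_class = classify_rearrangement(record)
    return record


def analyse_preset(
    toy: ToyData, preset_name: str, config: SimulationConfig, workdir, index=None
):
    """Simulate one preset and run the full pipeline over its outputs.

    The DNA side goes through the VCF round trip (write then parse) and
    the somatic filters; the RNA side through the read scanner.
    """
    workdir = Path(workdir)
    case = get_preset(preset_name)
    summary = scan_composition(
        toy, case.rna_composition, config, workdir, index=index
    ) if case.rna_composition else None
    sim = simulate_sv_vcf(case.junctions, config, workdir)
    parsed = parse_breakend_vcf(sim["vcf"])
    kept = filter_somatic(parsed, panel=load_panel_bedpe(sim["panel"]))
    record = analyse_junctions(toy, kept, summary, case_id=preset_name)
    return record, summary, kept


def analyse_cohort(toy: ToyData, config: SimulationConfig, workdir):
    """Run the synthetic cohort through the pipeline, case by case.

    Cases with DNA junctions go through the VCF write/parse round trip and
    the somatic filters; fusion-positive cases additionally get their RNA
    compositions simulated and scanned.  Returns the per-case records
    (evidence-bearing and negative alike) ready for cohort summarisation,
    plus the cohort case list.
    """
    workdir = Path(workdir)
    cases = make_cohort()
    index = build_anchor_index(list(toy.genes.values()), toy.genome, k=20)
    records = []
    for case in cases:
        summary = None
        if case.rna_composition:
            summary = scan_composition(
                toy, case.rna_composition, config, workdir / case.case_id, index=index
            )
        junctions = []
        if case.junctions:
            sim = simulate_sv_vcf(
                case.junctions, config, workdir / case.case_id, include_artefacts=False
            )
            junctions = filter_somatic(parse_breakend_vcf(sim["vcf"]))
        record = analyse_junctions(toy, junctions, summary, case_id=case.case_id)
        records.append(record)
    return records, cases
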