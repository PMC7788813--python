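# nrgfusion

Targeted analysis of *NRG1* gene fusions and rearrangements from paired
DNA and RNA sequencing, at desk scale.

*NRG1* encodes ligands of the ERBB2(HER2)–ERBB3 receptor heterodimer.
Fusions that place another gene's promoter (and possibly coding sequence)
upstream of *NRG1*'s EGF-like receptor-binding domain can create an
autocrine loop and are candidate drug targets; but *NRG1* is also
*in*activated in many carcinomas, and a large fraction of *NRG1*
rearrangements break the gene without creating an activating fusion.
Telling the two apart requires combining weak RNA evidence (often one or
two junction-spanning reads) with filtered DNA rearrangement calls and
interpreting reading frame and domain retention carefully. `nrgfusion`
implements that workflow for a configurable set of genes of interest:

- **Splice-anchor read scan** (`junction_scan`) — a pure text search of
  FASTQ reads for exon-boundary anchor k-mers (default k = 20) and their
  reverse complements; the sequence adjacent to each anchor hit is
  classified against the donor/acceptor anchors of all modelled exons,
  including unannotated cryptic exons, or reported verbatim as novel.
  This finds fusions that alignment-based callers miss for lack of read
  support or because the partner exon is undocumented.
- **Breakend SV integration** (`sv_integration`) — VCF 4.2 BND bracket
  decoding into oriented junctions, somatic filtering (matched-normal
  support, panel of normals, mitochondrial/unassembled contigs), and
  orientation-consistent fusion candidate prediction.
- **Fusion interpretation** (`fusion_annotation`) — reading-frame calls
  from partner CDS length vs acceptor exon phase (a coding partner is in
  frame iff `partner_cds_len ≡ phase (mod 3)`; a UTR-only partner leaves
  translation to the 3' gene's own start codon), per-isoform domain
  retention flags, and an activating / likely-inactivating /
  indeterminate classification; cohort-level frequency summaries.
- **Copy number** (`copy_number`) — windowed read-count ratios with
  binary-segmentation change points, and concordance of unbalanced
  junctions with copy-number steps.
- **Reconstruction** (`reconstruction`) — breakpoint segment graphs,
  exhaustive derivative-chromosome walk enumeration, transcript
  explanation, and detection of the tandem-duplication-with-inverted-
  insertion junction motif.
- **Synthetic data** (`synthetic_data`) — a seeded generator for a toy
  two-chromosome genome with NRG1/TENM4/PPP6R3/WRN/ZNF704-like mini
  genes, derivative chromosomes, junction-spanning reads at exact
  compositions, and tumour/normal breakend VCFs, so the entire pipeline
  is testable without any external data.

## Worked example

Simulate the cell-line-like double-fusion rearrangement (a 5' gene's
non-coding first exon spliced onto a middle gene, then into *NRG1*-like
exon 3, with an inverted intronic fragment carrying a 78-nt cryptic exon
inserted at the main junction) and run the full analysis:

```bash
nrgfusion all --preset mda175 --seed 2 --out demo
cat demo/report.md
```

```
# nrgfusion report: preset mda175

- breakpoints in gene: 7 (multi: True)
- activation class: activating
- fusion calls: 2

## Junction summary

   acceptor       donor donor_kind  count  total_at_acceptor  percent
     NRG1:3    TENM4:12    known      122                160       76
     NRG1:3 TENM4:int15  cryptic       38                160       24
    TENM4:3    PPP6R3:1    known      144                145       99
    TENM4:3     TENM4:2    known        1                145        1
TENM4:int15    TENM4:12    known       10                 10      100
```

Reading the output: 160 split reads cross the junction into NRG1 exon 3;
24% (38/160) splice in from the cryptic antisense exon `int15` and the
rest from TENM4 exon 12, so the cryptic exon is a minor isoform.  At the
TENM4 exon 3 acceptor, 144 of 145 reads splice in from PPP6R3 exon 1 and
only one carries TENM4's own exon 2 donor — the double fusion, not
normal TENM4, drives expression.  Seven DNA breakpoints fall within the
NRG1-like gene (DNA alone would make fusion prediction hazardous), but
the RNA-supported, in-frame, EGF-domain-retaining call classifies the
case as activating.  The 78-nt cryptic exon inserts 26 amino acids and
preserves the reading frame (78 ≡ 0 mod 3).

Other presets exercise the remaining outcomes: `simple_del` (in-frame
deletion fusion, activating), `simple_del_oof` (out of frame, likely
inactivating), `dup_inv_insert` (fusion from an unannotated partner exon
with a 57 kb tandem duplication interrupted by a 24 kb inverted insert;
indeterminate — "possible activating, partner frame unknown"),
`inactivating` (retains only the gene's 5' end), and `complex_multi`
(multiple breakpoints, no consistent fusion, indeterminate).

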