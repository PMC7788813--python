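# Methods

## Scope and model

`nrgfusion` analyses rearrangements of a 3' gene of interest (an
*NRG1*-like gene) against a small panel of candidate 5' partner genes.
It does not align reads or call variants from BAMs; it consumes raw RNA
reads (FASTQ), breakend SV calls (VCF 4.2 BND), gene models (GTF plus a
YAML side file) and a reference FASTA, and produces junction summaries,
filtered junction sets, integrated fusion calls with an activation
class, copy-number concordance tables and derivative-chromosome models.

Coordinates are 0-based half-open internally and 1-based inclusive in
all I/O and reports, so a printed interval `start..end` has length
`end − start + 1`.  Exons are numbered by genome order (ascending
genomic start), independent of transcript usage: fusion breakpoints are
genomic events, and this numbering keeps DNA and RNA evidence on one
scale.  The numbering is deterministic and invariant to input order;
overlapping exon intervals are rejected as annotation errors.

## Splice-anchor read scan

Each exon boundary contributes an anchor: the first (acceptor) or last
(donor) k transcribed bases of the exon, read 5'→3' on the mRNA.  The
default k = 20 was chosen so that anchors are unique in desk-scale
genomes; the synthetic generator verifies uniqueness exhaustively and
the index construction fails loudly on collisions (the remedy is a
larger k).  Cryptic exons — unannotated, possibly antisense within
another gene's intron — carry host-strand coordinates plus their own
expressed strand; their anchors are computed on the expressed strand.

Reads are scanned for exact anchor occurrences in both orientations,
anywhere within the read (the junction position in a read is
arbitrary).  The default is a pure text search with zero mismatches; an
optional one-mismatch mode expands the index over the 1-Hamming
neighbourhood, dropping ambiguous neighbours.  The partner-side flank of
each hit (5' of an acceptor anchor, 3' of a donor anchor) is classified
by exact prefix/suffix match against the complementary-side anchors of
all modelled exons; no match is reported as `novel` with the literal
flank retained, which is what makes fusions from undocumented partner
exons discoverable.  Flanks shorter than `min_flank` (default 12 nt)
are `too_short` and excluded from fraction denominators — denominators
count only classifiable split reads.

A read spanning a junction between two indexed exons carries both
anchors; the two hits are collapsed per (read, acceptor, donor) so each
read counts once per junction.  Summaries are per-acceptor donor
counts with integer percentages (rounded half away from zero).
Duplicate collapsing of identical strand-normalised read sequences is a
flag: cell-line-style libraries are summarised with duplicates removed,
cohort RNA (sequenced without duplicate removal) with duplicates kept.

## Breakend integration and somatic filtering

VCF BND mate pairs are collapsed to one oriented junction each; the
bracket notation is decoded so each breakend records which side of its
position is retained.  Somatic filtering drops junctions with any
supporting reads in the matched normal, junctions matching a
panel-of-normals junction (same orientation, both ends within ±10 bp —
the panel tolerance is a package decision, exposed as a parameter), and
junctions touching mitochondrial or unassembled contigs.  Filtering is
order-preserving and idempotent.

"Breakpoints within the gene" counts breakends inside the annotated
gene span (flank 0 bp by default, configurable for promoter-region
joins).  A fusion candidate is proposed from a junction iff one
breakend lies inside a 5' partner gene retaining its promoter-proximal
exons on the coding strand, and the other lies upstream of a 3'-gene
acceptor exon with the retained side reading into it; the predicted
spliced-in exon is the lowest-numbered acceptor downstream.  Breakends
inside the 3' gene downstream of the receptor-binding exon that retain
only the gene's 5' part are emitted as `five_prime_end_only`
candidates for interpretation, never as fusions.

## Frame, domains, activation class

A coding 5' partner preserves the reading frame iff the CDS length it
contributes is congruent mod 3 to the acceptor phase of the spliced-in
exon (the number of nucleotides of the boundary codon contributed
upstream in the native transcript).  A partner contributing only
untranslated sequence is in frame by construction: translation
initiates at the 3' gene's own start codon.  A cassette-exon insertion
of ℓ nt is frame-preserving iff ℓ ≡ 0 (mod 3), adding ℓ/3 residues.
When the RNA shows a multi-gene transcript chain, the partner CDS is
accumulated by walking junction calls upstream (best-supported donor at
each step, bounded depth).

Domain flags come from exon role tags (Ig-like, EGF-like,
transmembrane, cytoplasmic tail); the β3 terminus is modelled as a
genomic extension of the last pre-tail exon, not a separate exon, and
is mutually exclusive with the transmembrane/tail flags.  Cytoplasmic-
tail presence is reported per isoform but never used in classification.

Classification precedence: **activating** requires an in-frame (or
UTR-only-partner) call retaining the EGF-like domain with RNA split-read
support (threshold 1 read — fusions with only one or two supporting
reads are real at cohort depth; configurable).  **Indeterminate** covers
unknown-partner-exon calls whose 3' side is in frame (reported as
"possible activating, partner frame unknown"; a flag can promote them)
and multi-breakpoint cases without RNA support — these take precedence
over inactivating-looking DNA candidates, because complex rearrangements
are uninterpretable from DNA alone.  **Likely inactivating** covers
cases whose candidates are all out of frame, lose the EGF-like domain,
retain only the 5' end, or splice in at/after the transmembrane exon,
and single-breakpoint cases with no fusion candidate.  Cohort
percentages are fixed-convention: fusion frequency to one decimal,
breakpoint-case frequency to the nearest integer, both rounded half
away from zero.

## Copy number

Read starts are counted in fixed windows (≥100 bp); ratios are
library-size-normalised tumour/reference per window, with
zero-reference windows masked.  Change points are found by recursive
binary splitting on the mean ratio with a threshold (`min_step`,
default 0.3 ratio units) — a deliberately simple, transparent stand-in
for a production caller, sufficient at targeted-capture scale; no GC
correction is applied at desk scale.  A junction breakend within one
window of a step is labelled unbalanced with the step's direction,
otherwise balanced.  Known behaviour: at thresholds well below the true
step size, single noisy boundary windows can produce spurious small
steps; the threshold is the control.

## Reconstruction

Breakpoints partition chromosomes into segments (per chromosome,
segments = breakpoints + 1); each junction induces one adjacency
between segment extremities, and consecutive segments are linked by
reference adjacencies.  Derivative models are walks of oriented
segments enumerated exhaustively to a length cap (default 12
traversals), deduplicated up to reverse complement; all consistent
walks are reported rather than asserting one, since junction evidence
typically underdetermines the derivative.  A walk explains an observed
splice junction iff donor and acceptor exons occur along it intact, in
order, transcribed forward, with no intervening exon of either gene in
the opposing orientation.  Walk multiplicities can be compared against
copy-number segments as a soft consistency score, not a hard
constraint.

The tandem-duplication-with-inverted-insertion motif leaves two
same-chromosome inversion-type junctions (one joining two left-retained
breakends, one two right-retained) whose coordinates give the
duplicated and inserted spans directly.  From junction evidence alone
the two spans are symmetric; the detector prefers the assignment whose
duplicated interval overlaps the gene of interest, which is the
configuration the motif describes (a duplication *of* the gene region).
A plain tandem duplication (single junction) never matches: the
insertion is required.

## Synthetic data: what it emulates, and what it does not

The generator builds a two-chromosome (~200 kb each) random genome
carrying five mini genes whose exon/CDS layout mirrors the loci of
interest: a 5' gene with a non-coding first exon; a 16-exon middle gene
hosting a 78-nt antisense cryptic exon in intron 15; an 18-exon 3' gene
with alternative exons {10, 11}, a β3 extension of exon 11, Ig-like
exons 3–4, EGF-like exon 9, transmembrane exon 12 and tail exons 13–18;
plus a deletion-fusion partner immediately 5' of it and a partner with
an unannotated donor exon.  CDS lengths are chosen so that the planted
in-frame and out-of-frame fusions have the intended phase relations.
All toy genes are on the + strand, so genome-order numbering coincides
with transcript order; the antisense geometry that matters — the
cryptic exon and the inverted-fragment derivative — is preserved.

Reads are 75 nt single-end (the junction scan is per-read), planted at
exact configured counts per junction with seeded uniform placement and
roughly half reverse-complemented; compositions are exact by default so
fractions are deterministic, with base errors available for stochastic
tests.  Breakend VCFs are emitted as one paired-sample file
(NORMAL + TUMOUR split-read counts), with optional planted germline,
panel and mitochondrial artefacts exercising every somatic filter.
Copy-number reads are Poisson-sampled uniform positions scaled by
segment copy ratio.

What passing tests on this generator show: the algorithms recover
planted truth exactly under error-free, anchor-unique, deterministic
conditions.  What they do not show: robustness to sequencing error,
paralogy/repeat-induced anchor ambiguity, alignment artefacts in real
SV call sets, coverage bias, or tumour purity/subclonality — real data
adds all of these.  Problem sizes throughout (200 kb chromosomes,
hundreds of reads, ≤30 copy-number windows, 571-case cohort with 24
evidence-bearing cases) were chosen as the smallest that exercise every
code path with comfortable statistical margins.

## Numerical and degenerate-input conventions

Percentages round half away from zero.  Anchor-index collisions are
errors, not warnings.  Anchors containing N are flagged ambiguous with
a warning.  Empty cohorts, empty FASTQs and junction-free VCFs return
empty results without error; empty copy-number regions and k larger
than the exon are errors.  Ties in flank classification (two candidate
anchors matching a sub-k flank) fall back to `novel` rather than
guessing.  All randomness flows from a single integer seed via
salt-separated NumPy generators; identical configurations give
byte-identical outputs.

## Known limitations

The scanner is exact-match (optionally 1-mismatch) and quality-blind by
design; at real read-error rates it undercounts junction reads.  The
binary-segmentation copy-number stand-in has no multi-scale penalty and
can over-segment at low thresholds.  Walk enumeration is exponential in
the adjacency branching and relies on the length cap; complex genomes
need start/end constraints.  The partner-chain resolver takes the
best-supported upstream donor and will mis-assemble mixtures of fusion
and normal transcripts at similar abundance.
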