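# Methods

This note documents the models and procedures implemented in
`neolandscape`, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the package's
numerical conventions and limitations.

## Somatic filter cascade

A candidate somatic call passes when all five criteria hold:

| id | criterion | threshold |
|----|-----------|-----------|
| C1 | tumor AND matched-normal sequencing depth | ≥ 10 |
| C2 | tumor reads supporting the variant | ≥ 3 |
| C3 | tumor allele fraction | ≥ 0.05 |
| C4 | normal allele fraction | ≤ 0.01 |
| C5 | panel-of-normals frequency < 0.05, **or** panel frequency ≥ 0.05 and tumor allele fraction ≥ 0.30 | — |

All thresholds are inclusive. C5's second clause is a rescue: a variant
recurrent in the normal panel is still accepted when its tumor allele
fraction is high enough to make a recurrent artifact or germline
leakage unlikely. The decision is a pure function of the five fields,
so filtering is idempotent and order-preserving; every decision records
the exact criteria failed.

TMB is the count of passing coding mutations (SNVs and indels) divided
by the coding footprint in Mb. The footprint is a parameter
(`coding_mb`, default 34.0 — a conventional whole-exome coding size)
because no single value is canonical; TMB scales inversely with it.

## Mutant proteins and candidate peptides

Only missense SNVs and in-frame (length difference ≡ 0 mod 3) indels
produce candidates; frameshifts, stop-gains and splice events are out
of scope. The variant is applied to the transcript CDS, the mutant CDS
is translated (standard code, stop-trimmed), and the affected residue
interval is the maximal changed span between wild-type and mutant
computed by common prefix/suffix. For pure deletions that span is
empty, so the two junction-flanking residues are marked instead — the
junction is the only place novel sequence arises. A variant creating a
premature stop is flagged and yields no peptides.

Candidate windows are every 9/10/11-residue substring of the mutant
that (a) lies in bounds, (b) overlaps the affected interval, and
(c) does not occur anywhere in the wild-type protein. Condition (c) is
a deliberate strictness: a window identical to wild-type sequence
cannot be tumor-specific, and after an in-frame indel some
mutation-overlapping windows do recur in the wild type. An interior
missense site therefore yields exactly 9 + 10 + 11 = 30 windows; sites
within 10 residues of a terminus yield fewer (truncation). Duplicate
sequences are collapsed, and candidates are deduplicated per
(sequence, allele) across transcripts of a gene — identical epitopes
are one candidate. Candidates are the cross product of windows with the
patient's consensus HLA alleles.

## HLA consensus

Alleles are compared at 4-digit (two-field) resolution; deeper fields
are truncated on parse. The consensus of several typing tools is the
set intersection of their reported allele sets (at least two tools
required), and the patient-level set is the further intersection across
tissue, organoid, and PBMC. Intersection is deliberately conservative:
a peptide predicted against an allele any tool or sample failed to
confirm would be unusable for validation. Homozygous loci appear as a
single set element. There is no tie-break when tools disagree on one of
two alleles at a locus — the discordant allele is simply dropped and
logged.

## Presentation scoring and HSN flagging

Peptide presentation prediction is an external problem with its own
tooling, so the scorer is a pluggable interface. A scorer maps
(peptide, allele) to three features: binding percentile rank in
[0, 100] (lower = stronger), and cleavage and TAP transport
efficiencies in [0, 1]. The packaged `mock` scorer hashes
(seed, feature, peptide, allele) to uniform deviates — fully
deterministic, no biophysical content; it exists so pipelines are
reproducible and testable offline, and its outputs must not be
interpreted as affinity predictions. Binding ranks from the mock are
skewed toward weak binding (square-root transform) to resemble the
shape of real percentile ranks.

The default combined score is
`(1 − rank/100) · cleavage · TAP` — bounded in [0, 1] and monotone in
each favorable component. It is a documented package default, not a
published formula; alternative combiners are selectable.

High-score neoantigens (HSNs) are defined by a pooled quantile: all
scored tissue candidates in the cohort are ranked, the top
⌈0.30·N⌉ scores are flagged, the cutoff is the minimum flagged score,
and ties at the cutoff are all flagged (equal scores share a fate).
The pool (tissue / organoid / both) and fraction are configurable;
per-cohort pooling over tissues is the default. The same cutoff is then
applied to organoid candidates.

Validation selection per patient is deterministic: all MS-detected
peptides, then all TP53-derived peptides, then the highest-scoring
remainder until at least `k_min = 10` are chosen, with ties broken by
(score descending, sequence lexicographic). Fewer than `k_min`
candidates selects all with a warning.

## Evidence integration

Mutant expression is `(mutated reads / total reads) × gene expression`,
with 0 when the locus has no RNA coverage (a convention, documented so
downstream filtering is well defined). "Unexpressed" means mutant
expression ≤ 0 — i.e. zero mutant reads or zero gene expression — since
no numeric cutoff is canonical; the threshold is configurable.
Excluded candidates are kept in an audit table with a reason
(`unexpressed` / `no_rna_row`), so kept + audited always partition the
input.

Single-cell support admits a cell only when QUAL > 10 and DP > 20
(strict inequalities); a variant is single-cell-detected with at least
`min_cells = 1` admitted carrier cells, and the variant → barcode map
is returned for downstream cluster labeling. MS matching is exact
residue identity by default, with an isoleucine/leucine equivalence
switch (`il_equivalent`) because mass spectrometry cannot distinguish
the two; exact matching is the default since the stricter reading
never over-claims.

## Concordance and cohort statistics

The per-pair overlap uses the union denominator — shared /
(tissue-only + organoid-only + shared) — computed in exact rational
arithmetic before any rounding, so the three proportions sum to 1
exactly. The cross-sample matrix is the Jaccard index of organoid i's
variant set against tissue j's (Pearson correlation on binary
membership vectors is available by option; neither is claimed to be
what any particular published "corregram" used). Spearman's ρ uses
average ranks for ties with the t approximation for p (conventional
for n < 500); paired and unpaired t tests are the textbook two-tailed
forms; ANOVA is one-way with Fisher's LSD post-hoc (pairwise t on the
pooled within-group MSE); the χ² test is Pearson's without continuity
correction. These route through `scipy.stats` where possible (LSD is
implemented directly); the test suite checks every statistic against
independently written closed-form implementations to 1e-9.

## Mutation spectra and signature refitting

Every SNV is assigned to one of 96 channels: substitution class with
pyrimidine reference (C>A, C>G, C>T, T>A, T>C, T>G) × 5′ flank × 3′
flank, in that fixed lexicographic order. Purine-reference calls are
reverse-complemented with flanks swapped and complemented, making the
spectrum strand-invariant. Variants at contig edges (no flank) are
skipped with a warning.

Attribution is refitting against a fixed catalog, not de-novo
factorization: the L1-normalized spectrum is decomposed by non-negative
least squares onto the 96 × K signature matrix, signatures with weight
below `prune_below = 0.06` are removed, and the fit re-runs until
stable; final weights are renormalized to sum to at most 1 and the
residual is the L2 reconstruction error. This mirrors the behavior of
the standard refitting tools (and their 0.06 pruning convention). No
trinucleotide-frequency (exome/genome context) renormalization is
applied by default.

The packaged catalog is **synthetic** — built programmatically with
columns imitating the qualitative shape of familiar processes
(CpG-deamination C>T; flat clock-like; aflatoxin-style C>A; T>C at
ApT; a structured broad column; plus smooth random columns). Columns
are deliberately mutually separable so recovery studies are
informative; real catalogs should be passed in for real data. Nearly
collinear catalog columns (e.g. two flat "clock-like" signatures, as in
the real COSMIC pair SBS3/SBS5) make individual weights unidentifiable
at moderate mutation counts; that is a property of refitting itself,
not of this implementation.

## Synthetic cohorts and the truth ledger

The generator emulates the data structure of a 27-pair
tissue/organoid study:

- **Reference**: one contig per gene, the contig being the CDS
  (variant position = CDS position, 1-based), lengths 300–1500 nt,
  stop-free codons with a terminal stop; gene 1 is TP53 with an
  arginine codon planted at residue 90.
- **Paired variant sets**: per pair, a union size ~Poisson(90); a
  shared fraction drawn from Beta(4.8, 2.18) truncated to
  [0.28, 0.89] (truncated mean 0.6673) and realized **exactly in
  counts** — shared/private assignment is planted, not sampled — so
  overlap statistics recover the ledger values exactly; remaining
  private mutations split evenly between tissue-only and organoid-only.
- **SNV contexts** sampled from a signature mixture (default
  0.35/0.30/0.35 on the deamination-, clock-, and aflatoxin-like
  columns, making C>T/G>A the dominant class while the C>A signature
  stays prominent) by drawing a channel and placing the mutation at a
  reference position with the matching trinucleotide context on either
  strand. About 8% of variants are in-frame single-codon deletions.
- **Read statistics** realized from designed per-criterion failure
  probabilities (default 5% per criterion, plus a 5% panel-spike rescue
  branch), so each filter branch — including the C5 rescue — is
  exercised at a known rate.
- **Hotspots**: TP53 R90S planted in the shared core of
  Bernoulli(0.43) carriers per patient.
- **HLA**: diploid genotypes from a common-allele pool
  (East-Asian-leaning frequencies); organoids lose an allele with
  probability 0.04 (emulating occasional tissue/organoid HLA
  discordance), and each typer drops an allele with probability 0.05.
- **Expression / single-cell / MS**: each variant is expressed with
  probability 0.7 (mutant reads binomial at roughly the DNA allele
  fraction, gene expression lognormal(2, 1), RNA depth Poisson(50));
  15% of organoid variants get 1–5 admitted single-cell carrier rows
  plus occasional sub-threshold rows; the MS list holds two true mutant
  9mers taken from early patients' shared missense variants.

One child random stream per artifact class (variants, HLA, expression,
single-cell, clinical) keeps stages reproducible when parts of the
specification change. The truth ledger (JSON) records realized per-pair
counts and shared fractions, expressed subsets, single-cell-detected
variants, hotspot carriers, HLA genotypes, and the generating
parameters.

What the generator does **not** emulate: read-level data (no
FASTQ/BAM), clonal structure and subclonal allele-fraction
correlations, linkage between nearby variants, transcript isoforms and
splicing, realistic HLA linkage disequilibrium, MS detectability bias,
and tumor purity. Passing tests on synthetic cohorts therefore
demonstrate the correctness of the computations and the recoverability
of planted parameters — not the biological fidelity of any predictor.
Because shared variants carry one set of read statistics used for both
samples, a shared variant passes or fails the cascade in both samples
together; post-filter shared fractions consequently drift only by the
random removal of private variants.

## Pipeline and reproducibility

Stages read and write plain files (VCF 4.2, TSV, FASTA, JSON) under
one run directory in a fixed order: simulate (or ingest) → filter →
HLA → enumerate → score → integrate → concordance → signatures.
Chaining the stage functions (or CLI subcommands) is byte-identical to
the monolithic run, and the manifest records per-stage record counts
plus SHA-256 digests of every output, so a run is verifiable and
re-runnable from its own echoed configuration. Configuration is a
single YAML schema validated by pydantic with unknown keys rejected and
all violations reported at once; every threshold above is a config
default, never hard-coded.

## Problem sizes

The default cohort (27 pairs × ~90 mutations, ~160k tissue candidates)
runs end-to-end in under a minute on one CPU. The test suite uses
smaller cohorts where many replicates are needed: 100 × 6-pair cohorts
for similarity diagonal dominance, 100 × n=2,000 multinomial spectra
for signature recovery, and 4-pair cohorts for determinism and
composition checks. These sizes were chosen to make the Monte-Carlo
bounds (binomial 3-SE bands, ≥ 90–95% replicate success) sharp while
keeping the suite fast.

## Known limitations

- The mock scorer's scores have no biophysical meaning; HSN cutoffs
  computed from it are internally consistent but not comparable to
  published score scales.
- Peptides are generated per sample from all passing eligible
  mutations; restricting to tissue∩organoid mutations first is a
  configuration of the analysis, not currently a switch.
- The synthetic catalog is not the COSMIC catalog; exposures fitted
  against it are labelled by the synthetic column names to avoid any
  suggestion that real signature attributions were computed.
- Fusion-derived, frameshift, and class II epitopes; HLA LOH; purity
  correction; and de-novo signature discovery are out of scope.
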