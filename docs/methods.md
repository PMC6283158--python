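# Methods

This note records the models and statistical procedures implemented in
`splicescreen`, the choices made where several reasonable designs exist,
and what the synthetic benchmarks do and do not demonstrate.

## Event model

Transcript models are read from GTF/GFF3 (exon and optional CDS features);
coordinates are 1-based inclusive internally, 0-based half-open in BED
exports. One reference isoform per gene is chosen as the `.1`-suffixed
transcript when present, else the lexicographically smallest id — exitron
calling and a few conventions need a single reference model per gene.

Event definitions (per gene, strand-aware):

- **IR** — an intron spliced by ≥ 1 isoform whose span, including both
  splice sites, lies inside a single exon of ≥ 1 other isoform. Inclusion
  isoforms are the retainers. Keyed by the intron (variable boundaries:
  flanking exon edges are free to differ between isoforms).
- **ES** — an internal exon of ≥ 1 isoform spanned entirely by a single
  junction of another isoform. Keyed by (skipped-exon span, junction).
- **A5/A3** — two introns of the gene sharing exactly one boundary; a
  shared acceptor with differing donors is alternative 5′ choice, a shared
  donor with differing acceptors alternative 3′ choice, both in transcript
  orientation (so the genomic side flips on the minus strand). Keyed by
  both introns (strict boundaries); the isoforms carrying the shorter
  intron (more exonic sequence) are the inclusion set.
- **EX** — an intron lying strictly inside a CDS interval of the gene's
  reference isoform; the retaining (unspliced) forms are inclusion.

Two consequences of these definitions are intentional and covered by the
truth tables rather than suppressed: an exitron is by construction also an
IR event (reported under both types with distinct ids), and an
exon-skipping structure also generates one A5 and one A3 event, because
the skipping junction shares one boundary with each flanking intron.

The **first-intron flag** of an IR/EX event is true iff the retained
intron is the 5′-most intron (transcript orientation) of at least one
isoform that splices it. When an intron is first in one host and internal
in another, the any-transcript rule applies; this is a recorded choice,
and the annotation-wide expected fraction used by the enrichment test is
computed with the same rule over all annotated IR events, keeping the test
self-consistent.

Correctness of the extractor is established against an independent
brute-force oracle (`tests/bruteforce.py`) that compares every ordered
isoform pair with plain nested loops; on randomised annotations with up to
6 isoforms per gene the two agree exactly, including inclusion/exclusion
sets and first-intron flags.

## PSI and the empirical differential test

Per-sample PSI of an event is the TPM share of its inclusion isoforms.
With total event TPM below the expression floor (default 1 TPM,
configurable) the ratio is unstable and PSI is NA; an event with any NA
replicate is excluded from testing and reported with p = NA. For IR and EX
the inclusion set is the retaining form, so ΔPSI > 0 in the mutant reads
as "more retained".

Significance of ΔPSI (difference of condition means) is assessed against
an empirical null assembled from replicate scatter, in the spirit of
event-based differential-splicing tools that compare the observed shift to
between-replicate variability in expression-matched events. Concretely:

1. For every testable event, all absolute within-condition pairwise
   replicate PSI differences are collected (6 values per event at 3+3).
2. Each difference is scaled by √((1/n₁+1/n₂)/2). A raw pairwise
   difference has variance 2σ², the observed difference of condition means
   σ²(1/n₁+1/n₂); without the scale factor the null is √3 too wide at
   3v3 and the test's attained type-I error collapses to ~10⁻⁵ at the
   0.01 level. With it, the null matches the sampling variance of the
   test statistic under within-condition exchangeability.
3. Events are binned into quantile bins of mean total event TPM (default
   10); null values pool within bins, and
   p = (1 + #{null ≥ |ΔPSI|}) / (1 + N_bin).

The procedure is deterministic; the `seed` argument exists for interface
stability. The granularity of p is 1/(1+N_bin): with few events (≲ 200 per
bin pool) the test cannot reach p < 0.01 at all, which is the intended
conservative behaviour of an empirical null at small scale — benchmarks
use ≳ 2000 events. Raw p-values carry the decision rule (|ΔPSI| ≥ 0.1,
p < 0.01, both configurable); Benjamini–Hochberg q-values are reported
alongside but do not gate significance.

Null calibration (no planted effect, ~2000 events, logit-normal replicate
noise σ = 0.05) attains type-I ≈ 0.009–0.015 at the 0.01 level; planted
|ΔPSI| = 0.3 effects in 10% of events are recovered with sensitivity 1.0
and false-discovery proportion 0 under the same conditions (see
`scripts/acceptance.py`). The residual mild anti-conservatism comes from
pooling events with unequal PSI-scale variances within a TPM bin.

## Splice-site windows and variant masking

Windows are fixed-width and strand-aware: 5′ (donor) = last 3 exonic +
first 10 intronic bases (13 nt); 3′ (acceptor) = last 14 intronic + first
3 exonic bases (17 nt). On the plus strand an intron [s, e] gives
[s−3, s+9] and [e−13, e+3]; minus-strand windows mirror so the
exonic/intronic counts hold in transcript orientation. Windows may overlap
for introns shorter than ~27 nt; both are still emitted. At a contig edge
the window is clipped with a warning.

An event is removed when any variant footprint intersects any window of
its defining introns — both windows of the retained/excised intron for
IR/EX, of both competing introns for A5/A3, and for ES the junction's two
sites plus the skipped exon's two flanking sites (which coincide with the
junction's sites in the common geometry, giving three distinct
junction-forming sites). Indel footprints follow VCF left-anchored
semantics: [POS, POS + len(REF) − 1]; insertions occupy one base. Variants
are additionally flagged (informationally) when they are not G→A / C→T
transitions, the signature expected of EMS mutagenesis. Only
CHROM/POS/REF/ALT are used; FILTER ≠ PASS rows can be skipped by flag.

## Position weight matrices

Matrices are trained on the annotation's own GT–AG introns over the same
13/17-nt windows used for masking — self-contained and geometry-consistent;
externally published matrices can be imported from the TSV format instead.
Per-position probabilities are (n_b + c)/(N + 4c) with pseudocount c = 0.5,
weights log₂ over a uniform 0.25 background. Sites containing ambiguity
codes are excluded from training and score NA. A site scores the sum of
its per-position weights; the normalised score maps the attainable range
onto [0, 100] so scores are comparable across matrices (a degenerate
matrix whose range is zero scores 100 by convention). Scoring is invariant
to the genomic strand encoding of a site and monotone under single-base
moves toward the consensus.

## Phosphosite statistics

PSMs collapse to canonical notations. A positioned modification at peptide
position k on a protein whose peptide starts at position p yields
protein position p + k − 1; with several master proteins, accession:position
pairs are chained in the reported master order. Modifications without an
explicit position yield, per candidate residue class, all matching peptide
positions joined by `/`, residue classes joined by `|`, and this ambiguous
dialect carries no `Phospho:` prefix. Notations are deterministic,
collision-free for distinct sites, and round-trip through the parser.
Multiple positioned marks on one peptide are chained with `+` (an
extension beyond the single-mark dialects; the generator emits only
single-mark PSMs).

Per (site, replicate), channel abundances of all PSMs are summed;
log₂(treatment/control) ratios are standardised to Z-scores using the
sample standard deviation (ddof = 1) across the replicate's site table —
within each replicate the Z-scores have mean 0 and sd 1 by construction.
Site-replicates with a zero channel sum are excluded with a warning.

Each site detected in k ≥ 2 replicates is tested for deviation from
unchanged abundance under a standard-normal model using the Stouffer
combination, Z = Σzᵢ/√k, two-sided. This is the minimal-assumption reading
of a combined standard-normal test; a one-sample t-test of the Z-scores
against zero (estimated variance) is available behind `method=
"one_sample_t"`. Direction is the sign of the mean log-ratio, and
per-replicate |z| ≥ 1.96 flags are emitted so users can apply a
replicate-consistency criterion themselves. No multiple-testing correction
gates the reported significance; BH q-values are emitted alongside.
Normalisation of reporter-ion abundances is assumed done upstream; the
channel-to-condition mapping is explicit input.

## Segregation

Genotype distributions come from exhaustive gamete enumeration with exact
`Fraction` probabilities under independent assortment. A hemizygous
transgene locus is modelled with a presence/absence allele pair (`T`/`-`),
and a reporter-positive phenotype means carrying ≥ 1 `T`. Genotype strings
canonicalise as uppercase-first alleles within loci, loci in specification
order. Goodness of fit uses the chi-square statistic, with an exact
binomial p-value for two classes (and full multinomial enumeration for ≤ 4
classes and n ≤ 200) whenever an expected count falls below 5.

## Synthetic data generator

The generator emulates the structure of a mutagenesis splicing screen:

- **Annotation/genome** — each gene instantiates one designated event type
  through two isoforms (plus, for a configurable fraction, a third
  "bystander" isoform with an alternative TSS that adds no events);
  IR genes carry 1–3 introns with the retained one drawn uniformly (or
  biased toward first introns via `first_intron_affected_prob`). Donor and
  acceptor site sequences are sampled from fixed consensus-like profiles
  with GT–AG dinucleotides (AT–AC for a configurable fraction, as
  non-canonical U2-type introns); `degrade_affected_donors` flattens the
  donor profile of affected retained introns to emulate weak 5′ sites.
- **Quantification** — gene totals are log-normal (default ln-mean 4,
  ln-sd 1, i.e. median ≈ 55 TPM); per sample the true condition PSI is
  jittered logit-normally (σ = 0.05 keeps PSI in [0, 1] with a single
  noise parameter; a Dirichlet scheme was the alternative) and isoform
  TPMs follow the implied fractions. 3 replicates per condition; 10% of
  genes carry a planted |ΔPSI| = 0.3 effect of random sign.
- **Truth tables** — per-event truth is derived from transcript-level true
  fractions, so incidental events (EX/IR duals, ES-derived A5/A3) carry
  correct true PSIs and the recovery benchmarks are well defined over the
  full extracted event set.
- **Variants** — EMS-style transitions placed inside chosen events'
  windows, plus optional deletions straddling window edges, plus variants
  placed ≥ 60 bp away from every window; which events must be masked is
  recomputed by direct interval arithmetic, independently of the masking
  module.
- **PSMs** — tryptic-like peptides (cut after K/R, length 7–25, ≥ 1 S/T/Y)
  from the generated proteins; per replicate 1–3 PSMs per site with
  log-normal channel noise (CV 20%), affected sites multiplied by the fold
  change (default 2) in the treatment channel; configurable fractions of
  ambiguous-position and multi-master records exercise all notation
  dialects. Multi-master records carry synthesized extra accessions with
  explicit peptide-start values rather than re-derivable FASTA positions.

All randomness flows through numpy's PCG64 generator; identical
configurations give byte-identical output files (fixed float formatting),
and the seed is recorded in file headers.

What the benchmarks do **not** show: the generator has no read-level
noise, no mapping or quantification bias, no isoform-ambiguous TPM
attribution, no batch effects, and its replicate noise is exactly
logit-normal — real screens will show lower sensitivity and imperfect
calibration relative to these clean conditions. Benchmark problem sizes
(~2000 events / 2000 phosphosites, 3v3 replicates) were chosen to match
the regime in which the empirical tests are well resolved while keeping
the default suite fast.

## Pipeline

`run_pipeline` executes events → PSI → differential test → masking →
features → first-intron analysis, with the phosphoproteomics branch
independent. PSI and test results are computed for all events and masked
events stay inspectable in the output table and removal log, but they are
excluded from the significant sets of the summary report (removed from the
final output). All outputs are TSV/JSON with metadata headers (version,
seed, thresholds); reruns are bitwise reproducible.
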