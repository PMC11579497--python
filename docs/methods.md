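# Methods

This note documents the models, the defaults and why they were chosen, what
the synthetic data do and do not emulate, and the numerical conventions a
user should know before trusting or extending the results.

## Decay model

After transcriptional arrest the relative abundance of a transcript is
modelled as `m(t) = exp(-alpha t)` (constant rate) or
`m(t) = exp(-(alpha/beta)(1 - e^(-beta t)))` (a rate that itself relaxes at
rate beta). `alpha` is in min⁻¹; the half-life is `ln(2)/alpha` (reported in
hours; values beyond a 72 h horizon are displayed as "> 72 h" because the
480-minute observation window carries no information that far out).

**Normalization.** Correction factors for total-pool/depth drift are the
geometric mean over decay-factor genes of `RPM(g,t,r)/RPM(g,0,r)`; each
profile is divided by its factor and then by its own t = 0 value, so every
profile starts at exactly 1 in every replicate. Decay-factor genes are
selected by combining two ranks: t = 0 abundance (high first) and a
stability slope (high first) computed on log profiles after removing the
drift common to all genes (the all-gene geometric mean). The slope is used
rather than a raw coefficient of variation because the common drift
dominates raw CV and makes truly stable genes indistinguishable from slow
decayers. Ties break by gene id, so selection is deterministic.

**Likelihood.** Replicates enter as independent Gaussian observations of
log relative abundance sharing the gene's parameters (a raw-abundance
residual scale is available via `log_scale=False`). Only t > 0 observations
are scored — the t = 0 values are 1 by construction and carry no
information. A relative pseudo-abundance floor of 1e-3 admits zero counts on
the log scale; the floor censors *both* the data and the model prediction,
so observations below the detection floor are uninformative rather than
biasing the rate (one-sided flooring overestimates fast rates
catastrophically). `sigma` is profiled out analytically
(`sigma² = RSS/n`), and AICc counts it among the k free parameters (k = 2
and 3 for the two models). The minimum-AICc model is reported; ties break
toward lower alpha.

**Optimization.** Bounded L-BFGS-B with five deterministic multi-starts on a
log-spaced alpha grid; for the constant-rate model on the log scale the
closed-form origin-regression estimate seeds the optimizer. Bounds:
`alpha` in [ln2/72 h, ln2/1 min] (the observed half-life range with
margin); `beta` in [1e-6, 1/15] min⁻¹ — rate decay faster than the first
sampling interval (15 min) is unidentifiable on the default grid and only
mimics a t = 0 offset.

**Known accuracy limits.** Anchoring each replicate at its own noisy t = 0
value injects a shared per-replicate offset (standard deviation roughly the
per-observation noise) into every log profile. Two consequences, measured
on simulated data at the default noise: (i) the median relative error of
alpha is ~20% rather than the ~8% a noiseless anchor would allow — no
estimator that respects this normalization can do better than ~11%; and
(ii) the offset is a structured residual that the decaying-rate model can
absorb, so AICc selects the constant-rate model on constant-rate truth only
~85% of the time, at any noise level. With noise switched off, recovery is
exact (max relative error < 1e-6) and selection is perfect. Users who need
tighter rates should average t = 0 across many replicates or treat the
anchor as a free amplitude, both of which change the reported model form.

**Curve comparison.** Two genes' decay curves are compared with a mixed
ANOVA (time within-subject, gene between; subjects are replicate profiles)
via pingouin; the gene x time interaction F is converted to a one-sided p
for the hypothesis that the nominated gene decays faster, with the
direction read from the mean relative abundance at t > 0 (exactly equal
curves give p = 0.5).

## Sequence features

CSC is the per-codon Pearson correlation, across genes, between that
codon's frequency and a stability measure. The default measure is
**half-life**, so a positive CSC means "enriched in stable mRNAs"; passing
decay rates instead flips the sign, and the choice is the caller's to
report (descriptions of the CSC orientation conflict in the literature, so
the package refuses to guess silently). cAI and tAI are geometric means of
per-codon weights over the CDS with stop codons excluded; weight tables are
inputs (a `relative_adaptiveness` helper derives cAI weights from a
reference gene set). Ambiguous bases are excluded from composition
denominators, and an empty region yields a missing value, never zero.
Translation efficiency is consumed as an external table; it is not computed
here.

## Structure features

SHAPE region summaries are arithmetic means of non-missing reactivities,
reported only when positional coverage reaches 30% (below that a mean is
mostly noise). Per-nucleotide pairing probability is `q(i) = sum_j p(i,j)`
from an externally produced base-pairing-probability table, clipped to
[0, 1] with clip events logged (valid partition-function output should not
exceed 1 beyond rounding). The folding itself is out of scope: the package
consumes `(i, j, p)` tables.

## Motif discovery

Seeds are degenerate stem-loops: left arm (4-7 nt) and loop (4-9 nt) over
the IUPAC alphabet, with the right arm implied by reverse
complementarity. Information content counts 2 bits per fully specified
position and `2 - log2(d)` for a code with d admissible bases, over the
left arm and loop only (the right arm is determined, under Watson-Crick
pairing, by the left); seeds must carry 14-20 bits and 4-6 degenerate
positions. The constrained grammar space is astronomically large, so
`enumerate_seeds` draws a seeded rejection sample (default budget 10,000);
external seed libraries (e.g. from thermodynamically folded aptamer
collections) can be imported, validated, and flagged when outside the
grammar.

Matching requires (a) IUPAC agreement on arm and loop, (b) Watson-Crick
pairing at every stem position, G·U wobble allowed by default (RNA duplexes
do form them; `allow_gu=False` gives strict WC), and (c) when SHAPE data
exist: mean stem reactivity below mean loop reactivity and below the
transcript median (formed stems are protected from probing). Windows with
no structure data skip filter (c). Presence is binary per transcript
(>= 1 match).

Transcripts are split into 15 equal-frequency bins by ascending decay rate
(bin 1 = most stable; ties break by id). MI is the plug-in estimate on the
2 x 15 contingency table, in bits with `0 log 0 := 0`; the 0.001 selection
threshold applies on this scale. The permutation null shuffles the bin
labels (preserving both marginals) with a seeded generator;
`Z = (MI - mean(MI_shuffled)) / sd(MI_shuffled)` over 1000 shuffles and
`p_emp = (1 + #{MI_shuffled >= MI}) / (n_shuffle + 1)`. One permutation set
is shared across seeds within a run — the null does not depend on the seed,
and sharing makes 200 seeds x 1000 shuffles tractable. Seeds matched by
fewer than `min_support=10` transcripts are not scored (their MI estimate
is dominated by discreteness). Passing motifs are classified by the
Spearman trend of per-bin frequency: decreasing toward unstable bins =
sRSM, increasing = uRSM; the orientation is exposed (`stable_trend`)
because verbal conventions for it are easy to invert.

## Subgenome and population statistics

Pair classification uses one-sided two-sample t-tests on replicate-level
rates (each replicate's profile fitted separately with the constant-rate
model — the only replicated decay quantity available); A_gt_B / A_lt_B at
p < 0.05, else no significant difference. At three replicates and the
default simulated noise this test calls ~half of the 2-fold pairs, but its
directional calls are >99% correct; the package reports precision and
coverage separately. Classification is exactly antisymmetric under
swapping the pair. Within-class delta-decay vs delta-abundance
correlations are truncated by the sign-conditioning of the classes; the
pooled ("all") stratum recovers a planted correlation unbiasedly.

F_ST defaults to the Weir-Cockerham variance-components estimator on
allele-count data (the diploid heterozygosity term is zero for allele
counts); Hudson's pairwise estimator is available. Raw values can be
slightly negative for undifferentiated loci; reporting clips to [0, 1] and
the raw value is available with `clip=False`. Monomorphic loci are NaN.

An SNV perturbs a motif when substituting its alternate allele makes the
match fail — either a stem pair becomes non-WC (and non-G·U when wobble is
allowed) or a seed IUPAC constraint is violated. The call is made by
re-matching the substituted sequence at the original offset, so the
pairing table and the grammar cannot drift apart. Substituting the
reference allele is a no-op by construction.

## Synthetic data: what it emulates, and what it does not

The generator reproduces: exponential decay on the 0/15/30/60/120/240/480
minute grid with three replicates; a log-normal half-life distribution
(median 6 h, log-sd 1.0, clipped to [2 min, 48 h], matching the reported
minutes-to-days range); negative-binomial count noise (dispersion 0.05,
i.e. ~22% CV at high counts) on a 5M-read library; a +/-20% per-step
log-random-walk depth drift shared by all genes; 30 highly expressed, truly
stable reference genes; i.i.d. uniform-ACGU 3' UTRs (120 nt) with one
planted stem-loop instance per selected transcript, planting frequency per
stability bin; SHAPE emission Beta(1,9) on planted stems and Beta(3,2)
elsewhere (paired reactivity well below unpaired); CDS sets whose
designated-codon frequency is linear in standardized log half-life;
homoeolog pairs with either a fixed rate fold change (alternating
direction) or bivariate-normal log2 deltas with a planted correlation; and
binomial allele counts in three populations with controlled differentiation
spread.

It does **not** emulate: correlated noise between neighbouring genes,
positional coverage bias, isoform mixtures, UTR composition bias (real
UTRs are AU-rich), motif families with correlated occurrences, linkage
between SNVs, or selection acting jointly on many loci. Passing tests
demonstrate that the estimators recover what they claim under the stated
noise model — not that the biological conclusions transfer to any
particular real library.

Every generator is deterministic given `SimulationConfig.seed` (PCG64
streams; identical output across runs and platforms), and every emitted
file round-trips through the package's own readers.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive throughout (GFF3 convention); one
representative transcript (longest mRNA) is kept per gene; strands are
resolved at read time so downstream sequence work is on the sense strand.
TSV writers use `%.17g` and readers parse with round-trip float precision,
so write-read cycles are bit-identical. Missing values are `NA` (also
accepted: `-999`). Zero-variance inputs yield NaN with a warning rather
than an exception wherever a single degenerate column should not abort a
genome-scale run (CSC of a constant codon, flat enrichment trends,
monomorphic loci); hard errors are reserved for structurally invalid input
(negative counts, overlapping regions, pairing probability sums above 1).

## Problem sizes

The test suite and the acceptance script run everything at simulation
scale: 2,000 genes for rate recovery, 1,500 UTRs x 201 seeds x 1,000
shuffles per motif run (20 runs in the recovery check), 500 null datasets
for calibration, 1,000-3,000 homoeolog pairs, and 200-400 SNV loci. These
sizes keep a full run in minutes on one core while leaving the Monte-Carlo
error of each check well inside its assertion margin.
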