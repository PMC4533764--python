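# Methods

## Scope and data model

`stressomics` analyses a two-stressor dose-response study: cultures stressed
with butanol (30/60/90 mM for low/med/high) or butyrate (30/40/50 mM), each
compared against an unstressed control, with iTRAQ 4-plex proteomics at
15/45/75 min and transcriptomes from RNAseq (15/30/60/75 min) and
microarrays.  The protein layer is a ratio-to-pool table: every sample is
quantified against a pooled reference mixed from equal protein amounts of
all samples of that stress experiment.  A protein missing from a sample is
an *absent* cell, never a zero: detection is a first-class concept and
drives the exclusive-detection categories.

All genomic intervals are 0-based half-open internally; GFF3's 1-based
closed convention is converted at the file boundary only, so interval
arithmetic is uniform everywhere else.

## Differential proteome

Ratios are log2-transformed and median-centred per sample — a deliberately
simple stand-in for instrument-level bias correction.  Each stress level is
tested against the control with the SAM statistic

    d_i = (x̄_stress,i − x̄_control,i) / (s_i + s0)

where `s_i` is the pooled standard error and `s0` an exchangeability
constant.  `s0` is selected Tusher-style (the value, scanned over quantiles
of the `s` distribution, that minimises the coefficient of variation of the
d-statistic spread across 100 `s`-quantile windows); a `median(s_i)` mode is
available for degenerate inputs.  Significance uses label permutations:
exhaustive when at most `n_perm` (default 1000) distinct assignments exist,
otherwise `n_perm` sampled with the run seed.  The calling threshold δ is
the smallest value whose estimated FDR — the **average** number of
permutation calls beyond the cutpoints divided by the number of real calls —
is at or below the 5 % target.  The average is used rather than the median
because with few exact permutations (twenty at 3 vs 3) the median false-call
count collapses to zero and under-estimates the FDR; the mean keeps a floor
of roughly `2·k/P` (identity and complement assignments always reproduce the
observed tails), which makes the caller correctly return an empty set on
null data.  π0 is fixed at 1 (conservative).

Classification is per stress level.  "Detected" in a condition means
quantified in ≥ 1 of its samples (a strict ≥ 2 mode exists).  Proteins
detected under both conditions are `up`/`down` when the SAM call passes and
the linear fold change (ratio of replicate-mean ratios; the mean matches
SAM's x̄) is ≥ 2 or ≤ 0.5, else `nonsig`.  Exclusive detections cannot carry
a fold change and are exported with sentinel display values +6.0
(stress-only) and −5.0 (control-only) — the extreme up/down folds of the
display scale — so heat-map exports remain a single numeric matrix.

## Transcript layer

Size factors are median-of-ratios: `s_j = median_g(k_gj / gm_g)` over genes
with non-zero counts in every sample, where `gm_g` is the geometric mean
across samples.  Fold changes are `log2((mean_stress + c)/(mean_control + c))`
with pseudocount `c = 1` normalised unit, keeping censored genes finite.
Microarray inputs are already log-ratios and bypass size factors; their DE
stand-in is a one-sample t-test against zero with BH adjustment and the same
fold filter.  The RNAseq DE stand-in is a label-permutation test on the mean
log2 difference with BH adjustment.  Exact permutation p-values are discrete
(minimum 3/(P+1) for a strong two-sided effect, since the identity and
complement assignments always match), so at small replicate numbers BH can
only reject when several genes carry true effects — the pipeline treats
transcript DE as an upstream given, and externally computed tables can be
slotted in.

Percentile abundance ranks ("blue plots") are `100·(rank − 1)/(n − 1)` with
averaged ties, computed per sample and averaged over a condition's samples
(rank-then-average, not average-then-rank), putting the least abundant
feature at 0 and the most abundant at 100.  Ranks are invariant under any
strictly monotone transform of abundances.  The protein layer is ranked
from reporter-intensity abundances, not ratio-to-pool values: the pooled
denominator is gene-specific, so ratios carry no between-gene abundance
information.

## TSS, 5′UTR, leaderless transcripts

The TSS caller scans the window up to 300 nt upstream of each operon-leading
gene's start codon (capped at the neighbouring gene boundary minus 1 nt, to
avoid run-through signal).  A candidate position needs TEX+ coverage
≥ 10 reads, a step ratio `(cov[p]+1)/(cov[upstream]+1) ≥ 3`, and — when a
TEX− library is present — TEX+/TEX− enrichment ≥ 2 (TEX degrades processed
5′-monophosphate ends, so primary starts are enriched).  The winner is the
maximal step ratio, ties broken toward the start codon: the conservative
choice for leaderless calling.  The 5′UTR length L is the strand-aware
distance from the TSS to the first CDS base; a transcript is leaderless when
`L ≤ leaderless_tol` (default 5 nt: single-nucleotide TSS calls are noisy,
and a ≤ 5 nt "UTR" cannot host an SD motif given the minimal 3-nt spacer;
the tolerance is configurable down to the strict L = 0 definition).
Condition-dependent switches are reported whenever the leaderless status of
a gene differs between control and a stress condition.

## RBS strength

The score is an exhaustive search over the 21 nt immediately 5′ of the start
codon: SD-like motifs (`AGGAGG`, its exact subwords down to 3 nt, and
single-mismatch 5/6-mers in lower tiers) crossed with spacer bins
{3–4, 5–10, 11–15}, where the spacer is the distance from the motif 3′ end
to the start codon.  The fixed lookup table is calibrated at its endpoints —
perfect `AGGAGG` at the optimal spacer scores 12.87, a motif-free window
scores the floor −18.92 — with the intermediate published bin values
(12.38, 12.09, 11.11, 9.25, 7.68) populating adjacent tiers and invented
low-tier values below them; the table is monotone in motif quality at fixed
spacer.  This reproduces the score *scale* of a Prodigal-style RBS model
without retraining Prodigal; genes with no motif (or insufficient upstream
sequence) take the floor score, following the convention that "no RBS" is
the weakest RBS.  The score is a pure function of the 21-nt window, hence
strand-symmetric by construction.

## Integration and screens

Discordance (the signature of post-transcriptional regulation) fires when
(1) the protein is up or stress-only while the reference mRNA is down,
(2) the protein is down or control-only while the mRNA is up, or (3) an
exclusive-detection protein has non-significant but well-expressed mRNA
(rank ≥ 50; the threshold operationalises a qualitative "good mRNA levels"
criterion).  The microarray is the default reference transcriptome for
differential calls and RNAseq for abundance ranks; both are configurable.

The hypothesis screens: H1 (chronic translational inefficiency) requires
mRNA rank ≥ 80 and protein rank ≤ 20 under stress *and* control; H2
(stress-specific silencing) requires, at medium/high stress, mRNA
differentially up with the protein down or undetected; H3 (high translation
efficiency) requires the protein differentially up with both transcript
datasets non-significant, annotated with `long_utr` (above the genome median
5′UTR) and `strong_rbs` (above the genome mean score).  The revised
percentile screens use strict inequalities: mRNA rank < 60 with protein
rank > 80 (protein up/stress-only), and the mirror with the thresholds
swapped (protein down/control-only, or protein undetected).  H3 and the
mirror screen are disjoint by construction (they require opposite protein
categories).

Pearson correlations between layer fold changes are computed per category
for `up`/`down`/`nonsig` only — exclusive detections have no fold change and
hence no variance.  COG enrichment is a one-sided Fisher exact test per
letter and direction against the rest of the categorised proteome, BH at
5 % across letters × directions.

## The synthetic-data generator

The generator emulates the study's structure, not its content: a single
contig with operons of geometric size (mean 2.5), gene lengths 300–900 nt,
a planted TSS `true_utr_len` upstream of each operon-leading start codon,
and a planted `AGGAGG` at spacer 7 for every gene that is leadered in at
least one condition.  Leadered UTRs are lognormal with median 42 nt
(σ = 0.6), clamped to [13, 250] so the SD motif fits inside the UTR; 20 % of
leading genes are leaderless, and 5 % switch leaderless status between
control and stress (in both directions, disabled at the degenerate fractions
0 and 1).

Each gene carries one expression class, shared across both stressors and all
three stress levels, because baseline abundance and translation efficiency
are physical properties of the gene common to the two experiments.  Default
fractions: conc_up 0.10, conc_down 0.10, disc_protein_up 0.06,
disc_protein_down 0.08, stress_only 0.10, control_only 0.08, nonsig 0.48 —
chosen so the planted discordant classes (disc_protein_down plus the
exclusive detections, 0.26 of the genome) sit inside the 23–31 % discordant
range the pipeline is meant to resolve.  Effect sizes are constant across
levels: concordant classes move mRNA ±3 log2; disc_protein_up boosts
translation 8-fold on flat mRNA (the H3 pattern); disc_protein_down pairs
mRNA +2 log2 with a 16-fold translation loss.  Exclusive-detection classes
are implemented through the censoring mechanism: stress_only genes have
constitutively low translation efficiency (−8 log2) rescued 2^8-fold under
stress; control_only genes lose 2^7-fold under stress.  Their baselines are
drawn from a higher, tighter stratum (N(11, 0.8) log2) than nonsig genes
(N(8, 2.5)) so that (a) "despite good mRNA" genuinely holds — their mRNA
ranks sit above the genome median — and (b) the planted label is
identifiable: a strong planted down-effect on a low-abundance protein would
be censored into exclusive detection and the label unrecoverable.  Effect
classes use N(10, 1.5) for the same identifiability reason.

Counts are negative-binomial (shared dispersion 0.05, gamma-Poisson
sampling, lognormal per-sample size factors); microarray values are the true
mRNA log2 fold change plus N(0, 0.25); protein abundance is the mRNA
abundance times efficiency, boost and lognormal noise (0.25 log2).  iTRAQ
is simulated directly at the protein-ratio level — the analysis consumes
protein ratios, so peptide/spectrum simulation would add nothing the
pipeline can see.  Detection is abundance-quantile censoring: in each
sample the bottom 15 % of protein abundances are absent, the simplest
mechanism that produces exclusive-detection patterns.  Coverage tracks put
Poisson(depth) reads on the transcribed strand from the planted TSS to the
operon end over Poisson(0.5) background, with the first 5 nt downstream of
the TSS multiplied by the TEX enrichment factor (default 5) in the TEX+
library.  Coverage depth is held uniform across operons: the dRNA-seq
tracks exist to position TSSs, while expression differences live in the
count tables.

What the generator does **not** emulate: read-level sequencing artefacts,
peptide-to-protein rollup and identification FDR, per-gene NB dispersion,
time-resolved dynamics (effects are constant across time points), internal
and antisense TSSs, and operon structures that differ between conditions.
Passing recovery tests therefore demonstrate that the screens are wired
correctly and calibrated under the planted statistical structure — not that
they would achieve the same rates on real MS/RNAseq data, whose headline
counts depend on instrument depth and identification pipelines.

## Problem sizes and numerical choices

Validation runs use 300 genes, 3 replicates, 3 (proteome) or 4 (RNAseq)
time points and 1000 permutations; the test suite uses 80–300 genes.  Seeds
are threaded everywhere (`numpy.random.default_rng` with derived seed
sequences), and a fixed seed reproduces byte-identical generator output and
pipeline summaries.  Degenerate inputs fail loudly: zero-variance SAM input
with `s0 = 0` instructs a mode change, all-absent samples cannot be
median-centred, counts matrices reject negatives and non-integers, and the
bedGraph reader applies a documented last-wins rule to overlapping intervals
with a logged warning.

## Known limitations

* The transcript DE stand-ins (permutation test, one-sample t-test) are
  intentionally simple; dispersion-shrinking NB models will differ at low
  counts and small replicate numbers.
* The RBS table reproduces a published score scale, not a trained model;
  scores are comparable within this package, not to external Prodigal runs.
* The discordance clause set is one reading of a qualitative definition;
  its thresholds (`fold 2`, `good mRNA rank 50`, percentile 60/80) are
  surfaced in the configuration rather than asserted as the only choice.
* TSS counts from real dRNA-seq depend on read depth and the upstream
  aligner; the caller here is validated on planted coverage only.
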