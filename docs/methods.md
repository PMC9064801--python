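# Methods

`viroconverge` re-implements, as a tested pipeline, a longitudinal analysis of
the preterm-infant gut virome anchored to the onset of necrotizing
enterocolitis (NEC): per-sample contig abundances are RPK-normalized and
noise-floored, beta diversity is computed within and between infants, every
sample is re-timed as days-before-event, and sliding windows over that axis
test whether case infants' viromes converge (become mutually more similar)
shortly before onset. A discriminant screen names the contigs driving the
convergence, trajectory and mixed-model stages characterize them, and a
bacterial 16S side (rarefaction + UniFrac) runs the same window machinery on
the genus level. Because the real cohort is not redistributable, the package
ships a synthetic-cohort generator with planted, labelled effects; every
claim the pipeline makes is tested against that planted truth.

## Normalization

Counts are converted to RPK as
`(scale_reads / total_qc_reads) x reads / (length_bp / 1000)` with
`scale_reads = 79,000` (the study's fixed reference depth; it cancels out of
all compositional analyses) and then noise-floored: cells below 0.5 RPK are
set to zero. The floor is applied after length division, matching the order
in which the normalization is defined. Presence/absence — the basis of
Sorensen dissimilarity and of all prevalence computations — means "survived
the floor". Shannon diversity uses natural logs (the ecology-package default)
with a switchable base.

## Beta diversity

Weighted Bray–Curtis, Sorensen and Hellinger are implemented directly from
their defining formulas and are cross-checked in the test suite against naive
double-loop oracles (1e-12) and against the classical identity
Sorensen = Bray–Curtis on 0/1 data. For "log-transformed RPK" the Hellinger
path uses `ln(1 + x)`: the offset is not fixed by the analysis being
reproduced, and zero RPK must remain finite; the transform is a config knob.
Pairs undefined because both samples are empty are reported missing (NaN),
never zero — zeroing would fabricate similarity.

UniFrac (bacterial side) follows the standard Lozupone definitions: a
postorder pass propagates per-sample presence or relative abundance to every
branch; unweighted UniFrac is unique branch length over spanned branch
length, weighted UniFrac is `sum b |p_A - p_B|`, optionally normalized by
`sum b (p_A + p_B)`. Both variants are verified against an explicit
branch-partition enumeration oracle and against scikit-bio. Note one
deliberately documented consequence of the standard definition: two samples
on sibling leaves share their ancestral branch, so e.g. on
`((A:1,B:1):1,C:2)` the pair {A} vs {B} has distance 2/3, not 1.

## Event anchoring, pairing, windows

Days-before-event = event day-of-life − sample day-of-life; controls borrow
their matched case's event day. Post-event samples are flagged and excluded.
Matched sample pairing selects, for each case sample and each matched
control infant, the control sample minimizing |Δ day-of-life| within
±3.5 days, ties broken toward the earlier sample, each control sample used
at most once per case-sample pass.

Windows are half-open `[k, k + 7)` days-before, advancing in 2-day steps up
to a 25-day lookback; the half-open convention puts day-0 samples in the
"7–0 d" window. Per window, the between-case multiset holds all cross-infant
case sample dissimilarities, the between-control multiset likewise over
*paired* control samples (an all-samples option exists), and a two-sided
Mann–Whitney U compares the two. Medians carry distribution-free
(order-statistic) 95% confidence intervals. Same-infant pairs never enter the
multisets; multiple samples of one infant in one window all contribute
cross-infant pairs (no collapsing rule is imposed). Kruskal–Wallis with a
Dunn post-hoc (Bonferroni by default, BH switchable) compares one group's
dissimilarities across windows.

A known limitation, documented on purpose: the per-window Mann–Whitney is
computed over pairwise dissimilarities, which are not independent (pairs
share samples and infants). The test is therefore mildly anti-conservative
under the null; the synthetic null experiments in the test suite measure the
realized false-positive rate rather than assuming the nominal 5%.

## Discriminant screen

The LDA-effect-size screen labels case samples *late* (`[0, 10)` days-before)
or *early* (`[10, 46]`), then (1) drops contigs detected in <10% of the
samples analysed, (2) total-sum scales each sample to one million,
(3) gates per-contig Kruskal–Wallis at α = 0.05, (4) scores survivors with a
bootstrapped effect size — over 30 seeded subsamples of 2/3 of each class,
the average of `(|w_i · Δm_i| + |Δm_i|) / 2`, where `w` is the unit-norm
two-class LDA coefficient vector (lsqr solver, auto shrinkage — the class
covariance is singular when features outnumber samples) and `Δm_i` the
class-mean difference of contig i, floored at 1 and log10-scaled — and
(5) keeps scores ≥ 2.0, assigning the class with the larger mean. The
boundary day itself belongs to the early class (the half-open convention),
which the output flags. The published tool's within-class (subclass) stage is
omitted: this design has no subclasses. The same algorithm applied to
control samples, anchored to the matched case's onset, gives the
control-side screen.

## Trajectories

Samples within 25 days before the event are binned into five 5-day blocks.
Per contig, group and block: prevalence is the percentage of the block's
samples with a detection; abundance is the RPK mean over all the block's
samples, zeros included. Empty blocks are missing, not zero — a mean over
zero samples is undefined. A Friedman test treats contigs as matched
subjects across blocks (the only structure yielding repeated measures), with
a Dunn post-hoc on within-subject ranks. Slopes are OLS of block values on
signed block midpoints (−22.5 … −2.5 days), so a positive slope means
increase while approaching the event; missing blocks are omitted pairwise.

## Bacterial side and interactions

Genus tables are rarefied to 2,500 reads by exact multivariate-
hypergeometric subsampling (seeded; samples below depth are dropped and
listed), then compared with UniFrac; normalized weighted UniFrac is the
default reported variant. Virus–bacteria association fits, per (contig,
genus) pair within one group, a random-intercept linear mixed model
`log(1 + TSS contig abundance) ~ genus relative abundance + (1 | infant)`
via statsmodels MixedLM (REML), with a 10% prevalence gate on both feature
sets. Wald p-values are Benjamini–Hochberg adjusted across all pairs tested
within the group; significance requires both p < 0.05 and q < 0.25. Only a
random intercept is fitted — with 4–8 samples per infant, random slopes are
unidentifiable. Whether predictors should be log or arcsine-sqrt transformed
is genuinely open; genus relative abundance (untransformed) is the default
and the response transform is config. The full-pipeline orchestrator caps
the association stage at the 20 strongest discriminant contigs
(`max_association_contigs`) because the stage is quadratic in features.

## Ordination and global tests

PCoA is classical metric MDS: Gower double-centering and symmetric
eigendecomposition; negative eigenvalues (non-Euclidean input) are reported
and their axes dropped, with a 1e-10 tolerance separating zero from
negative. PERMANOVA supports continuous covariates (postmenstrual age) as a
single centered regression column — the pseudo-F is formed from the
hat-matrix projection of the Gower-centered inner-product matrix — and
categorical covariates as dummy designs (cross-checked against scikit-bio's
categorical PERMANOVA). p-values come from seeded label permutations,
`p = (1 + #{F* >= F}) / (1 + n_perm)`, with exhaustive enumeration available
at small n. Permutations are unstratified by default (whether the original
analysis stratified by infant is unknown); repeated-measures users should
interpret accordingly. The Mann–Whitney wrapper uses exact enumeration when
both groups have n ≤ 8 without ties, else the tie-corrected normal
approximation; the two-sided Fisher test sums hypergeometric point
probabilities ≤ that of the observed table, which reproduces the cohort
table's printed values (0.16, 0.21, >0.99). The alpha-diversity trend model
is a random-intercept mixed model of Shannon/richness on postmenstrual age.

## Synthetic cohort

The generator emulates the study conditions: 9 cases and 14 matched controls
(five cases carry two controls), gestational ages 23–27 weeks, event ages
near 31 weeks postmenstrual, 4 (4–6) samples per case infant and 7 (6–8) per
control, sequencing depths log-normal around a median of 412,905 reads
(IQR-matched sigma 0.44), 2,000 contigs with length distribution matched to
an assembly catalog (min 800 bp) and family labels drawn so the expected
profile is unclassified-dominated (~85%).

Community model, per infant: a heavy-tailed weight vector (Gamma(0.05)
components — a symmetric Dirichlet once normalized, concentration chosen for
strong individuality), masked to a per-infant repertoire (each infant can
carry ~55% of the pool) and truncated at a fixed absolute cut several times
above the RPK detection floor. The cut makes *which contigs an infant
carries* a stable property of the infant rather than of its total community
mass; without it, heavy-tailed mass fluctuations couple every contig's
detectability to the sample's dominant contigs and inject large infant-level
noise into presence-based dissimilarities. Per sample, a Markov presence
mask (persistence 0.8, stationary occupancy 0.5) adds temporal turnover, and
counts are drawn multinomially at the sample's depth, so column sums equal
the drawn depths exactly.

Planted effects (all named in the truth labels, all switched off in null
cohorts): 137 signature contigs occur at 5% baseline everywhere and, in case
samples inside the 10 days before the event, ramp linearly to 60% occurrence
at day 0 with an 8x abundance lift; 11 early contigs occur at 50% in the
case antecedent period and decay toward the event; 100 control-late contigs
ramp with absolute age in a random 60% subset of control infants — the
subset keeps each contig's late/early contrast strong while the set shared
by any two control infants stays small, so between-control dissimilarity
stays flat over the windows. Case sampling days are spread so the near-event
windows and the antecedent period are all populated (two draws inside the
window, two before it); control days mirror their case's days ±2 days so the
matched pairing is well populated. The bacterial table gives case infants a
shared low-dispersion profile (controls are individually drawn), and four
signed contig–genus couplings multiply the genus weight by
`exp(sign x 0.45 x z)` with z the standardized log viral signal, in cases
only.

What the generator does **not** emulate: read-level noise and mapping
artifacts, contig mis-assembly, chimeric families, strain replacement,
antibiotic perturbations, irregular gaps in sampling, or any correlation
between the viral and bacterial sides beyond the planted couplings. Passing
tests therefore demonstrate that the pipeline detects the planted structure
at realistic scale and rejects it in its absence — not that the biological
effect sizes of any real cohort are reproduced.

## Problem sizes and numerical choices

The default generator (2,000 contigs, ~140 samples) keeps every stage within
seconds on one core; the test suite's replicated null experiments use 10–20
generator seeds and 200 replicates for the type-I error checks, sizes chosen
so the whole suite stays interactive. Tie-breaks and degenerate inputs:
identical-value groups short-circuit Kruskal–Wallis/Friedman to statistic 0,
p 1; pairing ties go to the earlier sample; eigenvalues within 1e-10 of zero
are zero; distance matrices must be symmetric within 1e-12 with zero
diagonal; manifest hashing normalizes floats to 10 significant digits so
end-to-end determinism is testable.
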