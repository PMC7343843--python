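# Methods

This note records the models behind each `asmqc` stage, the parameters
that matter, the numerical choices, and what the synthetic-data recovery
tests do and do not demonstrate.

## Duplicate-exon scan

**Model.** A collapsed-haplotype assembly error duplicates a ~kb sequence
in tandem; when exons overlap the repeat, annotation acquires two nearly
identical exons a short distance apart. The scan therefore considers
same-contig, non-overlapping exon pairs with an interval gap ≤ 5,000 bp
(inclusive; sequences compared as their plus-strand projections, same-gene
pairs not excluded) and flags pairs whose length-normalized global
alignment score exceeds 4.8, a near-identity criterion (identity scores
exactly 5 under NUC.4.4; each substitution in an L-column alignment costs
9/L, so 4.8 corresponds to roughly > 97.8% identity).

**Scoring.** The raw score is the optimal Needleman–Wunsch score under
NUC.4.4 with affine gaps costing 10 + L for a run of L gap columns
(implemented as Biopython `PairwiseAligner` open −11 / extend −1); the
normalization denominator is the total number of alignment columns, gaps
included. Gap penalties are a package choice — the identity anchor of 5.0
is penalty-independent, and with gaps this expensive relative to the −4
mismatch, near-identical copies align gap-free. Among co-optimal
alignments the first reported one defines the denominator; the anchor and
threshold comparisons are unaffected. Strict inequalities are used at
every gate (> 4.8, > 50% coverage, e-value < 10⁻¹⁰).

**Significance pre-filter.** Candidate pairs must share a local alignment
covering more than half of the shorter exon with Karlin–Altschul e-value
E = K·m·n·e^{−λS} below 10⁻¹⁰. The pre-filter uses *ungapped*
Smith–Waterman scores: Karlin–Altschul theory is exact for ungapped local
alignment, whereas under the cheap gap scheme above, gapped local scores
of unrelated 300-bp sequences reach 110–240 and would make any
ungapped-λ e-value gate vacuous (measured: 18% of random pairs would
"pass"; with ungapped scoring, 0 of 1,000 do, while true tandem copies
still align end-to-end). λ is solved numerically for the +5/−4 scheme at
uniform base composition (λ ≈ 0.1915); K is set to the conservative bound
1, which only inflates e-values — the decision gates sit orders of
magnitude from the boundary on both sides, so the precise K is
immaterial. The search space is m·n, the product of the two exon lengths.

**False chimers.** A gene model is a false fusion when its 5′ and 3′
parts hit two distinct reference genes adjacent in reference gene order
(rank difference exactly 1). The proposed split is the midpoint of the
query interval between the hit blocks — reference coordinates are
abstracted away here; overlapping blocks make the gene unsplittable and
route it to manual review.

## Sex-linkage assignment

**Statistic.** ρ = (med_f/G_f) / (med_m/G_m), with contig medians and
genome-wide medians G computed per individual after retaining every
100th position and discarding retained positions above that individual's
99.9th depth percentile (computed genome-wide over retained positions).
Genome medians are computed after subsampling and trimming. ρ is
invariant to global depth rescaling; expectation ~1 for autosomes, ~2 for
X-linked contigs in an XY system. Including X positions in the male
genome median biases ρ slightly downward; as in the motivating analysis
this is documented, not corrected — on the standard simulation the median
X-contig ρ computes to 1.90.

**Filters before fitting.** Contigs with male median < 5×, female median
< 2×, fewer than 100 retained positions, or a median above
Q3 + 1.5·IQR of the contig-median distribution in either individual are
excluded with a recorded reason.

**Mixture and call rule.** A two-component, equal-variance 1-D Gaussian
mixture is fit to the ρ values by EM, deterministically initialized at
means (1, 2) — the biological expectations, which also fixes component
identity and avoids label switching — with equal weights and the sample
SD; convergence is a log-likelihood gain < 10⁻⁸ and the trace is
monotone. A contig's candidate class is the component with the larger
posterior; the call is confirmed only if the *other* component's
two-sided tail probability at ρ is < 0.01. If ρ is implausible under
both components, the contig remains unassigned rather than force-called
— the conservative reading of a "p < 0.01 confidence" rule. Degenerate
inputs (fewer than 4 values, zero spread, a component losing all
responsibility) raise explicit errors.

**Limitations.** Because contig medians are integers, short contigs
(few retained positions) produce discretized ρ values that can fall
several σ̂ from both component means and stay unassigned; with ≥ 10⁴
retained positions per contig the medians stabilize and ≥ 99% of
non-filtered contigs are recovered (measured 298/300, zero X↔autosome
confusions). Y-chromosome detection and dosage compensation are out of
scope.

## Pool-seq window diversity

**Estimator.** For pooled sequencing of n haploids at read depth r, a
site segregating in the pool may be missed by the reads. The Watterson
denominator is corrected per site:

    f(r, n, b) = Σ_{i=1}^{n−1} (1/i) · P(b ≤ Bin(r, i/n) ≤ r − b)

derived from the neutral spectrum E[ξ_i] = θ/i and binomial read
sampling; b is the minor-allele read threshold. At b = 1 this equals
E[a(K)], the expected harmonic number of the count K of distinct pool
haploids among the r reads (verified in tests against an independent
occupancy-distribution enumeration). Per 10-kb window,
θ̂ = S / Σ_{analyzed sites} f, with S the number of analyzed sites whose
minor allele has ≥ b reads.

**Defaults.** Analyzed sites have 4 ≤ r < 250 (upper bound strict);
b = 2 by default as an error guard (b = 1 available and gives the clean
closed form); pool size 50; windows anchored at coordinate 0 of each
contig, with windows of < 9,000 analyzed positions reported but dropped
from summaries. Base-quality filtering is assumed applied upstream when
the count table was produced. Factors are computed per unique depth and
cached; depths above 10⁴ are rejected rather than risk numerical
trouble.

**Calibration.** Against the neutral simulator the grand-mean window
estimate recovers θ ∈ {0.00122, 0.005, 0.0224} within 5% at pool sizes
10–100 (tested), mirroring the estimator's documented insensitivity to
the assumed pool size. Per-class summaries report the mean and SEM of
retained window estimates; a single-window class has undefined SEM
(reported as missing).

**Hysteresis segmentation.** Any ordered per-window rate track (indel
rate, θ̂, ...) is segmented with two thresholds: a region opens at the
first window of a run of ≥ 5 consecutive windows with rate > 0.005 and
closes at the window preceding a run of ≥ 5 consecutive windows with
rate < 0.001 (closing run excluded; an open region closes at the contig
end). Intermediate rates neither open nor close, making regions robust
to local dips. Regions are emitted as half-open bp intervals; the scanner
is verified exactly against an independently written brute-force
reference on thousands of random tracks. How a particular rate track is
produced is outside the package's scope — segmentation is generic.

## Local-ancestry HMM

**Model.** Two hidden states (C and H source ancestries) per
ancestry-informative SNP (AIM); stationary first-order chain with a
constant per-adjacent-AIM switch probability τ ∈ (0, 0.5) — transitions
are not distance-scaled, as no recombination map exists for a de novo
assembly and AIMs are dense. The emission at AIM i is the probability of
the observed assembly allele under each source: since the reference
allele *is* the assembly allele, these are its Laplace-smoothed
frequencies p_C,i and p_H,i in the two source pools. Frequency-estimate
noise is absorbed by the Laplace smoothing ((x+1)/(n+2), strictly inside
(0,1)) rather than modeled by binomial emission integrals — simpler, and
adequate at the 20–250× depths the AIM filter admits.

**AIM selection.** Bi-allelic sites with 20 < depth < 250 (strict) in
both pools and |p_C − p_H| > 0.2; the strict frequency gate keeps only
strongly informative markers so posteriors saturate within a few AIMs of
a true switch.

**Inference.** Scaled forward–backward (scalar inner loops; stable for
millions of AIMs) gives per-AIM posteriors P(C) and the data
log-likelihood; Viterbi gives the segment mosaic, with bp boundaries at
midpoints between adjacent AIMs of different states. τ and the
initial-state probability π_C are re-estimated by Baum–Welch with
emissions held fixed (they are data, not parameters); τ is clamped to
[10⁻⁸, 0.5 − 10⁻⁸] with a warning if an update collapses. α per contig
is the mean posterior P(C) over its AIMs; per-class α is the
AIM-count-weighted mean of per-contig values (not bp-weighted; at
uniform AIM density the two coincide) and the reported SD is across
contigs within a class.

**Verification.** Forward–backward and Viterbi agree with exhaustive
2^L path enumeration to 10⁻¹⁰ for L ≤ 12; on the standard simulated
mosaic (2×10⁴ AIMs, switch 10⁻³, divergence 0.5, depth 50×) τ̂ is within
×1.5 of truth, α̂ within ±0.02 of the realized path fraction, and the
Viterbi path matches the truth at ≥ 95% of AIMs. Swapping the two source
pools maps α → 1 − α and relabels segments exactly. Only two source
populations and haploid (unphased) painting are supported.

## Synthetic data: what it emulates, and what it does not

The generators reproduce exactly the structure the analyses assume —
uniform-random background sequence with planted near-identical tandem
copies; independent negative-binomial depths with X dosage (dispersion 5
by default, var = m + m²/k, Poisson in the k → ∞ limit; overdispersion is
a package assumption, chosen because real short-read depth is
overdispersed); infinite-sites neutral pools (segregating-site count
Poisson with mean θ·L·a(n), pool counts ∝ 1/i, binomial reads at
Poisson depth); and stationary two-state Markov ancestry paths with
divergence-constrained source frequencies (asymmetric rates s/(2α),
s/(2(1−α)) so the stationary C fraction and the unconditional switch
probability are both exact). All generators are bit-reproducible under a
fixed seed.

They deliberately omit: sequencing error and base-quality structure,
mapping bias and repeat-driven coverage artifacts, GC- or
mappability-driven depth autocorrelation along contigs, linkage and
selection in the pool model, and read-level (FASTQ) detail. Passing
recovery tests therefore demonstrates the correctness and calibration of
the estimators under their stated assumptions, not robustness to
real-data artifacts — e.g. the sex-assignment mixture sees no
contig-level coverage heterogeneity beyond sampling noise, which real
data would add.

A note on single-realization variability: with switch probability 10⁻³
over 2×10⁴ AIMs a path carries only ~20 switches, so the *realized* C
fraction of one mosaic has SD ≈ 0.08 around its stationary target;
generator stationarity is therefore tested on replicate averages, while
estimator accuracy (α̂ vs the realized path) is tested per realization,
where it is tight.

## Problem sizes

Default test and acceptance runs use: 300 contigs × 1 Mb for the
coverage-ratio simulation (the scale at which contig medians stabilize);
100 × 10-kb windows (10⁶ sites) per diversity configuration; 2×10⁴ AIMs
for the ancestry scenario; 10³ random pairs/tracks for the
false-positive and segmentation-equivalence suites. These sizes were
chosen so every statistical tolerance is comfortably resolvable at desk
scale.
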