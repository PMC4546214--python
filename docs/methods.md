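# Methods

This note documents the models, defaults and numerical choices behind
`xcidyn`, and what the synthetic-data tests do and do not establish.

## Allelic quantification

Counts at polymorphic sites are assigned to the 129 or Cast allele
upstream of this package (read mapping is out of scope); the pipeline
starts from per-site count tables. Site selection keeps sites covered at
least twice from *both* alleles, pooled across every sample of the run —
one global site list, so a site's eligibility does not flip between
samples. Gene-level counts are sums over sites inside exons; a site shared
by exons of two overlapping genes counts for both (no exclusion rule is
imposed; the behavior is documented rather than configurable away
silently).

Three gene-level filters define "quantified" for a differentiation course:

| filter | rule | default |
|---|---|---|
| course coverage | counts summed over the course `> 80` from both alleles (strict; an inclusive `>= 80` switch exists) | 80 |
| consistency | SEM of per-site pooled 129-ratios `<= 0.1` over qualifying sites (course-summed count `> 9` on either allele); single-site genes pass | 0.1 |
| expression | mean RPKM over the course `> 0.5` (strict) | 0.5 |

A gene with zero allelic counts has an undefined ratio, which propagates
as missing — never as 0 or 0.5 — so downstream statistics cannot be
diluted by fabricated ratios.

## Silencing kinetics

Trajectories are `Δ(t) = log₂(Xi/Xa)(t) − log₂(Xi/Xa)(0)`. A time point
with zero counts on one allele is floored/capped at ±10 with a flag (rare
after the 80-count filter); zero on both alleles makes the time point
missing and drops the gene from clustering.

K-means (Euclidean, k = 4, 10 restarts, seeded) runs on the delta matrix
with the *positive* side clipped at +1 log2 unit. Rationale: for silencing
kinetics any Xi/Xa increase means "not silenced"; the Xi-only Xist-like
locus gains several log2 units and, unclipped, captures a singleton
centroid on some datasets, merging the real not-silenced genes into the
"late" cluster. Raw deltas are kept for all reporting. Cluster labels are
assigned deterministically: the cluster whose mean day-8 delta stays above
−0.5 (the Xi retains >~70 % of its initial relative expression) is
`not_silenced`; the rest are ranked by mean day-2 delta, most negative
first: `early`, `intermediate`, `late`. The −0.5 threshold is a package
choice — the original description identifies that cluster by inspection.

Positional enrichment uses the classic unweighted running-sum rank
statistic: genes ordered by distance to the XIC (gene midpoint to the XIC
coordinate), members step `+√((N−n)/n)`, non-members `−√(n/(N−n))`, score
= signed extremum. The null is label permutation; because the score lives
on a discrete lattice, ties against the observed score are counted half
(mid-p) — this keeps the p-value uniform under the null, which the suite
verifies by a KS test over 500 replicates. For N ≤ 8 an exhaustive
enumeration replaces sampling. BH-FDR is applied across the k clusters.
The enrichment variant used by the original external service is not
stated anywhere; the unweighted statistic is the simplest defensible
choice and is isolated behind one function.

Distribution comparisons (expression strata, Xa upregulation) use McGill
notched boxplots: notch half-width `1.58 · IQR / √n`, quartiles by linear
interpolation (the common "type 7" convention; no convention is stated in
the source material, so the most widespread default is fixed and
documented). Non-overlapping notches ≈ p < 0.05; intervals sharing exactly
one endpoint count as overlapping (conservative). Only the binary decision
is reported — the notch method defines no finer p-value.

## Escape calling

A gene escapes XCI in a stably inactivated line iff

1. ≥ 2 polymorphic sites show Xi signal (≥ 1 Xi count; the minimum is
   configurable),
2. Xi counts sum to more than two (≥ 3), and
3. the Xi/Xa **ratio** exceeds 0.10, strictly — log₂ cutoff −3.32.

Criterion 3 deliberately thresholds the ratio rather than the
fraction-of-total (the two differ: ratio 0.10 ⇔ fraction 1/11): only the
ratio rule reproduces the published per-gene calls (a gene printed at
log₂ = −3.2 escapes). Escape regions are maximal runs of ≥ 3 consecutive
informative escapers; genes without allelic information are transparent to
a run and never break it. Allelic-bias calls in undifferentiated cells
need ≥ 2 per-site exact binomial tests at p < 0.01, ≥ 80 % of the
significant sites agreeing in direction (a switch widens the denominator
to all tested sites), and a gene-level contribution > 75 %.

## Hi-C and TADs

Contacts are binned at 40 kb. Balancing is iterative proportional fitting
to equal row sums (coefficient of variation < tol, zero rows untouched,
overall scale preserved) — a standard, testable stand-in for
library-internal normalizations with the fixed-point and scale-invariance
properties the tests assert. The directionality index per bin i uses
upstream/downstream sums A and B over a 2-Mb window (truncated at the
ends), E = (A+B)/2, `DI = sign(B−A) · ((A−E)² + (B−E)²) / E`, zero when
A = B or E = 0.

Domains come from a 3-state Gaussian HMM (downstream-biased / none /
upstream-biased) decoded by Viterbi. The emission variable is
`sign(DI)·log1p(|DI|)`: the raw DI is chi-square-like with boundary spikes
two orders of magnitude above interior values, and raw-scale Gaussian
emissions let one EM state swallow both tails on a noticeable fraction of
datasets, scrambling the sign labeling. EM starts from a deterministic
initialization (means at ±(75th percentile of |z|) and 0, sticky
transitions), so calls are reproducible given the seed. A domain runs from
the start of a downstream-biased segment to the end of the following
upstream-biased segment; domains under 3 bins are discarded. Boundary sets
are matched greedily, nearest pair first, with an inclusive ≤ 40 kb
cutoff. Gene-to-TAD assignment is by majority of the gene body, with the
strand-aware 10-kb upstream promoter window assigned separately.

## Synthetic data

The generator emulates the statistical structure of the hybrid ESC
system at desk scale: one X-like chromosome (16.6 Mb) and one autosome
(19.5 Mb), ~10× smaller than mouse, with 300 + 700 genes — sized so the
full suite runs in minutes. Defaults that mirror the study conditions:
SNP spacing 300 bp (X) / 130 bp (autosomes); time points 0/2/3/4/8 days;
kinetic class proportions 30/30/30/10; the XIC at 10.07 Mb (100.7 Mb
scaled); Xa upregulation slope 0.025/day (+20 % by day 8); X:autosome
expression scale 1.5; NPC zero-Xi probability 0.7 per silenced gene.

Silenced genes follow `f(t) = (0.5 − floor)·e^(−t/τ) + floor` for the Xi
fraction (floor 0.02; `f(0) = 0.5` exactly so deltas start at zero). The
curve family is invented — the source trajectories are monotone without a
stated functional form — chosen for its two-parameter simplicity. τ grows
with distance to the XIC (rank score with Gaussian noise, cut at the class
proportions) and with expression level (±30 % across expression ranks),
and the global τ scale is calibrated by root-finding so that the mean
planted day-2 Xi/Xa silencing, `mean(1 − r(2)/r(0))` with `r = f/(1−f)`,
equals 0.46. The calibration is on the ratio scale because that is the
scale of the measured deltas (`1 − 2^Δ(2)`); the early class is capped so
it reaches `f ≤ 0.05` by day 8. Counts are Poisson per site (expected
`site_depth · RPKM`, default 30) split binomially at the planted Xi
fraction; an optional beta-binomial adds overdispersion. RPKM tables come
from Poisson-sampled whole-gene read counts, so expression noise is
consistent with the count model.

Escape regions occupy whole TADs distal to the XIC (plus scattered
singleton escapers and one Xi-only Xist-like gene at the XIC). Escape
genes express the Xi at a uniform 15–50 % share: published escapers sit
overwhelmingly well above the 10 % cutoff, and genes hovering at ~10 % are
exactly the unstable borderline calls, so planting them would make "exact
recovery" meaningless. For the same reason planted region genes are
guaranteed ≥ 2 exonic SNPs and ≥ 1 RPKM — the generator plants
*detectable* regions. Hi-C expected counts are
`L·(1+|i−j|)^(−α)` (α = 0.8) boosted ×3 within a TAD, Poisson sampled;
the allele-tagged variant is a 50 % binomial thinning.

Two deliberate departures from realism: the expression spread is
σ_ln = 0.6 (real RNA-seq is broader) so that nearly every simulated gene
is informative at desk-scale coverage, and chromosomes/genes are far
fewer than real. Consequently the suite demonstrates *method correctness*
(filters, estimators, callers recover planted truth) — not performance on
the long-tailed coverage and expression distributions of real libraries.
The generator does not simulate reads, sequence content, mappability or
strand; allelic assignment is taken as given.

## Known limitations

* The Hi-C normalization and domain segmentation are documented stand-ins,
  not re-implementations of any specific published caller; absolute domain
  counts on real data will differ with caller settings.
* Escape calling assumes complete XCI skewing in each line; mosaic lines
  would need a mixture model the package does not provide.
* The GSEA variant, notch quartile convention and not-silenced threshold
  are fixed package choices where the source material is silent; each is
  isolated behind one function or constant and switchable.
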