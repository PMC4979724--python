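# Methods

This note documents the statistical machinery in `clinezone`, the choices
made where the published description of the original analyses left the
design open, and what the synthetic-data checks do and do not establish.

## Data model and pooling

Genotypes are unordered diploid pairs of integer allele lengths per locus;
a call is either complete or fully missing (half-missing calls are
promoted to missing with a warning when read from GenePop files, and
rejected in the CSV dialect, where they usually indicate an export error
rather than allele dropout).

Collection sites are pooled into analysis populations by single-linkage
closure over great-circle distance (haversine, sphere radius 6371.0088 km)
with a 4 km threshold: sites A and C end up pooled whenever a chain of
within-threshold links connects them, even if A–C itself exceeds the
threshold. The published population groupings for the chorus-frog system
are exactly reproduced by this rule from the raw site coordinates,
including the exclusion of one unpoolable single-individual site; the
alternative (strict pairwise) rule would split one population and was
rejected on that basis. Pooled population coordinates are
individual-count-weighted means of the member site coordinates. An
optional guard recomputes pairwise FST with permutation p-values inside
every pool and reports (but does not block) merges that remain significant
after Holm correction, mirroring how pooling was validated originally.

## Diversity statistics

Expected heterozygosity uses Nei's unbiased correction,
H_e = (2n/(2n−1))(1 − Σp²), per locus, averaged over loci (the
uncorrected variant is available via `unbiased_he=False`). G_IS is
1 − H̄_o/H̄_e from the locus-averaged values and is reported missing when
H̄_e = 0, since the ratio is undefined. Allelic richness is rarefied
exactly: AR_g = Σ_a [1 − C(2n−n_a, g)/C(2n, g)], evaluated with log-gamma
arithmetic; it equals the observed allele count when g equals the sampled
gene count and is monotone in g.

The Hardy–Weinberg test is a Monte-Carlo exact test: alleles are shuffled
into genotypes within each locus × population and the probability-ordering
p-value is the fraction of shuffles whose conditional genotype-table
probability (Levene's distribution) does not exceed the observed one. This
shares its null with the Markov-chain walker used by the original GENEPOP
analysis but has a simpler convergence story; the replicate count is a
parameter (default 10⁴) and a full-enumeration oracle for biallelic
samples is part of the package for validation. "Sequential Bonferroni" is
Holm's step-down procedure, applied table-wide across all locus ×
population tests. Linkage disequilibrium uses the genotypic G-test with
the null built by permuting one locus's genotypes across individuals
within populations, with standard Bonferroni across locus pairs. Pairwise
FST is Weir–Cockerham θ (the permutation test is estimator-agnostic, so
the choice of estimator does not affect significance calls).

## Hybrid index

The per-allele mixture likelihood treats allele copies independently; it
is concave in h, so a single bounded optimisation finds the MLE, with
endpoints checked explicitly and ties broken toward the boundary (flat
likelihoods occur for individuals carrying only alleles shared between
pools). The 95% interval is the profile-likelihood set at a 1.92
log-likelihood drop (χ²₁/2). Parental pool frequencies receive an
additive pseudocount (default 10⁻⁶) over every allele observed anywhere in
the dataset, preventing −∞ likelihoods from alleles unseen in one pool
while perturbing the MLE negligibly. Two classification rules are
implemented: hybrid iff 0.25 ≤ h ≤ 0.75, and hybrid iff the 95% interval
excludes both 0 and 1. Orientation follows the bundled tables: h = 1 is
the *P. fouquettei* (western) side.

## Transect

Coordinates are mapped to a local equirectangular frame (longitude scaled
by cos of the mean latitude, 111.32 km/degree) and a least-squares line of
latitude on longitude is fitted through all populations of both eras; each
population is orthogonally projected and x is the signed km distance from
the westernmost projection. Which regression variant the original
analysis used is not recoverable, so all downstream fitting also accepts a
printed distance table verbatim (`load_printed_distances`); the bundled
chorus-frog positions are those published distances, making the cline
results independent of the projection choice.

## Cline models

The central cline is s(x) = 1/(1+exp(−4(x−c)/w)), mirrored for data that
decrease west to east (an explicit orientation flag, never inferred from
a draw). On a tailed side the curve beyond distance δ from the center
follows an exponential whose rate is 4τ / (w(1+exp(−4δ/w))); the tail is
value-continuous at the junction for every τ, slope-continuous at τ = 1,
and flat at τ = 0. End frequencies are fixed at 0 and 1. Five variants
(none k=2, west/east/symmetric k=4, asymmetric k=6) are compared by AIC
with Akaike weights and evidence ratios.

The population likelihood is the binomial log-likelihood ratio against the
saturated model with effective count N_i (individuals). The saturated
reference makes a perfect fit ln L = 0, reproducing the near-zero
magnitudes of the published model-comparison tables, and both the
(c, w) argmax and all likelihood-ratio statistics are invariant to a
uniform rescaling of the N_i, so the individuals-versus-allele-copies
ambiguity cannot move the center/width estimates. Terms with p̄ ∈ {0, 1}
use the 0·ln 0 = 0 convention and μ is clamped to [10⁻¹², 1−10⁻¹²] so
boundary populations contribute finite terms.

Flat priors: c uniform over the sampled span ±50 km; w uniform on
(0, 2×span] (the recent width interval reaches ~582 km, so the prior must
not bind below roughly twice the ~690 km span); τ uniform [0,1]; δ uniform
[0, span]. Fitting runs a pilot Metropolis chain with diagonal proposals
to estimate the parameter covariance, then three independent chains with
multivariate Gaussian proposals scaled by 2.38/√d times that covariance;
draws are thinned after burn-in and pooled for 2.5–97.5 percentile
credibility intervals. Reported MLEs are the better of the
highest-posterior draw and a deterministic multi-start bounded
optimisation (Latin-hypercube starts seeded by a coarse vectorised scan,
plus starts embedded from nested simpler models — the tailed likelihoods
have narrow high-likelihood basins at small width and small δ that widely
spaced starts alone can miss, and the embedding guarantees the nesting
property ln L(tailed) ≥ ln L(no tails) in practice). Diagnostics include
the acceptance rate, split-half percentile drift per parameter, and a
flag for posteriors leaning on their prior support (e.g. the width with
only two informative populations).

Because the deterministic optimiser searches the likelihood surface more
aggressively than a finite MCMC run, refitted tailed-model likelihoods can
exceed the published ones (which were read off posterior draws); on very
flat ridges the published point estimate can also sit a few km from the
surface optimum at a ~0.5 log-unit cost, which is why the
recent-without-B–D center is reproduced only to ~5%.

## Constraint tests and subsampling

Constrained fits truncate the prior support of the constrained parameters
to the supplied interval (a degenerate interval fixes the parameter) and
reuse the identical machinery. Following the published AIC arithmetic, a
constrained parameter is treated as no longer free: k drops by the number
of constrained parameters, so a non-binding constraint improves AIC by
exactly 2 per parameter. Comparisons report 2LLR = 2(lnL_con − lnL_uncon)
and ΔAIC = AIC_uncon − AIC_con.

Stratified subsampling matches each historical population to a candidate
set of recent populations (one candidate drawn uniformly per replicate),
subsamples individuals without replacement so both members of each pair
share the pair's smaller N, recomputes population mean hybrid indices
from the retained individuals, and refits the no-tails model to both eras.
A parameter differs significantly in a replicate iff the two 95%
credibility intervals are disjoint — deliberately conservative.
Per-pair matching is adopted because it is the only scheme consistent
with equal era totals; replicate fits default to shorter MCMC runs
(10⁵ generations post-burn-in, configurable) to keep 100-replicate
analyses tractable on a single CPU.

## Synthetic data

The generator emulates the study design rather than the biology: two
parental allele-frequency pools per locus (a shared symmetric Dirichlet
base, two pools drawn around it with concentration 20(1−d)/d for
divergence d, and a fraction of alleles zeroed in exactly one pool),
populations at the historical transect positions with the historical
sample sizes (N = 16, 4, 17, 25, 6, 30, 19), per-individual admixture
h ~ Beta(qν, (1−q)ν) around the cline expectation q (ν = 30 by default;
∞ makes individuals deterministic), and allele copies drawn independently
from the per-individual mixture. Missing data (2% default, settable per
locus) and allele-specific dropout (null alleles, producing spurious
homozygotes) are applied last. Defaults: 11 loci with 4–10 alleles,
divergence 0.8, private-allele fraction 0.55 — the last matches the
species-private share of alleles actually observed in the system (139/245
historical, 147/291 recent alleles private to one species).

What the generator does not emulate: pedigree structure (no F1/F2/backcross
classes, no interspecific-heterozygosity signal), mutation models, linkage,
and spatially explicit dispersal. Passing the recovery checks therefore
shows that the estimation chain is consistent under the sampling design
and noise levels stated above, not that it is robust to every feature of
real microsatellite data.

One interaction matters for interpreting the recovery checks: the
hybrid-index MLE is bounded to [0, 1], so per-individual estimation error
near the parental ends can only push population means toward the interior.
With weakly diagnostic markers this inflates fitted cline widths enough
that narrow-cline credibility intervals sit above the true width. At the
observed marker informativeness (private-allele fraction ≈ 0.55) the bias
is negligible and 95% intervals cover the true center and width in
essentially all of 50 simulated historical-design datasets; reruns with
deliberately less diagnostic markers (fraction 0.3) show the width
coverage collapsing to ~70%, which is worth remembering when applying the
pipeline to systems with low parental differentiation.

## Problem sizes used in tests

The test suite and the acceptance script run Monte-Carlo pieces at sizes
chosen for a single CPU: HWE/LD/FST permutation tests at 10³–2×10⁴
replicates, MCMC runs of 1–5 × 10⁴ generations for credibility intervals
(the full protocol of 10⁶ generations sampled every 100 after 10⁵ burn-in
remains the default for production fits), 50 seeds for coverage checks,
and 3–5 subsampling replicates where the published analysis used 100.
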