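# Methods

This note documents the models, defaults, and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Lipid chemistry and sn-position assignment

Shorthand parsing covers 18 lipid class codes plus chain-level
(`TAG 18:0_18:1_20:4`) and species-level (`TAG 56:5`) annotations, ether
("e") and plasmenyl ("p") chains, chain deuteration (`18:1D7` internal
standards), and `[sn-1]`/`[sn-2]` suffixes kept as metadata.

Molecular formulas are assembled for glycerophospholipid classes (LPE, LPC,
PE, PC, PG, PS, PI) as the neutral glycerophospho-headgroup backbone plus
each chain as free fatty acid (or fatty alcohol for ethers) minus one water
per attachment. Monoisotopic masses use IUPAC atomic values to ≥ 10 decimal
places; ion m/z accounts for the electron (proton mass 1.00727645 u), so
[M+H]⁺ − [M−H]⁻ = 2 × proton mass exactly. Nominal m/z is
round-half-away-from-zero of the monoisotopic value, which reproduces all
four reference fragments of LPE 22:6 (524 / 327 / 283 / 196).

The m/z 196 diagnostic is modelled as C₅H₁₁NO₅P⁻, the dehydrated
deprotonated glycerophosphoethanolamine fragment. Two facts support this
assignment: its computed m/z (196.038) matches the observed nominal mass,
and the fragment carries no chain atoms, so it must be insensitive to chain
deuteration — exactly the behaviour of the 18:1D7 LPE internal standard,
whose spectrum retains the 196 peak while its acyl anion shifts by
7 × (m_D − m_H). The test suite checks both properties.

sn-calls use a 10 ppm default matching tolerance (high-resolution Orbitrap
class accuracy; configurable). The decision logic: *sn*-1 requires the
headgroup diagnostic plus intact and acyl ions; intact + acyl without the
diagnostic gives *sn*-2; a co-eluting isomer pair can be resolved by
retention order (later = *sn*-1) when the spectrum is uninformative. A
spectral diagnostic outranks the retention rule on conflict (the retention
rule is treated as confirmation only), and the conflict is logged. LPC has
no validated negative-mode headgroup diagnostic here, so LPC calls rely on
the retention rule alone. Missing peaks degrade a call to *ambiguous*, never
to the opposite label.

## Preprocessing

Filtering keeps features with SNR > 3, peak quality > 0.6 and ID grade in
{A, B, C} (strict inequalities); internal standards are excluded from the
analysis set but preserved in a side table.

Missing values: features with > 20% missing are dropped; the remainder are
imputed as half the feature minimum. This is standard practice for
left-censored LC-MS missingness; both thresholds are arguments.

Drift correction models each feature's systematic component on the QC pools
with a random-forest regression on injection order plus the k = 10 features
most correlated with it on the QC pools, then subtracts the prediction in
log2 space (equivalently divides it out on the linear scale) and re-centres
at the feature's QC median — per batch, followed by median alignment across
batches. The forest uses 100 trees by default: at the default cohort scale
(about 300 retained features, 356 injections) this completes in well under a
minute while leaving the QC relative standard deviation (RSD) statistics
indistinguishable from larger forests; the tree count is a parameter for
anyone who prefers a heavier model. With fewer than 5 QC pools per batch the
model falls back to LOESS on injection order (QC trend interpolated across
the run, edges clamped). The correction preserves sample/feature counts and
non-negativity, and on drift-free data is a near-identity (median |log2
change| < 0.05), which the tests verify along with a KS check that null
group statistics are not distorted.

Covariate screening runs a one-way MANOVA (Pillai's trace) of the lipidome
against each covariate. With more features than samples the matrix is
reduced to its top 10 principal components first — a necessary
regularization whenever p ≥ n. The screen only flags covariates (default α
= 0.05); residualization is deliberately not applied by default, matching
the screen-and-proceed workflow this pipeline reproduces.

Class aggregation sums species on the linear scale before taking log2 (class
abundance is a physical sum of concentrations); ratios are log2 differences
of class totals, so a ratio difference of x between groups is a 2^x fold
difference.

## Differential abundance

ANOVA post-hoc defaults to Tukey HSD (studentized-range p on the pooled
MSE); Fisher LSD (unadjusted pooled t) is available by flag. The
Kruskal–Wallis table reports BH FDR across features, with a configurable
display threshold (default 0.7) that flags features for visualization — it
is not a significance claim. Fold-change tables use the two-sided pooled t
test, optionally variance-moderated: per-feature variances are shrunk toward
a scaled-inverse-chi-square prior whose (d₀, s₀²) are moment-matched on the
log-variances (digamma/trigamma inversion); prior df → 0 recovers the plain
t exactly, and the infinite-prior branch uses the normal reference. Features
with zero variance and no moderation return a missing p rather than a fake
one.

## Lipid set enrichment

Sets are built from the annotation itself: one set per lipid class, per
total acyl carbon count, and per total double-bond count, with a minimum set
size of 3. The enrichment score walks the fold-change-ranked lipid list; the
running sum gains |stat|^w (normalized over members; weight w = 1 by
default) at each member and loses 1/N at every position, and ES is the
extremum — i.e. the weighted-hit CDF compared against the uniform
expectation. This form is bounded by 1, is invariant to monotone transforms
of the statistic at w = 0, and degrades gracefully to 0 for a set equal to
the whole universe (which is rejected as degenerate anyway). A brute-force
re-implementation of the same definition serves as the oracle in tests.

Significance permutes set membership (not sample labels): B = 10,000 draws
of random same-size subsets by default, p = (1 + #{|ES₀| ≥ |ES|}) / (B + 1),
NES = ES / mean|ES₀|, BH within each facet. Membership permutation matches
the gene-label null of the GSEA adaptation this follows and keeps the test
O(B·m) per set; a sample-permutation null (re-ranking per permutation) is
out of scope. Under an i.i.d. null the membership permutation is exact, and
the calibration test confirms a 3–7% rejection rate at α = 0.05; when
features inside a set are strongly co-expressed but not group-associated the
membership null can be mildly anticonservative — a known property of
gene-label permutation inherited by design.

Class over-representation of module hubs uses the one-sided Fisher exact
(hypergeometric upper tail) against all annotated lipids, BH-corrected
within module, significance at 5% FDR.

## Co-expression network

Correlation is Pearson by default; biweight midcorrelation (c = 9) is
available. Signed adjacency ((1 + r)/2)^β; β is chosen as the smallest power
reaching scale-free fit R² ≥ 0.9 (R² of log10 p(k) vs log10 k over 10
connectivity bins, negative slope required). When no power reaches the
target — common for strongly modular or synthetic data, which is *not*
scale-free — the fallback takes the argmax R² among powers whose mean
connectivity stays ≥ 2; without that guard the argmax runs off to degenerate
powers where the network is effectively empty. The selection table is always
returned so the choice can be inspected.

The topological overlap uses the min-overlap form
TOM_ij = (Σ_{u≠i,j} min(a_iu, a_uj) + a_ij) / (min(k_i, k_j) + 1 − a_ij),
dissTOM = 1 − TOM. A consequence worth knowing: unconnected background
features share a diffuse neighbourhood and therefore sit at a *lower*
mutual dissTOM than the module-to-module distance — the background forms its
own loose blob rather than scattering at dissimilarity ≈ 1.

Module detection: average-linkage clustering of dissTOM, static cut at
cutHeight 0.97, then each branch is recursively re-cut at its largest
relative merge-height gap when that gap reaches the deepSplit-mapped
threshold (deepSplit 0–4 → ∞, 0.40, 0.20, 0.10, 0.05); the rationale is that
merge heights inside a homogeneous module rise smoothly while the transition
to bridge merges leaves a gap. Candidate clusters become modules only if
they are cohesive (mean intra dissTOM < 0.75) and separated (mean
cross-dissimilarity ≥ 1.3 × intra mean) — the separation test is what
rejects the background blob, whose cross-distance barely exceeds its
internal spread. Over-split fragments are merged back when their
cross-distance lies within 0.10 of the target's intra mean, and leftover
features attach to a module only under the same closeness rule, else stay
unassigned (module 0, "grey"). Modules are numbered by decreasing size.
Planted-block recovery (6 × 20 features, intra-correlation 0.7, n = 300)
at these exact parameters is an acceptance test (ARI ≥ 0.8); label
invariance to feature order is a property test. Known limitation: with
min-overlap TOM, weakly co-expressed background features that sit *between*
two modules can attach to one of them; the cohesion/separation thresholds
are configurable if a dataset needs stricter gating.

Eigenlipids are PC1 scores of the standardized module submatrix, scaled to
unit variance and sign-aligned with the module mean profile; variance
explained is the first-eigenvalue share; kME is each feature's correlation
with each eigenlipid; hubs default to kME > 0.60 (a stricter 0.8 is a
parameter). Module–trait association is pairwise-complete Pearson r with
the Student asymptotic p on n − 2 df; a 10,000-draw permutation check in the
tests confirms the asymptotic p within Monte-Carlo error at n = 25.
Diagnosis enters trait tables as ordered codes 0/1/2
(Control/AAD/SAD); CERAD and Reagan can be carried on the inverted scale and
are annotated as such. Sample outliers are removed by robust z-score
(median/MAD) of the standardized Euclidean distance to the centroid,
threshold 3.

## Classification rules

The three rule regions are evaluated in order Control → AAD → SAD; the
"Braak 3 requires CERAD 0" clause resolves the only potential overlap
(CERAD 1, Braak 3, no dementia) in favour of AAD, which an exhaustive
enumeration over CERAD × Braak × dementia verifies, together with the fact
that the Unclassified region is exactly the complement. The inverted
recording maps 4→0, 3→1, 2→2, 1→3; classification raises on an undeclared
scale rather than guessing.

## Supervised models

sPLS-DA: NIPALS power iteration on X'Y (dummy-coded classes), initialized at
the dominant singular vector (deterministic), with soft-thresholding of the
X-loading to the keepX largest entries per component (threshold = the
(keepX+1)-th magnitude, mixOmics-style), regression deflation of X and Y.
keepX defaults to all features, in which case the component-1 variate
matches standard PLS (|r| ≥ 0.99 — an acceptance oracle against an
independent dense-PLS implementation). Prediction projects through
W(PᵀW)⁻¹ and assigns by centroid distance (default), Mahalanobis distance
on the pooled within-class covariance, or the largest predicted dummy
response; per-class continuous scores feed ROC. AUC is the Mann–Whitney U
statistic over n₁n₀ with the tie-corrected normal-approximation p.

The multiblock fit gives every block its own outcome variate u_b and
maximizes Σ_b cov(X_b w_b, Y u_b) + Σ_{b<c} d_bc cov(X_b w_b, X_c w_c) by
alternating updates. The per-block u_b (rather than one shared outcome
variate) was chosen so that an all-zero design decouples *exactly* into
independent per-block sPLS-DA fits — a testable limiting case — while any
nonzero design couples the blocks through the covariance terms. With dense
loadings each update is the constrained maximizer, so the objective is
non-decreasing within a component (a property test); soft-thresholded
updates are only approximately monotone, as in the reference algorithm.
Relevance networks compute direct Pearson correlations between typed node
vectors and keep cross-type edges with |r| above the cutoff (default 0.7) —
a documented simplification of similarity-from-latent-components
reconstruction with identical thresholding semantics. Pairwise
lipid–protein association uses the fact that one-component PLS with a
univariate predictor reduces to Pearson correlation; edges need |r| > 0.5
and Student p < 0.05.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a tuning
surface. Defaults mirror the emulated cohort: 92/77/147 Control/AAD/SAD
samples, 343 lipid features plus 4 deuterated internal standards, 40 QC-pool
injections interspersed through the run, 30% linear multiplicative
injection-order drift, 2% missingness, ~15% of features failing the QC
filter.

Neuropathology is sampled inside each diagnosis rule's region (e.g. SAD
draws CERAD ∈ {2,3}, Braak ∈ {3..6}, and dementia-range MMSE/CASI/CDR), so
the classification rules reproduce the planted label for every sample — a
construction constraint the tests assert. Continuous traits use
group-ordered means (global cognition 0.25 / −0.09 / −1.29; pathology and
age increasing into disease); education and PMI are group-independent. Age
is deliberately group-associated (AD groups older), so the covariate screen
can flag a weak age signal — realistic, and handled by the flag-only
default.

The lipidome is log-normal: per-feature baseline mu ~ U(10, 20) log2 units,
biological sd 0.5 log2 units. Planted modules draw a latent factor per
module; members load √ρ on it (default intra-correlation ρ = 0.7, six
20-feature modules). The LPE/LPC module adds −0.8 sd to SAD samples — the
planted effect the differential and enrichment stages must recover. Study
samples are assigned to injection slots in *randomized* order, as in actual
practice; without randomization the monotone drift confounds with diagnosis
and produces spurious group effects in null features. QC pools are the mean
profile plus 0.05 log2-sd technical noise. Drift is monotone per feature
with random direction; 10% of features drift heavily (4–7× the base slope),
which is what places some raw QC RSDs above 50% so the correction's
improvement is visible in both the median and the <50% count. Protein-module
eigenvalues are generated on the first 266 samples (the common-case subset);
coupled columns share the referenced lipid-module latent at the specified r
(default: the lyso module ↔ "black" at 0.8).

What the generator does **not** emulate: adduct/isotope structure in the
spectra beyond the predicted fragment set; non-random (intensity-dependent)
missingness; lipid co-regulation beyond block correlation; batch effects
other than run-order drift (the default is a single batch); scale-free
degree topology (planted equal-size blocks are modular, not scale-free —
which is precisely why the soft-threshold fallback path exists and is
exercised). Passing tests therefore demonstrate correct recovery of planted
block/effect/coupling structure under drift and missingness, not robustness
to every artefact of real acquisitions.

Spectra generation jitters theoretical fragments uniformly within the stated
ppm (default 10), draws log-normal intensities, omits the headgroup
diagnostic for *sn*-2, assigns *sn*-2 the earlier retention time, and places
decoy peaks only outside a 3× tolerance window around every theoretical
fragment — decoys are meant to test robustness to unrelated peaks, not to
counterfeit diagnostics.

Determinism: every generator consumes a `numpy` Generator seeded from the
single integer `SimConfig.seed`; identical seeds give bit-identical outputs,
asserted in tests.

## Problem sizes used in the checks

The acceptance-style checks run at the sizes their definitions state: the
fragment masses are closed-form; sn round-trip uses 200 spectra; module
recovery uses 6 × 20 features at n = 300; drift correction runs the
full-scale default preset; LSEA calibration uses 200 null repeats (100
features, 63 samples, B = 1000) and 100 planted repeats; the Fisher oracle
enumerates every 2×2 table with n ≤ 50; integration recovery uses 100 seeds
at n = 266 with drift disabled (the coupling question is orthogonal to drift,
and the drift stage has its own criterion). Unit and property tests use
smaller instances chosen to exercise the same code paths.

## Known limitations

* The min-overlap TOM makes background features mutually similar at scale;
  module acceptance therefore needs the separation criterion, and very
  weak modules (ρ ≲ 0.2) will be rejected as background.
* The MANOVA screen's PC reduction (top 10 components) is a pragmatic
  choice; covariate effects confined to low-variance directions can escape
  it.
* LSEA membership permutation is anticonservative for internally correlated,
  group-null sets (inherent to label permutation).
* sPLS-DA/DIABLO sparsity uses soft thresholding without an optimality
  certificate; only the dense limits are oracle-checked.
* LPC sn-position calls are retention-rule-only; spectral LPC diagnostics
  in negative mode are not implemented.
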