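# Methods

This note documents the statistical procedures implemented in `synoclass`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot demonstrate.

## Data model

A cohort is a table of biopsies with absolute densities (cells/mm² of
subintima, real-valued because each is an average over ≥ 10 microscopic
fields) for the five-marker panel CD15/CD68/CD3/CD20/CD38 and one of six
diagnosis labels. The severity order N < Orth.A < OA < EA < RA < SeA is
fixed package-wide: it selects the positive class of every binary
comparison, the numerator of every ratio, and the class order of the
multicategory analysis. Group labels are case-sensitive canonical strings;
a small alias map ("Normal" → "N", "Orth. A" → "Orth.A") is applied before
validation.

The default group sizes are n = (15, 6, 26, 10, 25, 11) for
(N, Orth.A, OA, EA, RA, SeA). The literature this design follows is
internally inconsistent about the RA count (25, 26, and confusion-matrix
rows summing to 24 all occur); 25 is used here and the inconsistency is
simply noted.

## Composition transform

TIC is the exact sum of the five densities; relative densities are
percentages of TIC and sum to 100 for every valid sample. A sample with
TIC = 0 has no defined composition: it is flagged invalid, excluded from
every relative-method analysis with a logged warning, and retained for
absolute-method analyses. Whether the original analyses used rounded or
raw counts per sample is unknown; raw values are used.

## Robust aggregation

Group location is the *mean of trimmed means*: the trimmed mean at each of
several trim factors, averaged. A trim factor of t% discards
k = floor(t/100 · n) values from **each** side (the standard per-side
convention; the source wording does not distinguish per-side from total).
Factors are {10, 20, 30}% for n < 12 and {0, 10, 20}% for n ≥ 12. Groups
with n ≤ 3 are rejected by `robust_group_mean`; where a summary must still
be produced for a tiny group (gestalt tables, ratio-of-ratios on toy
data), the plain mean is substituted with a warning — the only consistent
reading of requirements that both reject n < 4 and summarise single-sample
groups.

Group-level relative summaries are robust means of the per-sample relative
values, not the ratio of robust-mean absolute to robust-mean TIC; the
ratio-of-ratios is built from these four robust means. Zero denominators
yield flagged undefined results, never exceptions — under realistic
parameters the least-inflamed groups genuinely have zero trimmed means for
the near-absent markers.

Gestalt output: per group, the five robust-mean relative densities
renormalised to sum to 100 (robust means of percentages need not sum to
100 exactly; the renormalisation is recorded in the output metadata) and
the robust-mean TIC as the height/inflammation axis.

## Rank tests

Per marker and method, a Kruskal–Wallis test (tie-corrected H, chi-square
reference; all-identical data returns p = 1 by convention) gates the 15
pairwise two-sided Mann–Whitney tests at α = 0.05 — the gate level is not
stated in the source and 0.05 is the conventional choice. Exact
Mann–Whitney p-values are used when the smaller group has n ≤ 8 and the
data are tie-free, the tie-corrected normal approximation otherwise.
Benjamini–Hochberg FDR is applied within one method's family (up to 75
tests), separately per method. Because the literature is ambiguous about
whether its significant-test tallies used raw or adjusted p-values, both
counts are reported. (Note BH adjustment is monotone and dominates the raw
p-values but is *not* idempotent; no such property is assumed anywhere.)

## Binary ROC

The AUC is the Mann–Whitney estimator (ties half-credited), so
AUC = U/(n₁n₂) holds exactly against the rank-test module. AUCs below 0.5
are "corrected" to 1 − AUC with a reversal flag; with the relative method
a reversal means the higher expression moved to the less inflamed group.

Inference: DeLong structural-component variance, Wald 95% CI, two-sided p
against 0.5. The CI method is a package choice (the source does not state
one); DeLong is standard and deterministic. With degenerate variance
(AUC exactly 0 or 1) the CI falls back to a stratified bootstrap
percentile interval (2000 resamples, seeded per comparison) and the
p-value to the exact Mann–Whitney p. Significance = CI excluding 0.5 AND
BH-adjusted p < 0.05 within the method family. Medians over even counts
use the midpoint convention.

The difference analysis subtracts corrected AUCs (absolute − relative) per
marker × pair; values strictly above 0.17 are outliers and [−0.07, 0.17]
is the agreement band (comparisons are ε-guarded at 10⁻⁹ so printed
two-decimal values sit on the correct side). Outlier counts on the
uncorrected-AUC basis are also emitted, because published outlier tallies
appear to have used uncorrected values and the two bases disagree for
reversed comparisons; no numeric claim is attached to either count.

## Multicategory ROC (HUM)

HUM = P(X₁ < X₂ < … < X_M) for one draw per class in severity order,
estimated by the U-statistic over cross-class tuples: exhaustive when the
tuple count is ≤ 10⁷ (the default cohort gives 6.4 × 10⁶ — feasible in a
few seconds as a vectorised broadcast), Monte Carlo with a seeded 5 × 10⁵
draws otherwise. A non-decreasing tuple containing ties is credited
1/∏(run length)! — the number of distinct strict orderings consistent with
the ties — which makes a constant marker score exactly the analytic null
1/M! and reduces HUM to the two-group AUC at M = 2. HUM is invariant under
strictly increasing transforms of the feature.

Marker+TIC combinations need a bivariate → scalar reduction, which the
source literature delegates to external methodology without specifying.
The default here: leave-one-out diagonal-Gaussian class-conditionals with
empirical priors (variance floor 10⁻⁹ · range²), posterior over the M
classes, score = Σ rank·posterior; HUM of the scores. This preserves the
1/M! null. Caveat: the reduction is only a *monotone* function of a single
duplicated feature when classes are roughly homoscedastic, so
HUM(combined TIC, TIC) equals HUM(TIC) exactly only for monotone reduction
rules; a `reducer` hook accepts alternatives. Rankings list features by
descending HUM, ties broken lexicographically, the null row appended last.

## Naive Bayes and wrapper selection

Gaussian naive Bayes per feature and class, empirical priors, per-feature
variance floor 10⁻⁹ · (training range)², features on their natural scales
(naive Bayes is scale-equivariant per feature). Every sample is predicted
by a model fitted on the remaining n − 1 (LOOCV); classes with a single
sample are rejected. The wrapper is deterministic best-first forward
search scored by LOOCV accuracy, starting from the empty subset
(priors-only classifier), stopping after five consecutive non-improving
expansions; ties prefer smaller subsets, then canonical feature order —
the documented defaults of the classical data-mining workbench this
protocol follows. Feature selection is performed once on the full data
set, not refolded inside the cross-validation; the reported wrapper
accuracies are therefore optimistically biased, as in the original
protocol.

## Synthetic cohorts

Each (group, marker) density is zero with probability p₀ and otherwise
log-normal(μ, σ); σ = 0.9 throughout gives the heavy right skew and large
variance characteristic of these data, and zero-inflation models true
absences of whole cell classes. Parameters are chosen once to encode the
qualitative group pattern — CD68/CD3 dominate the infiltrates of N and
Orth.A; CD15/CD20/CD38 are near-absent there (p₀ ≥ 0.85); the humoral
markers appear in a *subset* of OA via p₀ = 0.5 (a mixture, not a latent
subgroup); all markers are elevated in EA/RA/SeA with TIC rising
monotonically; SeA carries the largest CD15 fraction. No per-sample values
were ever published, so these defaults are plausible, not calibrated, and
no numeric agreement with published per-cohort statistics is claimed.
Randomness uses one master seed with per-(group, marker) substreams keyed
by stable name hashes, so removing a group never shifts the other draws.

What passing tests on synthetic cohorts demonstrate: correctness of the
estimators and the qualitative regime (absolute medians above relative,
TIC first by HUM, absolute classification at least as accurate as
relative) under the stated generative assumptions. What they do not
demonstrate: any property of real synovial tissue — the generator has no
within-joint spatial heterogeneity, no correlation between markers beyond
what the group structure induces, no measurement error model, and
marker-level parameters that were never fitted to data.

## Problem sizes and numerical conventions

Default analyses run at the study group sizes (93 samples), where the
exhaustive HUM estimator and the full pipeline complete in well under a
minute. Oracle-equivalence tests use small instances (tuple counts ≤ 500,
6 samples per group for exhaustive wrapper enumeration); null-recovery
simulations use 2000 Mann–Whitney replicates and 50 label permutations at
8 samples per group. Result tables round-trip through CSV at 12
significant digits; reports serialise with sorted keys and are
byte-identical across runs at fixed seeds.
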