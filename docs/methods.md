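# Methods

This note documents the models, estimators, defaults and numerical choices
behind `mistkit`, and what the synthetic-data tests do and do not establish.

## Scoring model

Responses are binary labels (real/fake) on a bank whose answer key is known.
V, r, f are counts of correct judgments; the bias scores are defined as

- d = max(0, #fake-labels − k_fake)  (distrust: labeling too much as fake),
- n = max(0, #real-labels − k_real)  (naïvité: labeling too much as real).

These count-based definitions enforce V = r + f and d·n = 0 exactly, and
d − n = f − r on balanced banks. Published summary tables that report both
d/n and f/r means can violate the latter identity when the bias scores were
computed on a different item set than the detection scores; the identity is
a mathematical consequence of any per-respondent count definition, so this
package does not attempt to reconcile such tables and keeps the definition
above.

Missing data: strict mode (the default) refuses to score incomplete rows.
Permissive mode scores answered items only and reports a prorated V
(V · k / answered); nothing is imputed. Percentile lookups are exact grid
reads on the packaged 0–100-by-5 norm tables; the inverse lookup returns the
*largest* grid percentile whose norm score does not exceed the observed
score (the grids repeat scores across percentiles, so a tie convention is
required).

## Item banks

Three banks are packaged: the 20-item full scale with 3PL a/b per item, the
8-item short form (a subset of the full scale), and the 16-item
graph-selected scale with four content dimensions (5/5/3/3). Items belonging
to several banks are stored once in a shared registry with per-bank ordered
id lists. The 16-item bank's veracity keys follow its dimension content
(dimensions 1 and 4 are real-news headlines, 2 and 3 fake-news), recorded in
the fixture metadata. Guessing is stored explicitly as c = 0.5 for every
calibrated item. Bank JSON is UTF-8 and headlines keep their original
punctuation.

## 3PL model

The logistic metric is used without the historical 1.702 scaling constant,
matching mainstream IRT software. Item information is
I(θ) = a²(Q/P)((P−c)/(1−c))²; with c = .5 this peaks at a²/12 at θ = b.

**EAP scoring** integrates a N(0,1) prior over 61 equally spaced nodes on
[−6, 6]; this agrees with a 10⁵-point dense-grid oracle to better than 1e−3.

**Calibration** is marginal maximum likelihood via EM on the same quadrature
grid. a, b are free per item within box constraints (a ∈ (0.05, 10],
b ∈ [−6, 6]); c is fixed (default 0.5). No priors are placed on a or b.
Convergence: max |Δparam| < 1e−4 or ΔLL < 1e−6, at most 500 cycles; the
marginal log-likelihood trace is non-decreasing by construction. Calibration
for the two-factor design is per veracity class (real and fake items fitted
as separate unidimensional models); the two-dimensional test-information
surface is reported descriptively as the sum of the two unidimensional
surfaces. Whether a joint multidimensional fit would match is not claimed.

A note on recovery precision: at n = 2000 with 10 items and c = .5, the
unpenalized MLE of the discrimination has substantial sampling error
(RMSE ≈ 0.3–0.6 across seeds, with a right-skewed error distribution),
because the guessing floor halves the usable probability range. Difficulty
recovers much more precisely (RMSE < 0.1). A shrinkage prior on a would
reduce this error but is deliberately not the default.

**DIF** uses the anchored likelihood-ratio test: the constrained model
calibrates both groups jointly with equal parameters; the free model lets
the studied item's (a, b) differ by group (two extra parameters, df = 2)
while the other items anchor the scale. Flagging is at α = .05, uncorrected.
Continuous grouping covariates are median-split.

## Classical engine

**Tetrachoric correlations** are pairwise maximum likelihood under a latent
bivariate normal: thresholds from the margins, ρ by a vectorized 401-point
grid search with quadratic refinement of the profile likelihood. The
bivariate normal CDF is computed from Owen's T function (machine precision
against direct integration). Zero cells receive +0.5 continuity correction.
The matrix is eigen-clipped to positive definite and rescaled to unit
diagonal when needed (flagged as smoothed).

**Parallel analysis** compares observed tetrachoric eigenvalues with
per-rank 95th percentiles from null datasets formed by independent column
permutations of the observed matrix — this preserves the binary margins,
keeping the null eigenvalues on the same tetrachoric scale. Retention is the
leading run of ranks above threshold. Per-rank thresholds are used
throughout rather than a single common cutoff.

**EFA** runs on the (smoothed) tetrachoric matrix. PAF iterates
communalities from squared multiple correlations (max Δh² < 1e−3, ≤ 100
iterations); ULS minimizes squared off-diagonal residuals over uniquenesses.
Varimax uses Kaiser row normalization; promax (power 4) provides the oblique
pattern and factor correlation when needed. Heywood cases are clipped to
h² = 1 and flagged.

**Reliability.** α is the covariance formula on 0/1 items (KR-20). The
α-pruning loop removes one item per iteration — the one whose deletion
raises α the most, if the gain exceeds .001 — and never removes an item
whose deletion would lower α. Item-total correlations are corrected (item
excluded from the total). McDonald's ω comes from a two-factor promax EFA
followed by Schmid–Leiman orthogonalization: the higher-order loading of
each first-order factor on the general factor is √φ₁₂; ω_g = (Σg)²/ΣR and
the group-factor ω values are computed on each subscale's items. The
decomposition can be computed on Pearson correlations (observed 0/1 scale,
the conventional reporting choice, attenuated by dichotomization) or on
tetrachorics (latent scale); tests validate the latter against the
closed-form (Σg)²/Var_total of the generating bifactor model.

## Network engine

**Network estimation**: graphical lasso over a log-spaced path of 100
penalties from the largest absolute off-diagonal correlation down to 1% of
it; per penalty EBIC = −2·loglik + E·log n + 4γE·log p with γ = 0.5 and E
the edge count; the minimal-EBIC model is returned as partial correlations.
The inner solver is scikit-learn's graphical lasso; the path, EBIC and
selection are this package's. The path iterator stops after 20 consecutive
penalties without EBIC improvement (the criterion is past its minimum on the
densifying path); a λ = 0 override reproduces the unregularized
inverse-correlation conversion exactly.

**Dimensions** come from Walktrap (4 steps, the algorithm's customary
default) on the |partial correlation| weighted graph; singleton communities
are merged into the community with the largest summed connection strength.

**Network loadings**: the raw loading of item i on dimension d is its summed
absolute edge weight to d's members; each dimension's column is divided by
the square root of that dimension's total within-strength, and the sign of
the dominant edge sum is restored. On simulated data with factor loadings
.40/.55/.70 the resulting loadings fall near the published low/moderate/high
anchors (.15/.25/.35) and are strictly ordered; the standardization is a
reconstruction of the published scheme validated by these anchors, not a
line-by-line port.

**Redundancy** (unique variable analysis): weighted topological overlap
wTO_ij = (Σ_u a_iu a_ju + a_ij)/(min(k_i, k_j) + 1 − a_ij) on absolute
weights; pairs with wTO ≥ 0.25 are flagged, and the member with the higher
main-to-cross loading ratio is suggested for retention.

**Bootstrap** (parametric): replicates are continuous multivariate-normal
draws from the smoothed empirical tetrachoric matrix, re-analyzed with
Pearson correlations — a deliberate simplification relative to re-binarizing
(documented, since the empirical data are binary). Replicate communities are
aligned to the empirical partition by maximal Jaccard overlap (ties: larger
intersection, then lower label). Item stability is the proportion of
replicates placing an item with its empirical dimension; structural
consistency is the proportion reproducing the dimension's item set exactly.

**TEFI**: with von Neumann entropies H(M) = −Σ λ̃ log λ̃ of trace-normalized
correlation (sub)matrices, TEFI = (mean_d H_d − H_total) +
(H_total − Σ_d H_d)·√K. Lower is better. Label invariance and the
true-partition-minimal ordering on planted block structures are the tested
properties; absolute TEFI values depend on the data and are not anchored.

## Selection pipeline

Stage order: (i) iterated two-factor EFA, removing *all* items whose largest
absolute loading is below .40 each iteration until none remain; (ii) a
cross-loading screen at .30; (iii) a 3PL-based communality filter
(λ = (a/1.702)/√(1+(a/1.702)²), h² = λ², cut at .40), iterated;
(iv) α pruning; (v) an optional DIF screen removing items flagged on any
grouping. The final selection formalizes "high discrimination across a wide
difficulty range" as greedy binning: per veracity class, difficulties are
split into n-per-factor equal-width bins and the highest-a candidate
(subject to a ≥ a_min) is taken per bin, falling back to the nearest unused
candidate when a bin is empty. This binning rule is a documented
reconstruction — the goal ("a diverse set of difficulties") admits many
algorithms. Content/topic diversity is out of algorithmic scope and is
surfaced as a manual checklist.

## Synthetic respondents

θ_V ~ N(0,1); θ_r = γ_r θ_V + √(1−γ_r²)ε, θ_f likewise (defaults
γ_r = γ_f = 0.8, a typical strong higher-order structure). Real items are
answered from θ_r, fake items from θ_f, each via the 3PL curve with c = .5.
A response-bias mixture replaces each response with probability τ by a pure
label draw ("fake" with probability π); bias acts per item-response by
default so intermediate d/n values arise (a respondent-level mode exists
behind a flag). Default generating a/b ranges mirror the calibrated
full-scale bank (a ∈ [2, 8.6], b ∈ [−1.3, 0.53]). Item pools use a
thresholded factor model with planted good/junk/cross-loaded items and
redundant pairs sharing a minor factor; every planted property is returned
as ground truth. A single seeded generator drives all draws; identical seeds
give byte-identical outputs.

What the generator does *not* emulate: panel demographics, item-content
effects, careless responding beyond the bias mixture, or longitudinal drift.
Passing recovery tests on these data shows the estimators are correct under
the stated model, not that real survey data satisfy the model.

## Evaluation utilities

Paired tests report the repeated-measures t per dimension, the mean
difference with its t-interval, d_z = M_diff/SD_diff (so t = d_z√n) with a
noncentral-t confidence interval, and d_av = M_diff/mean(SD_pre, SD_post).
d_z is the default effect size; published intervention tables whose
M_diff/d ratios imply SD_diff ≈ 0.8 are consistent with this choice, but the
exact published variant is not stated and this is a reconstruction. If pre
and post are identical the result is the null result (t = 0, p = 1) rather
than an error; a nonzero constant difference raises a degenerate-variance
error. No multiple-testing correction is applied across the five dimensions
by default (a Holm option exists in the caller's hands via the returned
p-values).

Power: the two-sample t solver inverts the noncentral-t power function by
bracketing and Brent's method (e.g. d = 0.25, α = .05, power = .90 → 337.2
per group, ceiling 338); the correlation solver uses the Fisher-z
approximation n = ((z_{1−α/2}+z_power)/atanh r)² + 3 (r = .15 → 463;
r = .10 → 1046.7, which rounds up to 1047 — a published value of 1046 for
this calculation is the truncated real solution, and the ceiling convention
is kept here). Incremental validity standardizes all variables and reports
adjusted R² for base and full OLS models with the coefficient table.

## Problem sizes used in tests and the acceptance script

Chosen to exercise each property at the smallest informative scale:
parallel-analysis nulls at 100 permutations (default 500); bootstrap EGA at
100 replicates (30–40 in unit tests; default 500); the selection pipeline's
multi-seed property on a 32-item pool (24 good / 6 junk / 2 cross-loaded,
n = 600, 5 seeds); DIF power at n = 500 per group, 8 items; calibration
recovery at n = 2000, 10 items; tetrachoric recovery at n = 10⁴.

## Known limitations

- No multidimensional IRT estimation, 1PL/2PL/graded models, or CFA/SEM fit
  indices; confirmatory modeling is left to SEM software.
- Tetrachorics are pairwise ML, not joint; for near-deterministic tables the
  estimate saturates at ±0.999.
- ω estimates inherit EFA rotation indeterminacy; on unidimensional data the
  forced two-factor decomposition attributes a little variance to
  pseudo-group factors.
- The network bootstrap's continuous replicates slightly understate binary
  sampling noise at extreme margins.
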