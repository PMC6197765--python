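# Methods

## Data model

The statistical unit is the replicate-aquarium mean, not the individual
animal: crabs sharing a tank are not independent, and averaging per
aquarium avoids pseudo-replication. The default design has 3 replicate
aquaria per (treatment × time) cell over {control, C1, C2} × {7, 14, 21} d,
plus 3 control-only units at time zero (animals sampled from the
acclimation stock before exposure) — 30 units in all, so a 3-unit holdout
is 10% of the data.

For the discriminant analysis the dependent variable is the
**pooled-control grouping**: all control units (every time, including time
zero) form one level representing natural variation in unexposed animals,
and each exposed (concentration × time) cell is its own level — 7 levels by
default. Whether time-zero units belong in the pooled control is genuinely
open; they are included by default and the choice is a config switch
(`include_time_zero_in_pool`).

## Synthetic data generator

The generator draws each biomarker as
`x = μ_b + σ_b · (main-effect shift + interaction deviation + noise)`,
with noise multivariate normal on the measurement scale (diagonal SDs,
optional common correlation). Baselines are plausible green-crab activity
levels with ~15% between-aquarium CV. Gaussian noise on the raw scale (not
log) matches how such activity data are analysed in practice; biomarker
activities at these CVs are far from the zero bound, so the positivity
issue log-normals would fix does not arise.

**Interaction-only signals.** The generator's defining feature is a signal
carried *only* by a biomarker product. For a planted k-tuple (k = 2 or 3)
with product shift Δ, each unit in the affected cell receives deviations
`s_i · d` with `d = |Δ|^(1/k)` SD, where the sign vector `(s_1..s_k)` is
drawn uniformly from `{−1,+1}^k` conditioned on the parity
`Π s_i = sign(Δ)`. Under this parity coding every `s_i` is marginally
symmetric and every sub-product of fewer than k signs has mean zero, so

* every marginal group mean is **exactly** preserved,
* every lower-order product mean is exactly preserved (for k = 3 the signs
  are pairwise independent),
* `E[Π x_i]` shifts by exactly `Δ · Π σ_i`.

An earlier design (one shared latent sign with group-dependent
`P(s = +1)`) shifts the marginals unless re-centred and attains a smaller
third moment after centring (max `0.77·d³` vs `d³`); the parity coding is
the cleaner construction and is what the closed-form expectations
(`EffectSpec.expected_marginal_mean` / `expected_product_mean`) describe
and the Monte-Carlo tests verify at n ≈ 10,000.

The price of a *detectable* pure-interaction signal is marginal **variance**
inflation (`+d²σ²` in the affected cell). This is unavoidable: a signal
that also preserved unit variances would have its third cross-moment
bounded by `E|z|³ ≈ 1.6 σ³` (the normal-marginal extremal case), which is
undetectable against a product-SD of ≈ 1σ³ with 3 units per cell. The
default scenario accepts the variance inflation and keeps the means null.

**Default effect size.** The reference scenario plants the
(AChEg, GPx, LPOdg) triple — neurotransmission, antioxidant defence and
oxidative damage responding as one axis — on the high concentration with
progressive couplings 2.0 / 2.5 / 3.0 SD at 7 / 14 / 21 d (product shifts
8 / 15.6 / 27 σ³). The sizes were fixed once, by a power pilot run before
the acceptance suite existed, to the weakest progressive ladder that gives
the stepwise selection reliable (≳85%) recovery of the planted triple at
the 30-unit design; they are comparable in strength to the near-perfect
first canonical roots such studies report. The `separable` scenario
displaces each exposure cell 16 SD along its own dedicated marker axis
(a classifier-realizable, perfectly separated configuration); `null` is
pure noise.

What the generator does **not** emulate: tissue-specific covariance
structure, non-normal tails, dose–response continuity between C1 and C2,
bioaccumulation kinetics, or feeding-behaviour time series. Passing tests
therefore demonstrate the *machinery* — recovery of planted interaction
structure under honest noise — not field realism.

## Univariate screening

Levene's test uses the original group-**mean** centre (the legacy default
of the commercial package such studies used), delegated to
`scipy.stats.levene(center="mean")`. Note the classical W is only
asymptotically F-distributed: at aquarium-scale group sizes (e.g. 6 groups
of 5) its true type-I rate is ≈ 0.10 at nominal 0.05. Calibration checks
are therefore run at group sizes (~50) where the F reference applies; at
study scale the test should be read as descriptive.

The two-way ANOVA is the classical balanced decomposition (on a balanced
grid, Type I/II/III sums of squares coincide). Imbalance beyond an empty
or unequal cell is refused with an explicit error rather than silently
reinterpreted — the printed df patterns of such studies ((2, 18) and
(4, 18) for a 3×3×3 grid) imply balance, and the balanced closed form
vectorises across thousands of simulated datasets for calibration. The
time-zero baseline cells are excluded from the factorial grid (they exist
only for controls; a crossed analysis is defined on exposure times only).
The implementation is cross-checked in the tests against a plain-Python
sum-of-squares oracle and against `statsmodels.stats.anova_lm`.

Duncan's multiple range test compares ordered means r apart against the
least significant range built from the studentized range quantile at
protection level `1 − (1−α)^(r−1)`, with quantiles computed numerically
(`scipy.stats.studentized_range`) so any error df is supported, and the
harmonic mean n for unequal group sizes. The step-down rule never
subdivides a window already declared homogeneous; letters mark maximal
homogeneous windows, so they always form contiguous runs over sorted means.
Zero within-group variance raises a degenerate-data error (the profile
layer maps an exactly-constant predictor to a single homogeneous group
instead).

## Interactive predictors

Products are unordered 2- and 3-tuples of distinct biomarkers — no squares
or cubes — in canonical order (singles, pairs, triples; lexicographic
constituents), labelled `"A x B x C"`. By default each biomarker is
z-scored across all units *before* multiplication: raw activities span two
orders of magnitude across the battery, and products of raw values would be
dominated by the large-scale markers. Whether to multiply raw or
standardized values is not settled practice; the raw alternative is kept
behind `standardize_first=False`.

## Canonical DFA with forward entry

Scatter matrices W (within), B (between), T = W + B are computed per group;
the eigenproblem `B a = λ W a` is solved with the symmetric-definite
generalized eigensolver; coefficients are scaled so canonical scores have
unit pooled within-group variance (which makes canonical-space Euclidean
distance a Mahalanobis distance). Standardized coefficients are raw
coefficients × pooled within-group SD. The sign of a canonical axis is
arbitrary; each function is oriented so its largest-|coefficient| predictor
is positive, making coefficient tables, clustering and trajectories
reproducible.

Forward entry: with q predictors in the model, each candidate's partial
Wilks' Λ is the ratio of Schur-complement pivots of W and T on the selected
block (one Cholesky factorization per step, vectorized over candidates);
the F-to-enter is `F = ((n−g−q)/(g−1)) · (1−Λr)/Λr` on `(g−1, n−g−q)` df.
The best candidate enters while its p-to-enter < 0.05; ties break by
canonical column order. There is no backward step. Guards: a
tolerance floor of 1e-7 on the within-matrix pivot (the classical stepwise
tolerance against collinear entry) and a hard cap `q ≤ n − g − 1` (the
within-scatter rank bound — the cap must sit close to the bound, since real
models of this kind retain ~20 predictors from 30 units). "Significant
roots" is the maximal leading run of Bartlett tests with p < 0.05
(sequential testing, the classical convention). An empty model (nothing
enters) is returned flagged, not raised; classification then falls back to
priors. Classification-function ties resolve to the higher prior, then to
group order.

## Cross-validation

Each round draws a random 3-unit holdout (without replacement within a
round, independently across rounds; a draw leaving any group with < 2
training units is redrawn and counted), reruns the **entire** stepwise
selection on the remainder, and classifies the held-out units with the
recalculated model — the only protocol in which the validation percentages
carry no leak from the full-data fit. The default 54 rounds × 3 units give
162 validation classifications. No exact partition (k-fold) is assumed.

**Known property: null-data pessimism.** On label-permuted (null) data the
validation percent-correct of *any* classifier fitted to the training
labels sits systematically **below** chance at these group sizes (measured
≈ 9.5% vs 14.3% chance for 7 balanced groups of 4): the held-out unit's own
group always loses at least one training member, so its prior shrinks and
its centroid estimate is noisier than its competitors'. The same bias
appears with an independent LDA implementation under the identical
resampling scheme, while a label-independent classifier scores exactly at
chance — it is a property of the estimator, not of this implementation, and
it errs in the conservative direction: repeated-holdout validation will
under-, never over-state diagnostic power on structureless data.

## Interpretation layer

Explained variance per root is `100 · λᵢ/Σλ` (cumulative sums to exactly
100 pre-rounding). Predictor clustering uses Euclidean distance on the
standardized coefficients over the significant functions with UPGMA
(average) linkage — distance and linkage are conventions, configurable, not
reconstructions of any particular prior analysis; the dendrogram is
exported as Newick with branch lengths from merge-height increments. The
integrated response index is the canonical-space distance of each exposure
cell's centroid from the pooled-control centroid (zero for control by
construction); per concentration, a distance that keeps growing over
{7, 14, 21} d is reported as *progressive*, a decline from an earlier peak
as *recovery-consistent* (acclimation). The index formula is this
package's definition of an integrated response, documented as such.

## Numerical and reporting choices

* All stochastic steps take a mandatory integer seed; identical
  (config, seed) reproduces every output byte-for-byte, verified by SHA-256
  checksums in the run manifest.
* Two toxicants are always two independent runs, never one joint model;
  a config switch refits without the lowest concentration (4-level
  grouping), the usual variant when low-dose cells add noise but no
  separation.
* Degenerate paths are explicit: zero error variance → F = ∞ with a flag;
  empty stepwise model → flagged model, interpretation skipped with a
  notice; singular within-scatter → error instructing a lower predictor
  cap.
* Reports embed the thresholds used (p-enter, alpha), so every table is
  self-describing.

## Limitations

The Bartlett chi-square approximation is unreliable when N ≤ p + g (a
warning is emitted; with ~20 retained predictors on 30 units the root
p-values are indicative, not exact — the cross-validation, not the root
tests, is the honest measure of such a model). Forward entry at a fixed
p-to-enter over 129 candidates is a multiple-testing procedure: on pure
noise it still admits predictors (min-p over ~127 correlated partial tests),
so selected-predictor counts must not be read as evidence by themselves.
Validation accuracy, not training accuracy, is the performance claim; the
null-data pessimism above means even that is conservative.
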