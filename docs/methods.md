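# Methods

This note documents the statistical conventions, default parameters and
design choices behind `odorqspr`, and what the synthetic-data tests do and
do not demonstrate.

## Response and curation

The response is log10 of the odor threshold in nmol. Log base 10 is used
because published wine-odorant thresholds on this scale span roughly −0.6
to 7.3 and the base is the community convention for threshold data. When a
compound is reported by several sources, averaging is done on the log scale
(the scale on which the response is modeled); the concordance window
`delta_max` defaults to 1.0 log-unit — sources differing by more than a
factor of ten are treated as discordant and the compound is excluded rather
than imputed. Both choices are configurable; no unit conversion from mass
concentration is attempted, inputs must already be nmol (or pre-computed
log(OT)).

## Descriptor pre-filtering

Three ordered passes: (1) any column with a missing value is removed
(removal, not imputation — descriptor values are deterministic functions of
structure, so a missing value signals a computation failure, not noise);
(2) columns with SD < 10⁻⁴ carry no information; (3) of every pair with
|Pearson r| ≥ 0.95 the later column in file order is removed. Which member
of a correlated pair survives is arbitrary in principle; keeping the earlier
column makes the operation deterministic and idempotent, and the removal log
records every decision. All standard deviations in the package use the n−1
denominator, matching the validation statistics.

## Rational train/test division

"Rational" division clusters autoscaled descriptor space so that the test
set spans the same chemistry as the training set. The k-medoid variant is
PAM: greedy BUILD initialization followed by best-improvement SWAP passes;
total cost (summed Euclidean distance to assigned medoids) is non-increasing
by construction and asserted per pass. Ties are broken by row order, making
the result deterministic; the seed parameter is accepted for interface
symmetry. Six clusters and a 25% test fraction are the defaults. Within each
cluster, members are ranked by distance to the medoid and round(0.25·size)
of them are taken at evenly spaced ranks — a deterministic systematic sample
across the cluster's spread. (A stepped every-k-th rule was considered but
floors each cluster's contribution and systematically undershoots the target
fraction on realistic cluster-size profiles.) Medoids always remain in
training; singleton clusters contribute no test compound.

## GFA

Candidate equations are ordered term lists; each term is a descriptor or a
truncated spline ⟨a − x⟩ with the knot restricted to observed training
values of that descriptor (the restriction keeps the search space finite and
mirrors how spline knots are placed in adaptive-regression practice).
Equations are least-squares fitted and scored by Friedman's lack-of-fit

    LOF = LSE / [1 − (c + d·p)/M]²

with c the number of basis terms, p the number of fitted parameters
(intercept, slopes, and one per spline knot), M the training-set size and d
the smoothness penalty (default 1.0). An over-parameterized equation
(denominator ≤ 0) scores +∞. Evolution is steady-state: two parents chosen
by independent size-2 tournaments on LOF, single-point crossover (prefix of
one parent, suffix of the other, duplicates dropped), mutation with
probability 0.5 drawn uniformly from {add, delete, replace-descriptor,
re-sample knot, toggle linear/spline}, child replaces the current worst
individual. The best LOF is therefore non-increasing over iterations.
Defaults: population 100, initial equation length 4, no length cap,
5000 iterations, mixed linear+spline populations (pure-linear or pure-spline
runs are available via `term_kind`).

The descriptor pool passed on is the union over the five best equations.
Spline terms keep their fitted knots and enter the next stage as fixed
transformed columns; terms that are degenerate on the training rows (a knot
at the observed minimum truncates to all zeros) or near-duplicates
(|r| ≥ 0.999) are dropped at the hand-over.

## Best-subset refinement

All C(p, 6) six-descriptor OLS models over the pool are enumerated —
batched normal-equation solves over precomputed cross-products make the
C(32,6) ≈ 9.1·10⁵ case run in a few seconds on one core; a configurable cap
(2·10⁶) guards against accidental explosions. Models are ranked by the
trimmed-MAE quality class of their validation-set predictions (good <
moderate < bad), then by the trimmed MAE, then lexicographically (for
determinism on ties). Following the study protocol the validation set is the
held-out test set; because ranking on the final test set is statistically
contentious, `subset_ranking="internal"` instead carves a response-ranked
systematic validation subset out of the training set, leaving the test set
untouched until final validation. The final PLS pool is the union of the top
five subset models.

## PLS

Single-response NIPALS on autoscaled X and standardized y: per component
w ∝ Xᵀy (normalized), t = Xw, p = Xᵀt/(tᵀt), q = yᵀt/(tᵀt), then X and y are
deflated. The collapsed coefficient vector b = W(PᵀW)⁻¹q is back-transformed
to original units; predictions via b and via the latent route agree to
machine precision and the training scores are mutually orthogonal. The
latent-variable count maximizes leave-one-out Q², computed by full honest
refits — every fold re-estimates all scaling parameters on its n−1 rows;
anything less inflates Q². Ties prefer fewer components. The search is
capped at K−1 components so at least one residual X-dimension remains for
the applicability domain.

VIP_j = √(J · Σ_f SSY_f (w_jf/‖w_f‖)² / SSY_total) with SSY_f the y-variance
explained by component f; mean VIP² = 1 identically.

## Applicability domain

DModX_i = s_i/s0 with s_i² = Σ_k e_ik²/(K−A) and
s0² = ΣΣ e²/((N−A−1)(K−A)) pooled over the training residual matrix. The
critical limit is

    d_crit = sqrt( F(1−α; K−A, (N−A−1)(K−A)) · N/(N−A−1) )

at α = 0.01 by default. The factor N/(N−A−1) is a finite-sample correction
compensating that s0 is estimated from the same training residuals that the
model has already shrunk; without it the limit is biased low for small N.
With it, the limit for the reference geometry N = 64, K = 7, A = 3 is 1.90,
consistent (within the uncertainty of proprietary degrees-of-freedom
conventions in commercial SIMCA-type software) with published values near
2.2 for that geometry. Hotelling T² uses training-score variances with the
limit A(N²−1)/(N(N−A))·F(0.95; A, N−A).

## Y-randomization

The response is permuted (default 100 times), the PLS model refitted at the
chosen component count, and R² and LOO-Q² recorded along with |corr(y,
y_perm)|. Straight lines of R² and Q² against |corr| — including the
unpermuted model at corr = 1 — give intercepts R²int and Q²int; the model is
chance-robust when R²int < 0.4 and Q²int < 0.05. Note the test detects
*chance correlation* (permuted models nearly as good as the real one), not
poor fit: a weak model with honestly low R² can still pass, which is the
intended behavior of the intercept criteria.

## Validation metrics

R²pred (Q²F1) normalizes test SSE by deviations from the *training* mean,
Q²F2 by the *test* mean; CCC is Lin's concordance in the n-denominator
moment form. The rm² family is computed by default on min-max scaled
vectors (the recommendation of the metric's literature); the raw-scale
variant — used by the Golbraikh–Tropsha checks — is available via
`scaled=False`, and both Δrm² variants are reported since conventions vary.
Thresholds: 0.5 for Q², rm² means, R²pred and Q²F2; 0.750 for CCC; 0.2
ceiling for Δrm²; Golbraikh–Tropsha requires r² > 0.6, an origin-forced
ratio (r²−r0²)/r² < 0.1 in at least one direction, and an origin-forced
slope k or k′ in (0.85, 1.15). The MAE criteria drop the 5% largest absolute
errors (count rounded half up), then classify against the training response
range R: good if MAE ≤ 0.1R and MAE+3σ ≤ 0.2R; bad if MAE > 0.15R or
MAE+3σ > 0.25R; moderate otherwise (σ = SD of the retained absolute
errors, n−1 denominator).

## Composite wines

Averaging happens on the model's final descriptor columns *after* spline
transformation: splining a mean is not the mean of splines, and the
composite value of a model descriptor is only well defined on the columns
the model actually uses. Consequently the composite prediction is exactly
the weighted mean of the per-component predictions — a property the tests
assert to 10⁻¹⁰. Weights default to uniform; concentration weighting is
supported but not assumed, since composition tables rarely state it.

## Synthetic data generator

`make_study` draws descriptor blocks from a one-factor Gaussian model
(x = √ρ·z_block + √(1−ρ)·ε, pairwise within-block correlation ρ), appends
constant, near-constant (SD ≈ 10⁻⁵) and missing-value columns, and builds
the response as intercept + Σβ·term(x) + N(0, σ). Defaults: 85 compounds,
60 descriptors in 6 blocks with ρ = 0.7, two constant/near-constant/missing
columns each, intercept 3.0 (mid-range log-nmol), noise SD 0.5, and four
planted effects — two linear (β = 1.2, −1.0) and two splines (β = 1.5,
−1.2) with knots at the within-sample median so the truncation is active
for about half the compounds. The planted descriptors are auto-placed in
four *distinct* correlation blocks: with two signal carriers inside one
ρ = 0.7 block the "true" set is not identifiable even in principle, and
recovery scoring would be meaningless. These defaults give training R²
around 0.85–0.95, comparable to published wine-odorant QSPR models.

What the generator does *not* emulate: realistic descriptor marginals
(counts, bounded fractions, heavy tails), structural relationships between
descriptors of the same molecule, non-Gaussian noise, or
concentration-dependent mixture perception. Passing tests therefore show
that the chain recovers the class of structure it assumes — not that any
particular chemistry holds.

## Problem sizes and randomness

Tests and the acceptance script run the GFA at 200–2000 iterations and
populations of 60–100, the pipeline on 85-compound studies, Y-randomization
at 10–50 permutations, and best-subset enumeration up to C(32,6); the
package defaults remain at the full study conditions (5000 GFA iterations,
100 permutations). One master seed fans out to per-stage child seeds via
`numpy.random.SeedSequence`, so every stage is independently reproducible
and no global random state is used.

## Known limitations

- Exact reproduction of any published wine-odorant model requires the
  original descriptor tables from commercial software; the package checks
  structural and statistical properties instead.
- The GFA is stochastic; with aggressive down-scaling of iterations it can
  return a correlated proxy (same block) instead of a planted descriptor.
- DModX critical limits depend on degrees-of-freedom conventions that
  differ between software packages by ~15%; the convention here is stated
  above and applied consistently.
- `mae_criteria` needs ≥ 5 errors and `rm2_metrics` ≥ 2 points; metrics on
  very small test sets are reported but statistically fragile.
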