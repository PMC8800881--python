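# Methods

## Scalability coefficients

For items *i*, *j* with integer scores, let `S_ij` be their sample
covariance and `S_ij^max` the maximum covariance attainable by any joint
distribution with the same two marginal category frequency tables.  The
maximum is attained by the comonotonic coupling — sort both score vectors
and pair rank by rank — and is computed in closed form from the overlap
of the two cumulative marginal distributions:

```
S_ij^max = Σ_{x,y} x·y·max(0, min(F_i(x), F_j(y)) − max(F_i(x−1), F_j(y−1))) − μ_i μ_j .
```

Item-pair, item and total coefficients are the ratios of (sums of)
observed to maximum covariances, which yields the ordering
`min(H_ij) ≤ min(H_i) ≤ H ≤ max(H_i) ≤ max(H_ij) ≤ 1` on every data set.
All covariances use the divide-by-N convention; since every coefficient
is a ratio of covariances the convention cancels.  Scores are shifted to
a 0-based coding internally; all coefficients are translation invariant.

Two deliberate edge-case rules: the diagonal of the pairwise table is NaN
(an `H_ii = 1` sentinel invites silent misuse), and items with zero
sample variance are accepted at ingestion but rejected by every
scalability computation (`H` is undefined when a margin is degenerate).

## Standard errors

Every coefficient is a smooth ratio of plug-in functionals of the
empirical distribution of score rows, so we linearise.  For a ratio
`H = A/B` with per-row influence values `a_r` (numerator) and `b_r`
(denominator), the influence of `H` at row *r* is
`ψ_r = (a_r − H·b_r)/B`.  The influence of `S_ij` is the classical
`(x_ri − μ_i)(x_rj − μ_j) − S_ij`; the influence of `S_ij^max`, a
piecewise-linear functional of the two margins, is its one-sided
directional derivative toward the point mass at the row's score pair,
computed exactly (min/max sub-derivative rules at ties of the cumulative
margins; no finite-difference step is involved).

* **One-level** (simple random sampling): `Var(Ĥ) = Σ_r ψ̃_r² / N²` with
  `ψ̃` the centred influence values — the usual sandwich/delta-method
  variance for an i.i.d. mean.
* **Two-level** (clustered sampling): groups are the independent units,
  `Var(Ĥ) = G/(G−1) · Σ_g T_g² / N²` with `T_g = Σ_{r∈g} ψ̃_r`.  Because
  group totals weight automatically by group size, the pooled point
  estimate is exactly the one-level point estimate; with singleton groups
  the two-level SE reduces to the one-level SE times `√(G/(G−1))`.

A nonparametric **cluster bootstrap** (resample G groups with
replacement, recompute every H, SD across replicates; degenerate
replicates redrawn with a cap; fully seeded) serves as the in-repo ground
truth.  The test suite checks the delta-method SEs against the bootstrap
and against the empirical SD of Ĥ over ≥ 1,000 simulated replicates, at
latent ICC 0 and 0.3: the two-level SE tracks the empirical SD to within
a few percent (a small downward finite-G effect remains at G = 30), while
the one-level SE underestimates it by ~20% under clustering.  95% Wald
intervals built from two-level SEs achieve ~0.94 coverage under
clustering (one-level: ~0.90).

## Tests and confidence intervals

* Mokken's Delta statistics (`Δ_ij = S_ij/(S_i S_j)·√(N−1)`, with item
  and total analogues) test marginal independence, one-sided against a
  standard normal; valid only for nonclustered data.
* Wald z tests `z = (Ĥ − c)/SE` test `H ≤ c` against `H > c` for any
  null value; with two-level SEs they are valid for clustered data.
* Range-preserving tests/intervals work on `g(H) = log(1 − H)` with
  `SE_g = SE/(1 − Ĥ)` (delta method); the back-transformed interval can
  never exceed the natural bound `H = 1`.  The test statistic is oriented
  as `(g(c) − g(Ĥ))/SE_g` so that large values favour `H > c`.  The
  logarithmic transform was chosen precisely for bound preservation; a
  different bound-preserving transform would change numbers slightly but
  not the contract (upper CI bound < 1, zero statistic at `Ĥ = c`).
* Tests are one-sided; confidence intervals two-sided (multiplier 1.96 at
  95%).  The default test flavour is Wald: in the realistic range
  `H ≤ 0.7` the range-preserving refinement matters little.

## Item selection

The greedy algorithm: start a scale with the qualifying pair of highest
`Ĥ_ij`; repeatedly add the qualifying item maximising the enlarged
scale's `Ĥ`; recurse on the leftovers.  Criterion evaluation:

* classic AISP — Criterion 1 `Δ_ij ≥ z_crit`; Criterion 2
  `Δ_i ≥ z_crit` **and** `Ĥ_i ≥ c` (point check).  On clustered data
  (level two) the Delta statistics are replaced by Wald z statistics
  against 0, retaining the point check.
* T-AISP — Criterion 1 `z_ij ≥ z_crit` (null `H_ij ≤ 0`); Criterion 2
  `z_i ≥ z_crit` (null `H_i ≤ c`).  For a two-item scale `H_i = H_ij`,
  so Criterion 2 of a starting pair is the pair statistic tested
  against `c`.

Design choices the literature leaves open, fixed here and exposed in the
per-step trace so deviations are auditable:

* **Bonferroni accounting**: one global running counter of criterion
  evaluations (two per candidate pair at scale starts; scale-size + 1 per
  candidate at extensions), incremented by the current step's tests
  before computing `z_crit = Φ⁻¹(1 − α/counter)`.  The counter never
  resets between scales; each lowerbound of a sweep is an independent
  run.
* **Tie-breaks**: first maximum in lexicographic item order, making the
  procedure fully deterministic.
* Degenerate items are reported unscalable (0), never silently dropped.
* One-level selection on clustered data warns loudly: items with large
  within-group dependency get too-small SEs and may be admitted wrongly.

Because the T-AISP tests Criterion 2 instead of point-checking it, an
accepted item always satisfies `Ĥ_i > c`, so at a common critical-value
history the T-AISP never admits an item the classic check would reject —
the procedure is conservative by construction, and the suite verifies the
selected-item sets against an independently coded greedy oracle.

## ICC diagnostics

One-way ANOVA ICC(1) with the unequal-group-size correction
`n₀ = (N − Σ n_g²/N)/(G − 1)`, `F = MSB/MSW` on `(G−1, N−G)` degrees of
freedom.  Negative estimates are reported as computed (truncation is an
opt-in flag) so the F-test logic stays transparent; zero within-group
variance yields an infinite F with a warning.  By design the workflow
computes ICCs only on *final* scales: unscalable items can mask the
dependency a clean scale would show, so there is no pre-selection ICC
screen.

## Synthetic data generator

A multilevel graded response model: latent trait
`θ_gr = τ_g + ε_gr` with `Var(τ) = ρ`, `Var(ε) = 1 − ρ` (total variance
1, `ρ` = latent ICC), cumulative category probabilities
`P(X ≥ k|θ) = logistic(a_i(θ − b_ik))` (probit optional), one or two
latent dimensions with configurable correlation.  Defaults model a
realistic questionnaire study: 30 groups of 20 respondents
(classroom-sized clusters), latent ICC 0.3 (mid-range of the 0–0.5 band
typical of quality-of-life measures), five-category items with
discrimination 1.5 and thresholds spread over [−1.5, 1.5].
`population_H` computes model-implied coefficients by Gauss–Hermite
quadrature (61 nodes; tensor grid with conditional normal factorisation
for two correlated dimensions) and anchors the coverage study's true
value.

What the generator does *not* emulate: missing responses, response
styles (e.g. extreme/midpoint preference), items violating monotonicity,
unequal cluster-level measurement (group-varying item parameters), or
more than two nesting levels.  Passing tests therefore show calibration
under a well-specified NIRT model with exchangeable clusters, not
robustness to those violations.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use reduced but informative
sizes chosen as the package's own verification budget: 1,000 random
matrices for the ordering inequality; exhaustive coupling enumeration for
all 3-category margin pairs with N ≤ 8; ≥ 1,000 simulation replicates for
SE calibration; 400–500 replicates for CI coverage (ICC 0.3, 50 groups of
20); 800–1,000 replicates for test sizes; four 6-item data sets per
selection-oracle comparison.  Monte-Carlo assertions use 3-sigma bands
plus a small slack, and SE-vs-SD comparisons a 10% relative band (the
finite-G bias of cluster-robust variances at G = 30 is a real, known
effect).  All randomness is seeded; the bootstrap is bit-reproducible.

## Known limitations

* The two-level variance is the standard cluster-robust (working
  independence) construction; like all such estimators it is mildly
  downward-biased for small numbers of groups (no small-G correction
  beyond `G/(G−1)` is applied).
* Two-level designs only; three-level or cross-nested sampling is out of
  scope.
* NIRT assumption checks (monotonicity, conditional association,
  non-intersection), reliability estimation and parametric IRT fits are
  downstream analyses not included here.
* Final-scale selection in the workflow is a recorded analyst choice (a
  named lowerbound), not an automated stability statistic.
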