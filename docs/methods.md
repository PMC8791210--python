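# Methods

## Model and solver

One sparse CCA mode is the rank-1 penalized matrix decomposition (PMD) of
the cross-product K = XᵀY of two z-scored blocks: unit-L2 weight vectors u, v
maximizing uᵀKv under L1 bounds ‖u‖₁ ≤ c₁ ∈ [1, √p], ‖v‖₁ ≤ c₂ ∈ [1, √q].
The alternating update is closed-form: u ← S(Kv, δ)/‖S(Kv, δ)‖₂ with S the
soft-threshold operator and δ the smallest threshold satisfying the L1 bound,
found by bisection to 1e-10 on δ (each bisection step is evaluated in
O(log d) from sorted cumulative sums of |Kv|; the resulting weight satisfies
‖w‖₁ ≤ c + 1e-8). The objective uᵀKv is checked non-decreasing at every
iteration, with 1e-6 relative slack covering the finite-precision threshold
search — near-tied problems (exactly collinear columns) oscillate at that
scale without affecting the fixed point.

Choices a reader should know:

- **Initialization** is the leading right singular vector of K (economy SVD),
  so every fit — including the thousands inside permutation and resampling
  loops — is deterministic and bit-reproducible. The `seed` argument is
  accepted for interface uniformity and reserved for optional random
  restarts.
- **Convergence**: max absolute weight change < 1e-6, cap 100 iterations.
  On strong-signal data the fit converges in 3–6 iterations; on pure noise
  in ~20.
- **Sign convention**: CCA modes are sign-indeterminate. We flip v so that
  r = corr(Xu, Yv) ≥ 0, then flip (u, v) jointly so the largest-magnitude
  behavioral weight is positive. Every downstream comparison (loadings,
  LOO, RR, split-half) relies on this or on explicit correlation-based sign
  alignment to the full-sample solution.
- **Degeneracy**: an identically-zero weight vector (possible at extreme
  sparsity) raises `DegenerateFitError`; resampling loops catch it, skip the
  replicate and count it, rather than recording a silent zero mode.
- Only the first mode is fitted; deflation to further modes is out of scope.

## Sparsity selection and inference

`grid_search_sparsity` fits every (c₁, c₂) combination and keeps the one
maximizing in-sample r; exact ties go to the smaller c₁ + c₂ (the sparser
model), then lexicographically. The full r-surface is returned and written
by the pipeline so the selection can be audited — in-sample r need not be
monotone in the bounds.

`permutation_test` shuffles the rows of the behavioral block (the imaging
block fixed), refits at the selected bounds, and reports
p = (# null r strictly greater than observed)/n_perm. The p-value is an
exact multiple of 1/n_perm; with 5,000 permutations its granularity is
0.0002, and an exceedance count of 2 prints as 0.0004. Because each permuted
refit maximizes correlation over all variables, the null is a max-statistic
null and the p-value needs no further multiple-testing correction. Two
documented alternatives are available but off by default: re-running the
full grid search inside every permutation (`retune=True`, the stricter
reading of "the exact same analysis"; fixed-bound nulls are standard
practice and 5,000 grid searches are needlessly slow), and the add-one
(k+1)/(B+1) estimator (`empirical_p` implements the plain k/B that the
0.0004 granularity implies). Permuting Y instead of X (`permute_side="y"`)
gives the same null in distribution and exists as a diagnostic.

## Loadings

Loadings are structure coefficients: Pearson correlations between each
original variable and the *opposing* block's canonical variate. Subgroup
profiles reuse the whole-sample weights — variates are computed once, then
correlated within each group's row subset; there is no per-group refit, so
group differences reflect different alignment of the same mode, not
different modes. A variable constant within scope has no defined
correlation; it is recorded as NaN and flagged, never silently zeroed.
Groups need ≥ 3 subjects.

## Reliability suite

- **Leave-one-out**: for each subject, the remaining rows are re-z-scored
  and refit at the same bounds; the refit (wx, wy), concatenated and
  sign-aligned, is correlated with the full-sample weights. Per-side
  correlations are retained alongside the concatenated one, since either
  could be the quantity of interest.
- **RR-score**: over n_splits random half-splits (group-stratified when
  labels exist, half sizes differing by ≤ 1 overall and per group), fit on
  the training half, compute the test half's concatenated
  variable-to-variate loading vector with the training weights, sign-align
  it to the full-sample loading vector, and correlate each split's vector
  with the elementwise mean over all splits. Scores are floored at 0 so the
  index lives in [0, 1] and summarized by median and sample SD. This
  operationalization is a reconstruction: the original RR-score is defined
  in external work and code we do not reproduce; the version here satisfies
  the properties its descriptions state (range, per-split values, "similarity
  between all test-sets") but may differ in detail. Treat cross-study
  numeric comparisons of RR values with caution.
- **Split-half prediction**: same splits; the held-out half is re-z-scored
  with its own statistics and projected with the training weights; the
  recorded r is the correlation of the held-out variates. Re-standardizing
  the test half is the default because loadings and correlations are
  scale-free; projecting training-standardized rows instead is available via
  `use_own_stats=False`.

All three are exactly reproducible from (seed, n_splits, bounds, data).

## Synthetic data generator

`generate_paired_data` draws, per subject, a shared latent z and builds
X = s·z·wxᵀ + d·u_div·axᵀ + b·F·L + ε (likewise Y), where wx is a sparse
unit vector (default 5 nonzeros, entries bounded away from zero so the
planted support is unambiguous), F·L is a 3-factor within-block nuisance
structure (factor scores drawn independently per block — within-block
correlation must not couple the blocks, or the null case would not be null),
and ε is i.i.d. Gaussian noise.

The group-divergent score is u_div = g·(z + z₂)/√2 with g = ±1 the group
indicator and z₂ an independent second latent. Mixing z into the divergence
score is deliberate: a divergent latent fully orthogonal to z would leave
the first mode's subgroup loading profiles identical in expectation (the
divergent columns would be uncorrelated with the opposing variate in every
group), whereas the mixed score makes the planted divergent variables load
with opposite signs in the two groups — the qualitative pattern of top
variables differing by age group that the generator exists to emulate. This
is an illustrative mechanism, not a biological claim.

Defaults are the emulated study's conditions: 27 + 26 subjects, p = 59
behavioral and q = 86 (structural) or 249 (functional) imaging variables,
support sizes 5, latent strength s = 3 with noise SD 1 (population
correlation of the true variate pair s²/(s²+1) = 0.9 — a strong, clearly
detectable mode), within-block factor scale 0.3, group divergence 1.
Randomness flows from one SeedSequence through named substreams, so the
draw of one component never shifts when another's size changes.

What the generator does **not** emulate: realistic covariance structure of
cortical thickness or FNC features, non-Gaussian marginals, site/scanner
effects, missing data, or any nonlinearity. Passing tests demonstrate the
machinery is correct and calibrated under the assumed model, not that any
particular real dataset contains a reliable mode.

## Problem sizes and numerical settings used by tests

The acceptance checks run at: 50 random 30 × 5 / 30 × 6 instances for the
dense-SVD oracle; 20 replicates at 53 × 59 / 53 × 249 for planted-mode
recovery (threshold |cos| ≥ 0.9 in ≥ 18/20, verified against the truth
record before freezing); 200 null datasets (n = 40, p = 10, q = 12) × 200
permutations for type-I calibration at α = 0.05 against the exact central
95% binomial interval; 500 splits for the signal/noise reliability
contrast; and one full pipeline run at 53 × 59 / 53 × 86 with 5,000
permutations and 5,000 splits. `scripts/acceptance.py` recomputes the same
quantities from a single `--seed`.

## Known limitations

- In-sample maximization over the sparsity grid is optimistic; the selected
  r is not an out-of-sample estimate (that is what split-half prediction is
  for).
- The greedy collinearity filter (drop the later column when |r| > 0.85,
  after a minimum-SD screen) is order-dependent by design — deterministic
  and auditable via the removal log, but a different column order can keep a
  different representative of a correlated cluster.
- Intracranial-volume-style covariate adjustment is OLS residualization on
  [1, covariate]; one defensible reading of "adjusted", not the only one.
- Missing values are a hard error by default (an explicit drop-subjects
  policy is opt-in); no imputation is provided.
- Only two-block, first-mode analysis; no deflation, no structured/fused
  penalties, no kernel variants.
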