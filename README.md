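# sparsecca

Sparse canonical correlation analysis (sCCA) for paired subject-by-feature
tables, with permutation inference, subgroup loading profiles and a full
reliability suite — built for brain–behavior covariation studies where a
behavioral-health block (demographics, cognition, lifestyle, metabolic
measures) and an imaging block (morphometry, activation peaks, functional
network connectivity) are measured on the same modest-sized sample and the
question is *which variables on each side move together, and how stable is
that pattern?*

## The model

Given row-aligned, z-scored blocks X (n × p, behavioral) and Y (n × q,
imaging), one sCCA mode is the penalized rank-1 decomposition of the
cross-product matrix:

```
maximize   uᵀ Xᵀ Y v
subject to ‖u‖₂ = 1, ‖v‖₂ = 1, ‖u‖₁ ≤ c₁, ‖v‖₁ ≤ c₂
```

with c₁ ∈ [1, √p], c₂ ∈ [1, √q]. The L1 bounds drive most weights to exactly
zero, so the mode is readable variable-by-variable and the fit is well posed
even when p + q exceeds n. The solver alternates closed-form updates — each a
soft-thresholding of Xᵀ Y v (resp. Yᵀ X u) followed by L2 normalization, with
the threshold found by binary search — and is deterministic (SVD-based
initialization).

Around the core fit the package provides:

- **Sparsity selection**: exhaustive grid search over (c₁, c₂) maximizing the
  canonical correlation r = corr(Xu, Yv), ties broken toward sparser models.
- **Permutation inference**: refit under row shuffles of the behavioral
  block; p = (# null r > observed r)/n_perm, a max-statistic null needing no
  further multiplicity correction.
- **Loadings**: Pearson correlations of each variable with the opposing
  block's variate, computed for the whole sample and within subgroups (e.g.
  younger/older) from whole-sample weights.
- **Reliability**: leave-one-out weight stability, RR-scores (similarity of
  each random test half's loading profile to the across-split mean) and
  split-half out-of-sample variate correlations.
- **Synthetic data**: a seeded generator of paired tables with a planted
  sparse mode, within-block nuisance correlation and a group-divergent
  latent, plus pure-noise nulls — every stage is testable without real data.

## Worked example

```python
import numpy as np
import sparsecca as sc

spec = sc.SyntheticSpec(seed=1)                 # 53 subjects, 59 x 86 blocks
behavioral, imaging, truth = sc.generate_paired_data(spec)
pair = sc.standardize_pair(behavioral, imaging)
model = sc.fit_scca(pair, cx=2.0, cy=2.0)
print(model.r, np.count_nonzero(model.wx), abs(model.wx @ truth.wx))
```

Running `python examples/01_simulate_and_fit.py` prints:

```
canonical correlation r = 0.908 (5 iterations, converged=True)
nonzero behavioral weights: 5 / 59
nonzero imaging weights:    5 / 86
planted support recovered:  True
|cos(wx, truth)| = 0.983, |cos(wy, truth)| = 0.982
```

r ≈ 0.9 matches the population correlation implied by the generator's
signal-to-noise settings, the fit kept exactly the 5 planted variables per
side, and the weight vectors align with the planted truth. The other
examples cover sparsity selection and permutation testing (`02`), subgroup
loading divergence (`03`), the reliability suite (`04`) and the one-call
pipeline (`05`); `examples/04_reliability.py` prints the signal/noise
contrast:

```
                     planted mode    pure noise
LOO min correlation      0.995         0.000
RR-score median          0.856         0.171
split-half mean r        0.809        -0.015
```

A thin CLI mirrors the stages: `sparsecca simulate | fit | permute |
reliability | run-all` (see `sparsecca --help`).

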