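# Methods

## Model and objective

The core model factorizes a z-scored gene-by-sample expression matrix
`Y` (n × m) as `Y ≈ Z B`, with the loadings `Z` (n × L) tied to a binary
gene-by-gene-set prior matrix `C` (n × k) through a nonnegative assignment
matrix `U` (k × L). The fitted factors minimize

```
f(Z, B, U) = ||Y − ZB||_F² + λ₁||Z − CU||_F² + λ₂||B||_F² + λ₃||U||_L1 ,
```

optionally subject to `U ≥ 0` (on by default). The model is linear: each
latent variable is a fixed weighted gene combination, and a sample's latent
expression is a linear functional of its gene expression. Assumptions worth
keeping in mind: genes enter symmetrically after z-scoring (no variance
weighting), prior sets are treated as flat membership lists (no gene-level
weights within a set), and the Gaussian-style squared-error loss means heavy
tails in the expression data are not down-weighted.

## Optimization

Block coordinate descent from a truncated-SVD initialization
(`Z₀ = U_L S_L`, `B₀ = V_Lᵀ`, `U₀ = 0`), cycling `U → Z → B`:

- `B = (ZᵀZ + λ₂I)⁻¹ZᵀY` and `Z = (YBᵀ + λ₁CU)(BBᵀ + λ₁I)⁻¹` are exact
  block minimizers (closed-form ridge solutions).
- Each column of `U` solves the nonnegative lasso
  `min_u λ₁||z − Cu||² + λ₃||u||₁, u ≥ 0` by coordinate descent in which
  every coordinate step is the exact one-dimensional minimizer
  (soft-threshold, clipped at zero); sweeps stop when the largest coordinate
  change falls below 1e-8 relative to the solution scale.

Because every block update attains its exact block minimum, the objective
recorded after each full cycle is non-increasing (the test suite allows
1e-9 absolute slack for float accumulation). Optional clipping of negative
`Z` entries is available for strictly nonnegative loading interpretations
but breaks the descent guarantee, so it is off by default. Iteration stops
when the relative objective change drops below `rel_tolerance` (default
1e-6) or after `max_iterations` (default 350) cycles. The core solver is
fully deterministic; no randomness enters the fit.

## Penalty defaults

Defaults are data-scaled from the singular spectrum, with `σ_L` the L-th
singular value of `Y`:

- `λ₁ = σ_L/2`, `λ₂ = σ_L`. The SVD initialization puts the scale into `Z`
  (`Z₀ᵀZ₀ = S²`, `B₀B₀ᵀ = I`), so penalties on the order of `σ_L` perturb
  the weakest retained latent dimension by an O(1) factor while leaving the
  strong ones nearly untouched. Penalties on the order of `σ_L²` (thousands
  of times the curvature of the data terms at this scale) drive all factors
  toward zero and stall the fit at `f ≈ ||Y||²`; this failure mode is easy
  to reproduce on the planted benchmark, which is why the defaults use the
  singular value, not its square.
- `λ₃` is chosen by a short path search: for candidates
  `λ₃ ∈ λ₁·{40, 20, 10, 5, 2}` (sparsest first) a 40-cycle pilot fit is run
  and the largest candidate keeping at least half the LVs attached to ≥ 1
  gene set wins. Attachment counts from the very first `U` update are
  uninformative (the unrotated SVD columns overlap every set enough that all
  LVs attach at any plausible λ₃), so the probe must let the factors
  partially converge. The "half attached" target mirrors the empirical
  behavior of compendium-trained pathway models, where a substantial
  fraction of LVs match no prior set and absorb technical signal.

All three penalties can be set explicitly in `PlierConfig`.

## Choosing the number of latent variables

`select_num_lvs` counts singular values above a Marchenko–Pastur-style bulk
edge `σ̂(√n + √m)`, where the noise level `σ̂` is re-estimated from the
singular values below the current threshold and iterated to a fixed point.
A 5% edge inflation absorbs Tracy–Widom fluctuation of the largest noise
singular value, and a relative floor of 1e-8·σ₁ handles noiseless input.
The estimate is deterministic for fixed data. An explicit `n_lvs` always
overrides it; published compendium models derive their LV count (hundreds)
from data scales this package does not reproduce.

## Preprocessing

- Gene universes are matched by exact, case-sensitive id equality (stable
  ids such as Ensembl are assumed; no symbol aliasing).
- TPM: per sample, counts are divided by gene length in bases and rescaled
  to sum to 10⁶. Scaling any sample's counts by a positive constant leaves
  its TPM unchanged.
- Z-scoring is per gene across all samples jointly, with the n−1 sample
  standard deviation. Constant gene rows become all-zero rows rather than
  being dropped — keeping row indices aligned with the prior matrix — and
  are reported in a warning. No log transform is applied by default;
  `log_transform` (log2(x+1)) is available ahead of z-scoring.
- Prior sets are dropped when fewer than `min_genes` (default 5) of their
  members are present in the expression universe — the count is of genes
  present, not nominal set size — and, when a pathway hierarchy is supplied,
  when they are non-leaf nodes. Sets from sources without a hierarchy are
  treated as leaves. Cyclic hierarchies are rejected.

## Projection and association

A new study is projected with `B_target = (ZᵀZ + λ₂I)⁻¹ZᵀY_target`, the
same closed form as the `B` block update, using the λ₂ stored in the trained
model. The target is z-scored against its own statistics. Model genes
missing from the target are filled with 0 (the z-scored mean) and logged;
below 50% overlap the projection refuses to run.

Association fits, per stratum and per LV, an OLS regression of latent
expression on age in months, with a two-sided t-test on the slope.
Benjamini–Hochberg adjustment is applied within each stratum across its
LVs — per-condition tables in this design report per-condition discoveries,
so the correction family is the stratum; correcting jointly across strata
would be the alternative reading. Significance is adjusted p < 0.05.

## Study query

For a chosen LV, each training study's samples are clustered on that LV's
values with exact one-dimensional 2-means: the optimal 2-partition of 1-D
data is contiguous in sorted order, so scanning all n−1 sorted split points
finds the global within-cluster-sum-of-squares optimum with no restarts and
no seed. Silhouette uses absolute difference as the distance, with s = 0
for singleton-cluster members and when both mean distances are zero.
Studies need ≥ 4 samples (two per cluster possible) and non-constant values
to be ranked; ties in silhouette break lexicographically by study id.

Null behavior matters for interpretation: the best 2-means split of ~20
i.i.d. Gaussian values already scores ~0.6–0.7, so only separations well
above that floor are meaningful. A planted two-condition split with modes
±3 latent sd about the study mean scores ~0.8 and reliably ranks first
among ten studies; a one-sided 3-sd shift (~0.64 expected) does not rise
above the null floor.

## Synthetic data

The generators emulate the statistical skeleton of a multi-study training
compendium: `Y = Z_true B_true + ε` with i.i.d. Gaussian latent expression
and residuals, prior-aligned loading columns (1.0 on one gene set's members,
N(0, 0.05) background; non-aligned columns rescaled to the same norm so all
LVs carry comparable signal), per-study two-condition mean shifts on chosen
LVs, and a target study whose chosen LVs follow `slope × age + noise` across
five adult ages (2–24 months, the numeric-age design of typical rodent aging
studies). All randomness flows from one seeded generator per call; same
seed, byte-identical output.

What the generators do *not* emulate — and hence what passing tests do not
establish about real data: count noise and library-size effects, batch and
platform structure, correlated genes within and across pathways beyond the
planted sets, non-Gaussian marginals, and incomplete or wrong prior
knowledge. The Gaussian latent model is an assumption chosen for
testability, not a claim about real compendia.

Default benchmark sizes (1,000 genes, 40 sets of 25 genes, 25 LVs of which
15 prior-aligned, 10 studies × 60 samples, latent noise sd 0.5; target
studies with 5 ages × 3 replicates × 2 strata, slope 0.15 latent-sd/month,
latent noise sd 1) are desk-scale stand-ins chosen so planted structure is
recoverable but not trivial: the per-LV signal-to-noise singular value ratio
(~4:1) is in the regime where initialization alone does not solve the
problem (the SVD basis is rotated) and the prior term is what breaks the
rotation.

## Numerical choices and edge cases

- Linear systems are solved with dense symmetric solvers (Cholesky for the
  projection); matrices here are L × L with L ≤ a few hundred.
- `update_B` with λ₂ = 0 and rank-deficient `Z` raises an error advising a
  positive λ₂ rather than silently pseudo-inverting.
- Exact ties in `U` when identifying an LV's top gene set break toward the
  lowest set index; top-gene rankings break ties lexicographically by id.
- Model bundles serialize floats with 10 significant digits; reloading a
  bundle and re-serializing reproduces the files byte-for-byte.
- All-zero gene-set columns in `C` get their `U` rows forced to zero with a
  warning.

## Known limitations

- In-memory dense linear algebra only; compendia that do not fit in memory
  need an out-of-core initialization this package does not provide.
- No cross-validated significance machinery for (pathway, LV) assignments;
  `U` magnitudes are descriptive.
- The linear model cannot represent nonlinear gene–pathway relationships.
- Study-query separations near the Gaussian null floor (silhouette ≲ 0.7)
  are not interpretable as real structure.
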