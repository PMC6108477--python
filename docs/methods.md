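# Methods

## Model

Let `X¹ … Xᵖ` be unordered factor variables, `Xⁱ` taking one of `m_i`
categorical values, and let a *region* `A` be a product of non-empty
category subsets, one per variable, with `C(A) = ∏ m_i(A)` combination
cells and `N(A)` observed samples.  The estimator places an optional Pólya
tree prior over distributions on the whole space: each region either stops
— its samples modeled as uniform over its cells — or is bipartitioned along
one variable, recursively.  The posterior over trees is summarized by three
families of quantities per region:

* **stopping probability** `ρ(A|D) = ρ Φ0(A) / Φ(A)`,
* **selection probabilities** over the per-variable candidate splits,
  proportional to `B(N1+α, N2+α)/B(α,α) · Φ(A_i1) Φ(A_i2)`,
* **mass allocations** to the two children, `(θ1, θ2) ~ Dirichlet(N1+α,
  N2+α)` (equivalently `θ1/(θ1+θ2) ~ Beta(N1+α, N2+α)`); within a stopped
  region, per-cell masses follow a symmetric `Dirichlet(N(A)/C(A)+β, …)`.

Region likelihoods obey

```
Φ(A) = ρ Φ0(A) + (1−ρ)/p · Σ_i B(N1_i+α, N2_i+α)/B(α,α) · Φ(A_i1) Φ(A_i2),
Φ(A_terminal) = Φ0(A) = C(A)^(−N(A)),
```

where a region is *terminal* when it is a single cell or holds no sample.
The measure entering `Φ0` is the counting measure on cells, which makes
`Φ0` the exact uniform-multinomial likelihood — the natural discrete
analogue of Lebesgue measure on a continuous region.

### Marginal-population-guided splits

Scoring all `2^(m−1) − 1` bipartitions of a variable's categories is
infeasible for large `m`.  Uniformity of a joint distribution implies
uniformity of its marginals, so the candidate set is shrunk to cuts of the
marginal ranking: categories are sorted ascending by their marginal count
`M_A(x)` inside the region (ties keep storage order, making everything
deterministic) and the `m − 1` prefix cuts are scored by the within-group
sum of squared deviations `T(s)`; the minimizing cut (smallest `s` on ties)
is the single candidate for that variable — `p` candidates per region in
total.  `T` is read as a sum of squared deviations about each group's own
mean; the grouped-deviation reading is the one consistent with measuring
"variation within each subregion", and is what the hand-checked example
`M = (1,2,9,10) → T(2) = 1` encodes.

### Limited lookahead and commitment

Exact evaluation of `Φ` recurses to terminal regions and is exponential.
The limited-lookahead scheme (LL-OPT) evaluates `Φ` only `h` levels deep —
regions at the horizon contribute `Φ0` — then commits the best single
action (`q = 1`): stop if `ρΦ0(A)` is at least every split term, else the
argmax split, and recurses into the committed children.  Ties commit the
stop (the simpler model).  Because the commit rule compares exactly the
summands of `Φ`, the committed structure coincides with the per-node
posterior mode, so the *mode tree* is the committed leaf set with Beta-mean
mass allocations.

### Inference modes

* **posterior mean** (default, deterministic): recursively, a region
  contributes `stop_prob · mass` uniformly over its cells and passes
  `(1−stop_prob) · mass` to the committed children in proportion
  `(N_child+α)/(N+2α)`; leaves contribute their whole incoming mass
  uniformly.  The symmetric Dirichlet cell extension has mean `1/C(A)`
  regardless of `β`, so `β` never affects posterior means.
* **mode tree**: committed partition + Beta-mean allocations, uniform
  within leaves.
* **random draw**: stop/descend sampled from `stop_prob`, allocations from
  the Beta posterior, cell masses from the symmetric Dirichlet; `β` widens
  or narrows the within-region dispersion.

All likelihood arithmetic is in log domain (log-Gamma for Beta ratios,
log-sum-exp for mixtures): `Φ0 = C^(−N)` reaches `10^(−600000)` at realistic
sizes and underflows anything else.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `rho` | 0.5 | prior stopping weight per region, in (0,1); larger → coarser partitions |
| `alpha` | 0.5 | pseudo count in Beta split weights and allocations; larger → smoother allocations |
| `beta` | 0.5 | pseudo count of the uniform-Dirichlet cell extension; affects sampled draws only |
| `lookahead_h` | 3 | levels of lookahead when scoring stop vs split |
| `commit_q` | 1 | levels committed per step (`q ≤ h`) |

`ρ = α = β = 0.5` are the customary neutral Pólya-tree choices (Jeffreys-type
pseudo counts, equal prior odds of stopping) and make the micro examples
exactly computable; `h = 3` matches the published simulation studies of
this estimator family.  All are configurable.

A practical note on `h`: deeper lookahead approximates the exact OPT
better, but the exact OPT itself over-partitions at low sample density.
Sorted noisy-uniform marginals always *look* structured (the prefix cut
separates low from high order statistics, and the Beta weight rewards the
induced imbalance), so at, say, 20³ cells with 800 samples, `h = 1` can
out-perform `h = 3`, and the random-partition variant — which lacks the
sorting selection effect — can be competitive there.  At the headline scale
(100³ cells, 10⁴ samples) the marginal-guided `h = 3` tree is decisively
better than both the count-based estimate and random partitioning.  It also
means the error of the `h = 3` estimator fluctuates with how deep the
committed tree happens to grow: its replicate-to-replicate coefficient of
variation at 20³/800 is on the order of 0.3, even though its mean error is
several-fold below the count-based baseline.

## Baselines

* **combination-wise MLE** — cell count / total weight; sparse.
* **categorical KDE** — product Aitchison–Aitken kernel: weight `1−λ` on
  the observed category, `λ/(m−1)` on each other category, bandwidth
  `λ = 0.9` by default per the categorical-KDE literature; `λ = 0` recovers
  the MLE.  Each factor sums to one, so the estimate is exactly normalized.
* **random-partition OPT** — candidate splits are uniform random
  bipartitions (each category assigned a side, redrawn until both sides are
  non-empty); likelihoods, commitment, and posterior are identical to the
  main method.  Isolates the value of the marginal guidance.

## Synthetic data

Generators lay down a designed truth, shuffle each variable's category
labels independently (estimators must not exploit generative order), and
draw `n` i.i.d. samples from the truth.

* **two-level uniform** — per variable, the first `m/2` categories form a
  "low" super category of mass `p`, the rest a "high" one of mass `1−p`,
  uniform within; *dependent* mode keeps only the two aligned blocks
  (requires a common `p`), *independent* mode multiplies marginals (2³
  blocks).  The numbered settings: (1) dependent, `p = 0.7`;
  (2) independent, `p = (0.7, 0.8, 0.9)`.
* **K-super uniform** — the same with `K` blocks per variable; default
  masses decrease linearly (`K+1−k`, normalized), `"equal"` or an explicit
  vector are available.
* **discretized normal / log-normal** — the trivariate density integrated
  over a uniform grid spanning mean ± 3σ per axis (log-normal: (0, e³]) by
  a per-cell Gauss–Legendre product rule (5 points per axis), renormalized
  for the truncated tail.  Settings (3)/(4) use equicorrelation 0.2/0.8.
* **additive exponential** — `Z_i = E0 + E_i`, i.i.d. `Exp(rate)`
  components with a shared `E0` inducing dependence; the closed-form joint
  density is discretized over `[0, mean + 3 sd]`.
* **Clayton copula + uniform marginals** — exact cell masses by
  `p`-dimensional finite differencing of the copula CDF (no quadrature).

Auxiliary-family parameters (correlations, rate, θ, K, masses) are exposed
with the defaults above; they parameterize families described only
qualitatively in the literature this design follows, so no numeric error
levels are attached to them.

What the generators do **not** emulate: real diagnosis or expression data
have heavy-tailed, hierarchically structured marginals, label sets that are
neither balanced nor block-uniform, and dependence that no copula family
captures.  Passing tests on these designs show the estimator recovers
planted block/smooth structure from sparse counts under label shuffling —
not that it discovers arbitrary real-world structure.

## Error metric and benchmark harness

`RSSE = sqrt(Σ_cells (estimate − truth)²)`, computed on dense arrays (the
spaces used stay ≤ 10⁶ cells; both tables are block- or cell-sparse until
materialization).  A useful analytic anchor: the combination-wise MLE has
`E[RSSE²] = (1 − Σ_c p_c²)/n`, which at setting (2) with `m = 100`,
`n = 10,000` gives RSSE ≈ 0.0100; the benchmark harness reproduces this to
within Monte-Carlo error, and the OPT posterior mean reaches ≈ 0.0053 under
the same conditions (≈ 47% below the count-based baseline).

`run_benchmark` derives every replicate's data seed and estimator seed from
one `SeedSequence`, so whole result tables are reproducible from a single
integer.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses 10 replicates for the conventional estimator
and 5 for the OPT at the full scale (100³ cells, `n = 10⁴`; the OPT's
replicate spread there is ~1% of its mean, so 5 replicates pin the mean
well), and 100 replicates per setting for the small-scale (20³, `n = 800`)
stability measurement.

## Numerical choices and degenerate inputs

* Ties: category ranking is stable (storage order); `argmin T` takes the
  smallest `s`; stop wins commit ties; edge ordering in networks breaks
  ties alphabetically.
* `(1−ρ)/p` uses the whole space's variable count `p` throughout and is not
  renormalized when some variables in a region are unsplittable — thin
  regions therefore lean slightly toward stopping, which is the
  conservative direction.
* Weighted rows (counts) are first-class: all formulas use summed weights
  as `N`, so count matrices reuse the sample-table code path unchanged.
  Non-integer weights are accepted everywhere except binomial subsampling.
* Empty regions are terminal with `Φ = Φ0 = 1` and stop probability 1;
  rows with missing values are rejected (no imputation mechanism exists in
  the model).
* The exact `Φ` recursion guards against misuse with a region-evaluation
  budget and raises rather than thrash on large spaces.
* Posterior tables carry uniform blocks, not materialized cells; total mass
  is 1 within 1e-9 after materialization.

## Known limitations

* The prior is the simplified one-`ρ`, one-`α` parameterization, not the
  fully general Wong–Ma weight system; only binary, single-variable,
  prefix-of-ranking splits are searched.
* At very low sample density the sorting selection effect described above
  can over-partition uniform regions; lowering `h` (or raising `ρ`)
  mitigates this at the cost of coarser fits elsewhere.
* Continuous or ordinal variables, mixed spaces, and missing data are out
  of scope.
* The co-occurrence network weights count terminal regions by default
  (sample-weighted counting is available via `weight_by="samples"`); which
  weighting published disease networks used is not documented, so small
  rank differences near the top-k cutoff are expected.
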