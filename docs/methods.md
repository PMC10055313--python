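# Methods

## Model and test

Each gene is tested marginally for dependence between its expression vector
`y ∈ ℝᴺ` and the spot coordinates `S ∈ ℝᴺˣᵈ` (d = 2 or 3). Expression is
first residualized by least squares on an intercept plus any per-spot
covariates (`y ← (I − P_X)y`), which makes every downstream statistic exactly
invariant to affine transformations `y ↦ ay + b`. Raw values are tested by
default; a `log1p` / median-library-size transform is available but not
required — the test is non-parametric and only uses the quadratic form of
the residuals. Genes whose residual sum of squares falls below `1e−12·N`
(constant genes, or genes fully explained by covariates) are flagged
degenerate and carry `p = 1` through every stage rather than being dropped,
so multiplicity accounting always refers to all tested genes.

The statistic for a kernel `H(S)` is `T = yᵀHy/(N·yᵀy)`. A batch of K genes
against one kernel costs a single `K×N · N×N` product, `O(N²K)` over the
dense families; only one kernel is resident at a time, so peak memory is
`O(N²) + O(NK)`. Projection kernels are never materialized: they are stored
as their `N×r` orthonormal factor and quadratic forms cost `O(Nr)`.

### Null distribution

The exact null of `T` is a weighted χ²₁ mixture whose weights require the
eigenvalues of `H` (`O(N³)`). Instead, a gamma law is matched to the first
two moments,

    E(T) = tr(H̃)/N²,    V(T) = 2·tr(H̃²)/N⁴,    H̃ = C H C,  C = I − 11ᵀ/N,

with shape `E²/V` and scale `V/E`. Both traces are computed in `O(N²)`
(`tr(H̃²)` is the squared Frobenius norm of the centered working copy).
Using the *centered* kernel is deliberate: residuals are mean-zero, so
`yᵀHy = yᵀH̃y`, and the centered moments agree with the moments of the
location-permutation null — the un-centered traces would bias `E(T)` upward
by the kernel's grand mean. Uncentered summaries are retained
(`center=False`) for comparison. Accuracy, measured against 2000–20000
random permutations: the mean matches to an `N/(N−1)` factor (≈0.5% at
N = 200), the variance to roughly `O(1/N)` relative (≈13% at N = 60, within
Monte-Carlo noise of 3 SEs at N = 200), and permutation p-values are
near-uniform (KS ≈ 0.03–0.05 for N = 60–200). p-values are floored at
1e−300 so `−log10 p` stays finite.

### Kernel battery and data-driven parameters

* **Gaussian** `H_ij = exp(−‖s_i−s_j‖²/(2l²))` — smooth, monotone decay;
  detects blob/gradient patterns at scale `l`.
* **Cosine** `H_ij = cos(2π‖s_i−s_j‖/p)` — oscillatory; detects periodic
  patterns with wavelength near `p`.
* **Projection** `D = Z(ZᵀZ)⁻¹Zᵀ` with `Z` the column-centered coordinates
  or their element-wise Gaussian (`exp(−z²/2σ²)`) or cosine (`cos(2πz/p)`)
  transforms — rank ≤ d, first-order (regression-type) dependence only.

Lengthscale/period grids (10 values each) are log-spaced between the 1st
and 99th percentiles of the nonzero pairwise distances of a seeded
subsample of at most 1000 spots, so grid construction is `O(cap²)`
regardless of N and deterministic given the seed. Transform parameters for
the projection battery (5 Gaussian scales + 5 cosine periods) are the
{0.1, 0.3, 0.5, 0.7, 0.9} quantiles of the absolute centered coordinate
values pooled over axes. Projection rank uses a `1e−10` relative Gram
eigenvalue cutoff (SVD of the `N×d` matrix; no `N×N` eigenproblem).

A known consequence of grids of *pure-tone* cosine kernels: a periodic
signal is only detected when some grid period matches its wavelength to
within roughly `|1/p − 1/p′| ≲ 1/L` (L = spatial extent). Signals whose
wavelength is much shorter than the domain and falls between grid values
can be missed entirely; signals whose wavelength is comparable to the
domain are also picked up by the smooth kernels through variance inflation
and are easy for every family.

### Combination and FDR

Per-gene, the R = 31 kernel p-values are combined as `min(1, R·min p)`
(Bonferroni-calibrated minimum-p). With strongly correlated kernels this is
conservative — measured null rejection at α = 0.05 is ≈0.012–0.019
(effective number of independent kernels ≈ 9 of 31). A Cauchy combination
(`combine="cauchy"`), which is nearly calibrated under dependence, is
provided for sensitivity analysis. SPARK-X combines its 11 projection
p-values with the Cauchy rule, matching its usual definition; its measured
null rejection is 0.05 ± 0.005. Gene-level calls apply Benjamini–Yekutieli
(via statsmodels) at a default FDR of 0.05 with a strict `<` threshold;
rankings break ties by combined p, then largest per-kernel statistic, then
gene id, so reports are fully deterministic.

## Synthetic data

Two generators provide ground-truth benchmarks. Both are pure functions of
their config (seed included) and write the same file formats as real data.

**Count patterns** (negative binomial). N locations uniform on the unit
square; exactly `round(0.2·N)` spots form the pattern — the band of largest
x-coordinates ("streak") or the disc nearest the center ("hotspot"), with
"reverse" variants elevating the complement instead. Counts are NB with
mean/dispersion parameterization (`var = μ + μ²/θ`), background mean 0.5,
dispersion 10, and on-pattern mean multiplied by the fold change; fold = 1
is the null. The background mean and dispersion are package defaults chosen
to mimic sparse sequencing-based ST counts (≈60% zeros at the default
mean); they are exposed on the config.

**Gaussian-process fields.** N uniform locations; each gene i.i.d.
`N(0, h·K + (1−h)·I)` with `K` a Gaussian or cosine kernel, so the total
variance is 1 and `h ∈ [0,1)` is the fraction attributable to space
(h = 0 is the null). The cosine kernel is indefinite in ≥2 dimensions;
negative eigenvalues are clipped to zero and the clipped kernel is rescaled
to unit mean diagonal, so `τ² + σ² = 1` continues to hold for the realized
fields (without the rescale the clipped diagonal can exceed 4 at short
periods). Default field parameters: lengthscales {0.05, 0.1, 0.2, 0.4} and
periods {0.5, 1, 2, 4} on the unit square, spanning fine to domain-scale
structure.

What the generators do *not* emulate: library-size variation between spots,
gene–gene correlation, zero inflation beyond NB sparsity, segmented tissue
anatomy, or platform-specific lattice geometries. Passing benchmarks here
therefore demonstrates calibration and relative power under idealized
spatial structure, not end-to-end behavior on any particular platform.

## Evaluation harness

Power is the fraction of signal genes with raw combined `p ≤ α` (α = 0.05),
averaged over replicates; null-only cells (fold = 1, h = 0) report the same
fraction as the type-I error. Raw rather than FDR-adjusted p-values are
used on purpose — operating characteristics at a nominal level, not calling
behavior. The permutation-null check permutes the coordinate rows
(expression fixed, default B = 5), re-runs the tests, and pools raw
combined p-values against uniform quantiles for QQ plots. Marker-set
enrichment uses the classic unweighted GSEA running sum (+1/|G| on hits,
−1/(n−|G|) on misses, ES = max(0, max running sum)) on the full tested
ranking by default; fold changes for the top-50 marker sets use an `1e−8`
pseudocount and id-based tie-breaks. An option ranks detected SVGs only.

## Problem sizes used by the test suite

The statistical checks run at: permutation calibration N = 200 with 2000
permutations (and N = 60/5000 for the small-sample check); type-I error at
N = 1000, K = 1000; count-pattern power at N = 1000, K = 500; GP power
ordering at N = 1000, K = 500 over 5 replicates; covariance recovery at
N = 100 over 20000 replicate genes. Monte-Carlo tolerances use 3 standard
errors with the kurtosis-correct SE for sample variances (the normal-theory
`s²√(2/B)` understates the SE of a skewed quadratic form's variance).

## Known limitations

* The minimum-p combination is conservative by a factor ≈3 at the 0.05
  level with the default battery; use `combine="cauchy"` when calibrated
  per-gene p-values matter more than strict family-wise control of the
  kernel battery.
* Cosine-kernel detection is grid-resonant (see above); for fine periodic
  structure on large domains, supply a denser period grid.
* The gamma null is a two-moment approximation; extreme tail p-values
  (far beyond the 1e−3 scale) inherit its skewness error.
* Covariates are removed linearly; nonlinear confounding (e.g. library
  size acting multiplicatively) should be handled by the expression
  transform, not the covariate projection.
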