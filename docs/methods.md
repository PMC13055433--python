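# Methods

## Model and parameterization

cosmoda models a compositional sample `x ∈ Δ^{p−1}` with covariate value `y`
by the unnormalized density

    log p(x) ∝ −½ t_a(x)ᵀ K t_a(x) + (η₀ + y η₁)ᵀ t_b(x),

with the Box–Cox-centered power transform `t_a(x) = (xᵃ − 1)/a` (`log x` at
`a = 0`). The centered transform is used in *all* sufficient statistics.
Rationale: ground-truth interaction matrices satisfy `K·1 = 0`, under which
the quadratic term is invariant to constant shifts of the transformed
coordinates, and the location term changes only by an additive constant
absorbed by normalization — so on the common ground the centered and
uncentered families describe the same distributions, while the centered one
is numerically continuous in `a` at 0 (the `a → 0` limit is exactly the
log-based family; a unit test asserts agreement to 1e−3 at `a = 1e−6`).
For `a ∉ {0, 1}` the convention amounts to measuring `K` on a rescaled
axis (our `K` equals `a` times the power-kernel `K` of the uncentered
`x^a/a` convention); all shipped benchmarks use `a = b = 0`, where the two
conventions coincide.

Propriety is checked case-wise on `(a, b)`: positive powers are always
proper; `a > 0, b = 0` needs every component of `η₀ + yη₁` above −1 at the
observed covariate extremes; the `a = 0` cases need a positive (resp.
nonnegative) quadratic form `log(x)ᵀ K log(x)` on the simplex, which cannot
be certified by sampling — the validator evaluates it on a seeded grid of
1000 random simplex points and documents the check as necessary-only. When
`K` vanishes identically the Dirichlet-type condition `η > −1` is used
instead.

## Score matching system

Estimation minimizes the empirical generalized (weighted) Hyvärinen
divergence with the last coordinate profiled out (`x_p = 1 − Σ x_j`) and
boundary weight `h_j(x) = min{x_j, x_p, C_j}^c`, defaults `c = 2`,
`C_j = 1`. The per-sample loss is

    Σ_j  ½ h_j (∂_j log p)² + h_j ∂_jj log p + (∂_j h_j)(∂_j log p),

the standard integrated-by-parts form; the derivative of the weight at the
kink `x_j = x_p` takes the `x_j` branch (a measure-zero tie). Because the
partials are linear in `θ = (vec K, η₀, η₁)`, the loss is the quadratic
`½θᵀΓθ − gᵀθ` with `Γ`, `g` sample averages. The K-diagonal of `Γ` is
multiplied by `δ = 2 − 1/(1 + 4e·max(√(6 log p/n), 6 log p/n)) > 1` to keep
the penalized problem bounded; `δ` is exposed as a configuration value.

Rather than transcribing closed-form entries for the ~ (p²+2p)² matrix, the
implementation collects coefficients of the per-sample derivative vectors
(sparse, ~4p nonzeros each) and is verified against a brute-force evaluation
of the divergence (`loss_direct`): for random datasets, powers and θ the
quadratic form agrees with the direct double sum to 1e−8 relative. This
makes the system construction self-verifying instead of
transcription-trusting. A constant covariate leaves `η₁` unidentified, so
the builder automatically falls back to the covariate-less parameterization
(`r = p² + p`) when `y` does not vary.

Zeros in the data are admissible only for `a, b > 0`; there the boundary
weight and its derivative vanish at zero entries, which exactly cancels the
singular power terms — the implementation skips those (sample, feature)
contributions rather than evaluating `0·∞`. With `a = 0` or `b = 0` the
builder raises and points to the pseudocount option.

Memory: `Γ` is dense `(p²+2p)²`; at p = 150 this is ~8 GB, so a guard
raises above `max_p = 150` with a suggestion to filter features.
Per-sample components (needed by the sandwich covariance) are recomputed on
demand from the stored data instead of being materialized n times.

## Optimizer

Proximal coordinate descent on
`½θᵀΓ_δθ − gᵀθ + λ₁‖vec K_off‖₁ + λ₂(‖η₀‖₁+‖η₁‖₁)`; K's diagonal is never
penalized. Each update is the exact 1-D minimizer (soft-thresholded Newton
step), so the objective is monotone. Convergence is declared when the
largest coordinate move in a sweep falls below `ε·max(1, ‖θ‖_∞)`; the
stand-alone solver defaults to `ε = 0.1`, `t_max = 1000` sweeps, while path
fitting (`fit_path`) defaults to `ε = 1e−4` because support selection along
warm-started paths benefits from tighter solves at modest cost. Moves
smaller than half the tolerance are skipped entirely (the coordinate is
already within-tolerance optimal), which keeps the gradient bookkeeping
exact while avoiding O(r) updates in the dense tail of the path — a ~10×
speedup at p = 100. KKT residuals are reported; solutions at `λ = 0` agree
with a dense solve to 1e−6 in tests. `K̂` is symmetrized on output; the
default path is 100 log-linear λ₁ values on [1e−6, 1].

## Model selection

5-fold cross-validation scores each λ by the *unpenalized* validation-fold
quadratic loss `½θ̂ᵀΓ_val θ̂ − g_valᵀθ̂` (the δ multiplier is an estimation
device, not part of the divergence, so it is omitted in validation). The
1SE rule picks the largest λ whose mean loss is within one standard error
of the minimizer; folds are assigned uniformly at random from the run seed,
with optional stratification on a binary covariate. The eBIC alternative is
`S·log n − 2·log(loss + shift) + 2γ‖vec K_off‖₁` with `S` the off-diagonal
support size and default `γ = 0.5`; since the quadratic loss can be
negative, the path-wide minimum shifts it positive before the log — a
convention of this package, exposed alongside a raw penalized-objective
variant.

## Differential abundance test

`θ̂` is an M-estimator of a penalized quadratic program; its covariance is
estimated by the sandwich `Ŝ = Γ⁻¹ Σ̂₀ Γ⁻¹ / n`, where
`Σ̂₀ = n⁻¹ Σ_i r_i r_iᵀ` is the empirical second moment of the per-sample
score residuals `r_i = Γ̃_δ⁽ⁱ⁾θ̂ − g̃⁽ⁱ⁾`. The bread uses the un-δ-scaled
`Γ` (configurable to `Γ_δ`), with a ridge jitter of `1e−8·tr(Γ)/r` on the
diagonal when the condition number exceeds 1e12; the product is assembled
as a Gram matrix so `Ŝ` is positive semidefinite by construction. The 1/n
factor is required for `Ŝ` to estimate `Var(θ̂)` (the average-residual
outer product estimates the score covariance of a *single* observation);
Monte-Carlo checks in the test suite confirm that the reported standard
errors match the replicate standard deviation of `η̂₁` within a few
percent, and that null statistics pass a Kolmogorov–Smirnov test against
t(n−3). The reference is asymptotic: at small n (≈200) the standard errors
run ~5% conservative and the empirical type-I error sits near 0.03 at a
nominal 0.05; from n ≈ 500 the test is calibrated within Monte-Carlo
error. Degrees of freedom are fixed at n−3 regardless of p or the selected
support. p-values are BH-adjusted across the p−1 tested features; the
profiled-out reference feature is flagged and excluded from testing and
adjustment. SEs are computed at the penalized `θ̂` without
post-selection adjustment — a caveat for aggressive λ.

## Power selection

For data with zeros, the power `φ = a = b` is chosen on a grid
(default 0.01…0.99) to maximize the Procrustes correlation between the
compositional Box–Cox transform `X_{φ,j} = φ⁻¹(p·X_jᶠ/Σ_k X_kᶠ − 1)`
(rows sum to zero; `φ → 0` recovers the CLR) and the ALR transform of
zero-replaced data with a zero column kept at the reference position.
Both matrices are column-centered and unit-Frobenius-normalized; the
optimal rotation comes from the SVD of the cross-product and
`r_φ = 1 − ‖A − BQ‖_F²`. Column centering replaces an explicit PCA
embedding: Procrustes over full-dimensional rotations is invariant to an
orthogonal change of basis, so aligning centered matrices equals aligning
complete PC-score embeddings (an explicit truncated-PCA option exists for
parity experiments). Ties in the argmax resolve to the smallest φ (closest
to log-ratio geometry). Zero replacement semantics: 0.5 counts for count
tables; `0.5/library size` when proportions come with library sizes;
otherwise half the smallest observed proportion (multiplicative-replacement
heuristic).

## Simulators

The banded benchmark generator builds `K` with off-diagonals
`|i−j|/(s+1) − 1` inside bandwidth `s` and diagonal equal to the negative
off-diagonal row sum (zero row sums, diagonally dominant, PSD), pairs it
with `η₀ = −1`, `a = b = 0`, and optionally attaches a misspecified binary
covariate drawn uniformly from {0, 1}. Two-group DA scenarios shift cases
by `η₁ = τ·indicator⊙η₀` with the effect-size grid
τ ∈ {−0.5, −0.3, 0.3, 0.5, 1}.

Sampling recognizes an exactly tractable subfamily first: for `a = b = 0`
with zero row sums and a positive-definite reference submatrix
`K̃ = K[:p−1, :p−1]`, substituting `x = alr⁻¹(w)` cancels every
reference-coordinate term (the Jacobian contributes `Σ log x_j`, the
location term `1ᵀη·log x_p`, and `K1 = 0` removes the rest), leaving a
density in `w` proportional to `N(K̃⁻¹(η̃+1), K̃⁻¹)` times the tilt
`x_p^{1ᵀη+p}`. When `1ᵀη = −p` (the banded recovery design with `η = −1`)
the draws are plain multivariate-normal samples mapped through the inverse
ALR — exact and instantaneous; otherwise an independence
Metropolis–Hastings chain with that normal as proposal corrects the tilt
(the acceptance ratio involves only the reference proportion, so the chain
mixes immediately; 200 steps by default). Validated against direct
quadrature at p = 3 for both tilted and untilted cases.

All other parameter settings use a pairwise Gibbs chain: each step picks a
coordinate pair, holds the rest fixed, and redistributes the pair's mass by
drawing the split fraction from a griddy inverse-CDF approximation of the
1-D conditional kernel (1024 bins by default, uniform within the chosen
bin; kernel evaluations use precomputed grid transforms and skip bins more
than 34 log-units below the peak). Two regimes: `chains="independent"`
(default) runs a fresh `burn_in`-sweep chain per draw — exactly independent
samples, emulating repeated rejection-sampler runs — while
`chains="single"` thins one long chain per covariate level, which is much
cheaper but leaves residual autocorrelation (lag-1 ≈ 0.6 at thin = 10 for
the p=100 banded model; thinning of 50–100 sweeps makes it negligible).
Pairwise mass swaps move collective modes (the overall log-scale) slowly:
at bandwidth-7 coupling the chain is visibly unconverged even after tens of
thousands of sweeps, which is precisely why the exact subfamily path above
is the default wherever it applies.
Sampler correctness is established against closed forms rather than any
external stream: Dirichlet moments in the `K = 0` special case, and a
total-variation distance < 0.05 between a long-chain 2-D histogram and
direct quadrature of the p=3 density.

The p=11 two-group base parameters are a synthetic stand-in (no real-data
fit is shipped). The interaction matrix is a connected ring of weak
couplings (−0.6) with five stronger pairs on top (abundant pair 0–1, rare
pair 6–7); connectivity matters, because a disconnected component leaves
its joint-scaling direction unpenalized and can make the a = b = 0 density
improper — a failure mode the random-grid propriety check cannot see. The
location vector is derived backwards from a target composition spanning
~2–30% relative abundance (η̃₀ = K̃μ − 1 in ALR coordinates, with the
reference component zeroing the tilt), which yields realistic log-scale
spreads (sd ≈ 1) and strongly correlated pairs (r ≈ 0.6–0.8), and makes
the τ-scaled target shifts comfortably detectable at n = 1000. DA
benchmark claims are property-based (ordering of false discovery rates),
never value-matching against any published figure.

## Evaluation

Support recovery is scored on the off-diagonal upper triangle of the
symmetrized `K̂`: each path point yields a (FPR, TPR) pair; the ROC is the
monotone upper envelope of the sorted points with (0,0) and (1,1) anchors
and the AUC its trapezoid integral (equal, for nested thresholding paths,
to the rank-based AUC — asserted against an exhaustive-threshold oracle).
Replicate curves are vertically averaged on a common FPR grid; the mean AUC
is the mean of per-replicate AUCs. DA calls at `p_adj < α` are scored by
FDR = FP/(FP+TP) (0 when nothing is called; the raw ratio otherwise, so a
single false call with no true hits counts as FDR 1), TPR, and Matthews
correlation (0 on degenerate margins). The comparator adapter runs
scikit-learn's graphical lasso on the empirical covariance of CLR data over
the same λ grid; non-converged path points reuse the previous precision.

## Problem sizes in the shipped checks

The full-scale reference studies use p=100 with R=50 replicates (n=80,
s=2 and n=1000, s=7) and 30 two-group scenario configurations. The package
runs the same designs at reduced size as its standing acceptance checks:
8–10 replicates for the low-n recovery study, a single n=400 replicate
for the high-n ordering check, 500 replicates of the p=5, n=500 null
calibration, and 5 scenario replicates × 5 effect sizes at p=11, n=1000
for the FDR-ordering comparison. The reduced sizes are the package's
choice of a desk-scale experiment; the generator defaults reproduce the
full designs verbatim when more compute is available.

## Known limitations

- A single covariate only; no multi-covariate designs or confounder
  adjustment.
- `θ` parameterizes all p² entries of `K` (no row-sum constraint during
  estimation). On the simplex `Σ_j log x_j` varies little across samples,
  so directions that add a constant to a row/column of `K` are nearly
  collinear with the location parameters; the δ diagonal ridge then
  shrinks the overall *magnitude* of `K̂` strongly in near-square problems
  (at p=11, n=1000, δ≈1.57 the recovered `K̂` is far below the generating
  scale, while δ→1 recovers it). Off-diagonal *support* and its ordering —
  what the recovery benchmark measures — are unaffected, as is the
  false-discovery-rate advantage of the covariate test, but users reading
  `K̂` magnitudes should fit with a δ override near 1 or at larger n/p
  ratios.
- Inference on very rare features is imprecise: the boundary weight
  suppresses exactly the observations that carry their signal, and strong
  location shifts toward the boundary attenuate `η̂₁` (visible in the
  shipped scenarios at τ = 1 on the rare pair).
- SEs ignore selection of λ; the t(n−3) reference is asymptotic.
- The synthetic scenario generator emulates interaction-induced secondary
  effects, not real-data features such as sequencing-depth variation,
  overdispersed zeros, or batch structure — passing benchmarks demonstrate
  method behavior under the model, not performance guarantees on real data.
- The griddy Gibbs sampler is an approximate MCMC scheme; its resolution is
  validated at desk scale but extreme concentration (|η| ≫ 10) may need a
  finer grid.
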