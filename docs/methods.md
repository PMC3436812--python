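# Methods

## Model and objective

Let `Y ∈ R^{N×D}` hold per-gene-centered expression values for N cells and
D genes, and `X ∈ R^{N×Q}` the latent coordinates (Q = 2 by default).
Placing independent Gaussian priors on the rows of the latent-to-data map
and marginalizing it yields D independent Gaussian processes with a shared
Gram matrix `K`, and the log marginal likelihood

    L(X, θ) = −(DN/2) ln 2π − (D/2) ln|K| − (1/2) tr(K⁻¹ Y Yᵀ).

Three kernels are provided, each plus an optional bias term and i.i.d.
observation noise with precision β:

| kind                 | base entry k(x, x′) |
|----------------------|----------------------|
| `linear`             | σ² ⟨x, x′⟩ |
| `rbf` (default)      | σ² exp(−‖x−x′‖² / 2ℓ²) |
| `rational_quadratic` | σ² (1 + ‖x−x′‖²/(2aℓ²))^(−a) |

With the linear kernel the model is dual probabilistic PCA
(`K = α X Xᵀ + β⁻¹ I`); the fitted latent subspace coincides with the
top-Q principal subspace, which the test suite verifies to < 1e−2 rad.
The likelihood is invariant under orthogonal rotations of `X` (all kernels)
and translations (stationary kernels), so latent configurations are
reported and compared only up to similarity transforms.

Hyperparameters are stored on the natural scale and optimized as
logarithms, which enforces positivity without constraints. A zero bias
variance is treated as structurally absent and never optimized.

## Stage-structure prior

For groups (stages) g with index sets I_g, within-group data-space
distances d\* (Euclidean by default; Manhattan and one-minus-correlation
available) are compared with latent Euclidean distances d via the grouped
Sammon stress

    C_g = (1/c_g) Σ_{m<n ∈ I_g} (d*_{mn} − d_{mn})² / d*_{mn},
    c_g = Σ_{m<n ∈ I_g} d*_{mn}.

The prior p(X) ∝ exp(−Σ_g γ_g C_g) gives the log posterior
`L − Σ_g γ_g C_g`. Design choices here:

- **Per-group normalization.** Each group carries its own Sammon constant
  c_g, making γ comparable across groups of different sizes. A global
  normalization is the other defensible convention; published γ magnitudes
  (10³–10⁴ range on real qPCR panels) do not transfer between conventions,
  so γ should always be calibrated by the escalation heuristic below.
- **γ handling.** A scalar γ broadcasts to all groups; a per-stage table
  reflects prior knowledge about within-stage heterogeneity (low for
  homogeneous early stages, higher for stages past a lineage decision).
  γ is never optimized, so the prior's γ-dependent normalizing constant can
  be ignored.
- **Degenerate pairs.** Pairs with d\* < 1e−12 (duplicated cells) are
  excluded from the sum; latent-coincident pairs contribute zero gradient.
  Singleton groups contribute nothing.
- **Calibration heuristic.** Start at γ = 0 and increase (the
  `sweep-gamma` command automates the grid) until within-group stress
  collapses and the map visibly fragments into small isolated clusters;
  back off one step. The sweep reports stress, likelihood and
  nearest-neighbour error per γ; automatic selection is deliberately out of
  scope. Note that within-group stress cannot reach zero in general: a
  group's high-dimensional distance pattern has no exact 2-D embedding, so
  even γ → ∞ leaves a positive residual stress.

With all γ = 0 the posterior reduces *exactly* (bit-for-bit) to the plain
likelihood, and the structured fit reproduces the plain fit's trajectory.

## Optimization

`X` and the log-scale hyperparameters are concatenated into one vector and
minimized (negative objective) with scaled conjugate gradients following
Møller's published update rules (σ₀ = 1e−4, initial λ = 1e−6). Two
behaviours worth noting:

- On negative curvature the scale is raised per Møller's step 4
  (δ ← −θ, λ ← −2θ/κ). The popular Netlab variant (δ ← λκ) can produce an
  enormous accepted step on stiff GPLVM objectives that drives all latent
  points apart into a degenerate optimum; Møller's rule does not.
- A non-finite objective or gradient during a trial step rejects the step
  and raises λ instead of aborting; ~100 consecutive rejections raise a
  stall error carrying the best iterate.

Initialization is deterministic: centered `Y` is projected onto its top-Q
principal directions (sign-fixed) and each latent dimension rescaled to
unit variance. Defaults: 1000 iterations, objective and parameter
tolerances 1e−6. Convergence is accepted when both step size and objective
change fall below tolerance; the objective trace is non-increasing at
accepted steps. The Gram matrix is Cholesky-factorized; jitter
(1e−6 × mean diagonal, escalated up to twice) is added only when the plain
factorization fails.

Identical inputs and settings give bit-identical results; there is no
hidden randomness anywhere in the fit.

## Predictions, relevance maps, gradient profiles

At a new latent point x\* the predicted expression is Gaussian with mean
`μ(x*) = m + Yᵀ K⁻¹ k(x*)` (m = per-gene training means, added back after
the centered fit) and shared variance
`σ²(x*) = k(x*,x*) − k(x*)ᵀ K⁻¹ k(x*) + β⁻¹` (clipped at 0 against
round-off). The D×Q Jacobian `∂μ/∂x* = Yᵀ K⁻¹ ∂k(x*)/∂x*` quantifies local
gene importance.

The **gene relevance map** evaluates the Jacobian on a regular grid
(default 20×20) spanning the bounding box of the fitted latents expanded by
5% per side, and reports per grid point each gene's Euclidean gradient norm
and the argmax gene (ties broken by smallest gene index, so output is
deterministic). **Gradient profiles** report, at one location, every gene's
gradient vector and norm together with the derivative-process SD: the
derivative of a GP is a GP whose posterior variance along latent dimension
q is the second kernel derivative at coincidence (σ²/ℓ² for the stationary
kernels, σ² for the linear one) minus the data-explained term
`(∂k/∂x_q)ᵀ K⁻¹ (∂k/∂x_q)`. Under the shared kernel this uncertainty is
common to all genes; it is the implemented construction for per-gene error
bars, verified against Monte-Carlo finite differences of posterior draws.
Whether published gradient-profile error bars were built this way is not
determinable; the choice is documented, not asserted.

## Evaluation toolkit

- **Nearest-neighbour error**: leave-one-out 1-NN misclassification *count*
  over class labels, Euclidean distance, ties to the smallest index.
  Counts (not rates) match how such errors are usually printed.
- **Baselines**: PCA (deterministic full SVD) and FastICA (seeded, then
  canonicalized by kurtosis ordering and first-loading sign so repeated
  runs agree). Rank-deficient inputs are zero-padded with a warning.
- **Subclustering**: two-component full-covariance Gaussian mixture, best
  of 10 seeded initializations, hard assignment; run on latent coordinates
  by default (data-space optional). Welch's unequal-variance t-test
  compares the two subclusters' minimum data-space distances to a reference
  population; the profile reports per-gene mean differences
  (larger-cluster minus smaller-cluster) with the smaller subcluster's SD.
- **Procrustes alignment** (translation + rotation/reflection + isotropic
  scale) for comparing latent configurations to ground truth.

## Synthetic data

The generator emulates a staged single-cell qPCR panel: stages occupy
consecutive arcs of a smooth planar curve (`[4t, 1.6 sin(1.5πt)]`,
t ∈ [0,1]) with within-stage jitter (SD 0.03 along the curve, 0.15
isotropic); the default fixture has 6 stages × 16 cells and 24 genes with
stage 4 split into two branches displaced ±2 latent units along the local
curve normal (split effect 4 against observation noise SD 0.5, seed
20120903). Ordinary genes map from latent space through a random
three-component sinusoidal basis (frequencies 0.4–1.0) — smooth but
deliberately outside the GP model family. Two planted marker genes are
dedicated branch reporters: a strong linear loading (2.0, alternating sign)
on the branch-normal coordinate plus a mild trend along the trajectory;
this emulates lineage markers whose variance is dominated by the fate
split and makes them the strongest between-branch differences by design.
Two control genes have high mean (12) and low SD (0.05) independent of the
latents, so control normalization (subtracting each cell's mean control
level) can be exercised.

For parameter-recovery experiments, `sample_gp_mapping` draws gene columns
exactly from a zero-mean RBF GP over given latents (eigendecomposition
square root with negative eigenvalues clipped, so duplicate latents give
exactly duplicate rows).

What the fixture does *not* emulate: qPCR chemistry (dropout,
amplification artefacts), missing values, realistic gene-gene correlation
structure, and strong nonlinearity — on this fixture the nonlinear
embedding only matches (rather than clearly beats) the PCA baseline's
nearest-neighbour error, so tests passing here demonstrate correctness of
the machinery, not the magnitude of the nonlinear advantage reported on
real embryo panels.

## Problem sizes and numerical choices in the checks

The test suite and `scripts/acceptance.py` run at desk scale by design:
the 96-cell fixture with 800 SCG iterations per γ, a 60×20 latent-recovery
instance, and 20-instance gradient sweeps (N ≤ 12, D ≤ 5). The
latent-recovery experiment draws 60 unit-SD latents and D = 20 GP genes at
lengthscale 2.5 with noise SD 0.1: the lengthscale is chosen large relative
to the latent spread so the configuration is globally identifiable (distant
pairs still covary; at lengthscale ≤ 1.5 roughly a third of instances have
bad local optima that even random restarts do not escape). The fit fixes
the kernel at the generating values and uses a deterministic coarse-to-fine
anneal (noise precision 5, then 100) — the high-noise pass smooths the
likelihood surface before refinement, a standard device for latent-variable
GP fits. Recovery error is 0.08–0.16 true-latent SD units across seeds
1–30.

## Known limitations

- O(N³) likelihood evaluations; hundreds of cells are comfortable,
  tens of thousands are not (no sparse/low-rank approximations).
- Nonconvex objective: different initializations can give different maps;
  only the deterministic PCA initialization is built in, restarts are left
  to the caller.
- Relevance maps are defined for Q = 2 only.
- γ is a manual dial; its useful range depends on the stress normalization
  convention and on the data scale.
- The ΔCt-style input convention (already log-scale, no missing values) is
  assumed; limit-of-detection imputation is available but off by default.
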