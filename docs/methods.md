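# Methods

## Model

`tsee` embeds N cells with expression profiles y₁…y_N (rows of a
preprocessed matrix, values in [0,1]) and normalized collection times
t(n) ∈ [0,1] into X ∈ ℝ^{N×d} by minimizing

    E[X; λ, β] = Σ_{n≠m} w^P_nm ‖x_n − x_m‖²
               + λ Σ_{n≠m} (w^N_nm + β t_nm) exp(−‖x_n − x_m‖²).

The attractive term pulls cells that are similar in expression space
together; the repulsive term pushes all pairs apart, with strength composed
of the expression disparity ‖y_n − y_m‖ and the experimental time interval
|t(n) − t(m)|. A long time interval therefore penalizes proximal placement
even when expression looks similar — the mechanism by which stage-specific
nuisance variation and periodic genes are prevented from collapsing
temporally distant cells onto each other.

Weights are normalized once, before optimization:

- w^P = N⁺·exp(−‖y_n−y_m‖²/2σ²) with N⁺ = 1/Σ_{n≠m} exp(·); the
  off-diagonal sum of w^P is exactly 1.
- w^N = N⁻·‖y_n−y_m‖ and t = N⁻·|t(n)−t(m)| share
  N⁻ = 1/Σ_{n≠m}(‖y_n−y_m‖ + β|t(n)−t(m)|), so Σ(w^N + β t) = 1.

Both sums run over ordered pairs n ≠ m, and the gradient below uses the same
convention. Diagonals are zeroed before normalization: self-affinity is
meaningless and would otherwise inflate N⁺ by exactly N. Note that β enters
twice — inside N⁻ and as the multiplier of t in the energy; the energy is
implemented exactly in this form, and with it every degeneration property
(β = 0 is plain elastic embedding with N⁻ = 1/Σ‖y_n−y_m‖; λ = 0 is the
Laplacian-eigenmap limit) holds identically.

The temporal matrix is one realization of a pluggable symmetric non-negative
side distance. Passing `side_distance` to `fit_tsee` substitutes any other
prior — for example 1 − PCC between cells over spatial marker genes — with
no other change to the algorithm.

## Optimization

The gradient has the Laplacian form ∇E = 4LX where L = D − W is the graph
Laplacian of the combined, possibly signed weight matrix

    w_nm = w^P_nm − λ (w^N_nm + β t_nm) exp(−‖x_n − x_m‖²).

Each iteration solves B p = −g with the partial Hessian
B = L^P ⊗ I_d + μI, where L^P is the Laplacian of the attractive weights —
the convex part of the Hessian. B is constant across iterations, so a single
Cholesky factorization of (L^P + μI) serves the whole fit, and the Kronecker
structure reduces the ND-dimensional solve to d independent N-dimensional
solves. Positive definiteness of B guarantees ⟨p, g⟩ < 0 whenever g ≠ 0.

Numerical choices:

- **Jitter μ.** μ = 10⁻¹⁰ × (largest diagonal entry of L^P): positive and
  scale-aware. A Laplacian's smallest entry is negative (off-diagonals are
  −w), so a jitter proportional to the minimum entry cannot ensure positive
  definiteness; the max-diagonal form realizes the jitter's purpose.
- **Line search.** Armijo backtracking with c = 10⁻⁴, shrink factor 0.5,
  starting from the previous accepted step × 2 (capped at 100). A step that
  underflows below 10⁻¹⁴ without sufficient decrease stalls the iteration,
  which is then treated as converged. Accepted energies are therefore
  non-increasing by construction.
- **Convergence.** Relative Frobenius displacement
  ‖X_{k+1} − X_k‖_F / max(1, ‖X_k‖_F) < 10⁻⁶, or 500 iterations.
- **Bandwidth σ.** Default is the median off-diagonal pairwise Euclidean
  distance of the input rows (scale-adaptive, deterministic); a fixed value
  can be forced with `sigma_policy="fixed:<value>"`. A single global σ is
  used — no per-point perplexity calibration.
- **Initialization.** Default: first d principal-component scores of the
  input, each column rescaled to unit variance and multiplied by 10⁻²
  (deterministic, including a sign convention that makes each component's
  largest-magnitude loading positive). Alternative: i.i.d. Gaussian with
  variance 10⁻⁴ from an explicit seed. `fit_tsee` also accepts an explicit
  starting matrix.
- **Degenerate inputs.** All-identical expression rows make both normalizers
  undefined and are rejected; a single time stage makes the temporal term
  inert (warned). Duplicate embedded points are legal (distance 0 is a valid
  nearest-neighbor minimum; ties break to the smallest index).
- **Complexity.** Affinities and per-iteration energies are dense O(N²); no
  kNN sparsification is applied, and a warning is logged above N = 10,000.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| λ | 10 | attraction vs repulsion trade-off; large values fragment the map into clusters, small values over-compress it |
| β | 10 | temporal vs expression repulsion; 0 disables temporal information entirely |
| d | 2 | embedding dimension |
| σ | median distance | Gaussian bandwidth of the attractive affinities |
| max_iter / step_tol | 500 / 10⁻⁶ | stopping rule |

The weighted-mean stage IGP is flat (< 0.01 movement) across λ ∈ [1, 50] and
β ∈ [1, 50] on the synthetic benchmark, so the defaults are not delicate.

## Preprocessing

Four steps, in order: (1) keep the most variable genes ranked by the Z-score
of their per-gene variance (Z-scoring is monotone in the variance, so this
is a top-variance selection; it is implemented literally anyway), (2)
whole-matrix min-max normalization to [0,1], (3) PCA, keeping the smallest
number of components whose cumulative explained variance reaches 0.95 (an
explicit component count can be forced instead), (4) whole-matrix min-max
normalization of the scores. Stage times are mapped affinely to [0,1]
(earliest stage 0, latest 1). No library-size normalization, log transform
or imputation is applied; whether the input is raw counts or normalized
values is the caller's decision. The variable-gene count (default 1000) and
the 0.95 variance target are conventional choices exposed in
`PreprocessConfig`.

## Metrics

For each cell j, j^N is the index of its nearest embedded neighbor
(Euclidean; ties to the smallest index). With stages as groups:

- IGP(u) = #{j : Class(j) = Class(j^N) = u} / #{j : Class(j) = u}. A
  singleton stage scores 0, since its nearest neighbor is necessarily
  elsewhere.
- IGP2(u) relaxes the match to |Class(j) − Class(j^N)| ≤ 1 on the stage
  rank (not elapsed time), so IGP2 ≥ IGP always.
- The weighted-mean IGP is Σ_u IGP(u)·m_u/N with m_u the stage size.
- A cell is flagged misplaced when its nearest neighbor is ≥ 2 stages away;
  within each stage the flagged fraction is exactly 1 − IGP2.
- Global temporal structure is scored by Pearson correlation between a
  caller-supplied per-cell ordering (an external pseudotime, or the
  synthetic ground-truth latent time projected out of the embedding's first
  principal axis) and the experimental time. No pseudotime method is
  implemented here.
- Stage-level geometry can be summarized by complete-linkage agglomeration
  of the per-stage centroids (scipy linkage matrix: merge order and
  heights).

All neighbor-based scores are invariant under rigid motions and uniform
scaling of the embedding.

## Synthetic data

The generator draws a latent time uniformly on [0,1] per cell; stages are
the n_stages equal-width bins of latent time (each bin guaranteed
non-empty). Genes are smooth functions of latent time: sigmoids with random
center, slope and direction (switch-like programs), Gaussian bumps
(transient programs), and sinusoids sin(2π·n_periods·t + φ) rescaled to
[0,1] (oscillatory genes, mimicking segmentation-clock-like transcripts that
repeat across the course and thereby confuse purely expression-based
neighborhoods). Two nuisance layers follow: an additive shift vector per
stage, drawn Gaussian(0, batch_shift_sd) and shared by all cells of the
stage (run-to-run technical variation), and i.i.d. Gaussian(0, noise_sd)
measurement noise. The final matrix is globally min-max normalized — an
affine map that changes no structure.

Defaults (300 cells, 5 stages, 50 genes, 10 oscillatory over 2 periods,
batch_shift_sd 0.5, noise_sd 0.25) describe a moderately noisy course.
`hard_recovery_config()` is the benchmark regime (noise_sd 0.9,
batch_shift_sd 0.25) in which expression alone no longer resolves stages —
a plain elastic embedding's weighted-mean stage IGP falls below 0.8 there,
which is the regime where the temporal term has something to correct. A
point worth recording: the per-stage additive shift alone cannot blur stage
purity, because a shift shared by every cell of a stage only separates
stage clusters in expression space; what it destroys is the *global*
arrangement of stages (latent-time recovery degrades sharply as the shift
grows). Local purity is degraded by noise. The benchmark therefore uses
noise as the purity-degrading nuisance and the shift as the global-order
confound.

What the generator does not emulate — and hence what passing tests do not
establish about real data: count statistics (dropout, library-size
variation, overdispersion), branching or converging trajectories,
cell-cycle structure, and gene-gene correlation beyond the shared latent
time. Conclusions about real time courses require the real pipelines.

## Problem sizes and determinism

The test suite and the reproduction script run at desk scale: N ≤ 300
cells, 5 synthetic seeds per comparison, ≥ 20 random instances for the
gradient and metric oracles. Every random draw flows from explicit seeds;
fits are deterministic given (dataset, config, side distance, start), and
the CLI pipeline is bit-reproducible given identical flags.

## Known limitations

- Dense O(N²) memory and per-iteration time; tens of thousands of cells are
  the practical ceiling on one machine.
- A single global σ can over- or under-smooth datasets with very uneven
  density.
- The method consumes collection time as a hard prior: if the biological
  process is asynchronous across cells within a stage, the temporal
  repulsion can separate cells that are genuinely in the same state; β
  controls that trade-off.
- No out-of-sample extension: new cells require a refit.
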