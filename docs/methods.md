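# Methods

## Model

`makl` fits a binary classifier of the form

    f(x) = β₀ + Σ_p z_p(x)ᵀ β_p ,

where z_p(·) is a randomized low-dimensional approximation of a Gaussian
kernel restricted to gene set F_p, and the coefficient blocks β_p are
estimated under a block-ℓ1 (group-Lasso) penalty. The model class is the
same as multiple kernel learning with one Gaussian kernel per gene set,
except that each N×N kernel matrix is replaced by an N×2D feature block,
so cost scales linearly instead of quadratically in the number of samples.

### Random Fourier blocks

A shift-invariant positive-definite kernel is the Fourier transform of a
probability measure (Bochner), so k(x, y) can be estimated by Monte-Carlo
over frequencies drawn from that measure. For the Gaussian kernel of
width σ the frequency law is N(0, σ⁻²I). The map used here pairs cos and
sin features and normalizes by 1/√D:

    z(x) = D^{−1/2}[cos(δ_jᵀx + b_j) … sin(δ_jᵀx + b_j) …] , j = 1..D,

with offsets b_j ~ U[0, 2π). Properties relied on elsewhere:

- each cos² + sin² pair contributes exactly 1/D, so ‖z(x)‖₂ = 1 for every
  x and Z Zᵀ has an exactly unit diagonal (the classic √(2/D)·cos-only map
  guarantees this only in expectation);
- z(x)ᵀz(y) is an unbiased estimator of k(x, y); the offsets cancel
  identically in the cos/sin pairing and are retained for fidelity to the
  construction, not because they change the estimator;
- the entrywise error of Z Zᵀ decays as 1/√D.

The bandwidth σ_p of each set's kernel is the mean Euclidean distance
over the S(S−1)/2 distinct pairs of a random row subset of size
S = min(N, 1000) of the (normalized) training matrix, computed on that
set's columns only. The zero diagonal is excluded and no pair is counted
twice; a full-matrix mean would deflate σ slightly. A set whose sampled
rows coincide (σ = 0, e.g. constant columns) is dropped from that fit
with a warning rather than aborting.

### Group Lasso

With labels mapped to s_i = 2y_i − 1 the objective is

    Σ_i log(1 + exp(−s_i f_i)) + λ Σ_p w_p ‖β_p‖₂ ,   w_p = √(2D),

with an unpenalized intercept. λ is always specified as a multiplier of
λ_max = max_p ‖Z_pᵀ(p̂ − y)‖/w_p evaluated at the intercept-only optimum
β₀ = log(n₁/n₀): the smallest penalty at which all blocks are zero. Since
every block has the same width 2D, any constant group weight is absorbed
into the multiplier parametrization; √(2D) is the standard convention.

Solver: monotone FISTA. Each iteration takes an accelerated proximal
gradient step with the exact Lipschitz step 1/L (L = 0.25·σ_max²([1|Z]),
power iteration, +2% margin; a backtracking loop guards the majorization),
applies block soft-thresholding — which produces *exact* zero blocks — and
falls back to the previous iterate if the objective would increase, so the
objective history is non-increasing. Two practical details:

- adaptive restart (O'Donoghue–Candès criterion) with restarts at least
  10 iterations apart; ungated, the criterion fires on sign noise near the
  optimum and degrades the accelerated rate;
- candidates are accepted within 16·eps·|F| of the incumbent objective.
  With a strict comparison the iteration can freeze: once true progress
  per step is below float resolution the candidate can round to slightly
  above the incumbent forever, while prox steps would still polish the
  KKT residual by orders of magnitude.

Convergence is declared when the KKT residual — max over groups of
max(0, ‖∇_p‖ − λw_p) for zero blocks and ‖∇_p + λw_p β_p/‖β_p‖‖ for
nonzero blocks, plus the absolute intercept gradient — falls below `tol`
(default 1e-6, max_iter 5000). Exhausting max_iter returns the model with
`converged=False` and a warning. On the evaluation harness's problem
sizes the harness uses tol 1e-5 and max_iter 3000: the residual lives on
a sum-over-samples loss scale, so 1e-5 at N ≈ 400 is tighter than the
module default at N = 40, and selection/AUROC are insensitive to the
difference.

### Prediction and selection

The maps (σ_p, Δ_p, b_p), the per-gene training mean/SD, and the
coefficients are frozen at fit time; new data is reordered to the
training gene layout, normalized with the stored statistics, and
transformed with the identical maps. Scores are returned on the linear
(log-odds) scale — AUROC is rank-based, so no sigmoid is applied.
η_p = ‖β_p‖₂ ranks sets; selection is η_p > 0, exact because zeros come
from the prox. The gene-coverage fraction is |∪ selected sets' genes| /
total genes (overlaps counted once).

## Evaluation protocol

Per replication: stratified 80/20 split (largest-remainder per-class
allocation, both classes guaranteed on both sides); per-gene
z-normalization with training statistics (sample SD, n−1; constant
columns map to zeros); 4-fold stratified inner CV over the multiplier
grid {0.9, 0.8, 0.7, 0.6}, each fold re-estimating bandwidths and maps on
its own training part and warm-starting the multiplier path from large to
small; the multiplier with the best mean validation AUROC wins, ties
toward the larger (sparser) value; refit on the full training split;
test AUROC (Mann–Whitney, ties ½), selected sets and gene coverage
recorded. A master seed spawns independent per-replication streams
(split / CV / fit), so extending R never perturbs earlier replications.
The inner-CV criterion is validation AUROC; deviance would also be
defensible, and the choice is isolated in one function.

Splits and folds are stratified by label even though the protocol source
does not say; unstratified folds can lose a class on imbalanced cohorts.

## Synthetic data generator

The generator emulates the statistical structure the method targets, not
sequencing physics (no count marginals or library-size effects):

- genes organized in P named sets, equicorrelated Gaussian within a set
  (correlation ρ, default 0.3), independent across sets; optional overlap
  variant where consecutive sets share a fraction of their genes;
- k informative sets each contribute a radial bump
  exp(−‖u_p − c_p‖²/γ) of the sample's profile u_p on that set's genes,
  with fixed random centers c_p (per-coordinate SD 0.25, i.e. near the
  origin) and γ = d_p / signal_scale;
- bumps are standardized over the cohort before summing so each
  informative set contributes comparably regardless of the realized
  center — without this the weakest set's selection frequency is
  unstable;
- the summed score is thresholded at its median (forcing ~50/50 classes)
  and labels are flipped at rate ε per class (stratified flips preserve
  the balance the threshold created; independent flips drift it).

Default study: N = 500, d = 500, P = 20 disjoint sets of 25 genes,
k = 3, ρ = 0.3, ε = 0.05, signal_scale = 1.0, seed 7. A near-origin
center makes the bump an even function of the set's latent factor, so the
class boundary is radial: representable by a Gaussian-kernel machine,
invisible to a linear model on raw genes (the L1 logistic baseline stays
near AUROC 0.5). The bump width was calibrated once so that the
20-replication mean test AUROC of the pipeline lands inside (0.8, 0.95)
at D = 50 — the regime where the recovery checks are sensitive in both
directions; sharper bumps (signal_scale ≥ 2) are no longer learnable at
this D and sample size, shifted centers leak linear signal.

What passing the synthetic checks does *not* show: robustness to heavy-
tailed expression marginals, batch effects, label imbalance far from
50/50, or gene sets whose signal is linear rather than radial.

## Numerical choices and degenerate inputs

- Exact zeros throughout the selection path: no epsilon thresholds.
- Labels accepted as {0,1} only; both classes required for fitting,
  splitting and AUROC.
- Constant training genes normalize to zero in train and test (guarded
  division).
- GMT parsing: ≥3 tab-separated fields per line, duplicate genes within a
  line deduplicated, duplicate set names rejected, empty files rejected;
  symbols matched case-sensitively with no alias translation; sets
  resolving below `min_size` (default 1) are dropped with a warning.
- Model persistence is a single .npz archive (maps, normalization,
  coefficients, names); loading reproduces scores bit-for-bit.
- Problem sizes in the acceptance runs: the replication study uses R = 20
  and D = 50 on the default fixture; solver cross-checks use N = 40
  instances; the Fourier-error check uses 50 points in R²⁰ averaged over
  10 maps. These sizes are the package's standard small-study settings.

## Known limitations

- Binary classification only (no regression branch, no multi-class).
- Gaussian kernel + random Fourier features only; the block interface
  would admit other approximations but none ship.
- Non-overlapping group penalty: a gene in several sets contributes
  independent coefficients per block; no overlap-aware penalty.
- The bandwidth heuristic is scale-sensitive by design; it presumes
  upstream normalization (the harness z-normalizes).
- λ is tuned on the fixed multiplier grid; no continuation path beyond it.
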