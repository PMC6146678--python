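# Methods

`ffasr` implements a family of example-based single-image super-resolution
(SISR) methods for fundus fluorescein angiography (FFA) and evaluates them
under a shared degradation/evaluation protocol. This note records the models,
the conventions the package fixes where the literature leaves them open, and
what the synthetic benchmark does and does not show.

## Degradation model and patch geometry

The low-resolution image is modeled as a pure spatial downsampling of the
high-resolution image, `x_l = G x_h`, with no separate blur operator: `G` is a
bicubic downsampler. The same separable Keys cubic kernel (a = −0.5) is used
for degradation, for the interpolation baseline and inside evaluation, with
the kernel support stretched by the scale factor when shrinking
(antialiasing) and replicate-clamped at borders. Self-consistency between the
degradation operator and the baseline matters more than the identity of the
kernel, so one implementation serves all three roles; it is float64
throughout and is cross-checked in the tests against an independently coded
direct evaluation of the same kernel and, loosely, against PIL.

Training pairs are dense overlapping patches: 3×3 LR patches on a stride-2
grid (one extra flush-to-border patch per axis when the stride does not tile
exactly), paired with 3M×3M HR patches anchored at M× the LR anchor, for
upscaling factor M ∈ {2, 4}. The LR patch's DC mean is removed from both
vectors of a pair and re-added at reconstruction; this makes all the linear
patch models invariant to local intensity offsets. No gradient features and
no PCA are applied: the regression space is the raw mean-removed intensity
patch. Whole-image reconstruction runs the same dense grid on the test LR
image, predicts each HR patch, re-adds the DC means, and averages overlapping
pixels with equal weights before clipping to [0, 1].

## The method families

All methods consume the same `PatchPairSet` and are evaluated identically.

- **NE+LS / NE+NNLS** (neighborhood embedding): for each query the K = 24
  nearest LR training patches (exact exhaustive Euclidean search, ties to the
  lower index) define reconstruction weights — sum-to-one least squares via
  the locally-linear-embedding Gram closed form (ridge jitter
  `1e-8·trace/K`), or non-negative least squares — applied to the paired HR
  patches.
- **SB-Yang** (coupled dictionary): alternating minimization of the joint
  objective `(1/S_h)‖X_h − D_h Z‖² + (1/S_l)‖X_l − D_l Z‖² +
  λ(1/S_h + 1/S_l)‖Z‖₁` with B atoms and λ = 0.1. The 1/S weights are folded
  into the stacked signal as 1/√S scalings; stacked training vectors are
  unit-normalized so the sparsity weight is scale-free. The coding step is a
  batched proximal-gradient lasso (FISTA with a monotone restart safeguard),
  the dictionary step the exact least-squares update; columns are normalized
  once after training with paired rescaling of `D_h` so the coupled LR→HR map
  is unchanged. In-loop renormalization is deliberately avoided: it changes
  the L1 term and would break the non-increasing objective that the trainer
  records and the tests assert. Reconstruction codes the unit-normalized
  query against `D_l` with the *same effective weight as training*,
  λ(1/S_h + 1/S_l), and rescales — using the raw λ at test time would make
  test codes several times sparser than the codes the dictionary was trained
  for.
- **SB-Zeyde**: K-SVD on the LR patches (OMP coding with at most L = 3 atoms
  per code, rank-1 SVD atom updates, dead and near-duplicate atoms re-seeded
  from the worst-represented signal, guarded re-coding so the recorded MSE is
  non-increasing per sweep), then the HR dictionary in closed form,
  `D_h = X_h Zᵀ(Z Zᵀ + εI)⁻¹` with ε = 1e−8. Reconstruction is OMP against
  `D_l` followed by `D_h α`.
- **ANR / A+**: per-atom ridge projections
  `P_j = N_h (N_lᵀ N_l + λI)⁻¹ N_lᵀ` precomputed offline over the K = 40 most
  |correlated| atoms (ANR) or the K = 2048 most correlated training patches
  (A+, correlation measured on normalized patches, raw values in the ridge),
  starting from the Zeyde-trained dictionary. Reconstruction is a
  nearest-anchor lookup (absolute correlation on the normalized query) and
  one matrix–vector product; zero-norm patches map to the zero HR patch.
  Projections are computed through the push-through identity so the solve
  stays in the 9-dimensional LR space even for K = 2048.
- **JOR**: O = 32 ridge regressors and a hard cluster indicator fit by an
  EM-style alternation — per-cluster ridge fits, then reassignment of every
  sample to its best regressor — for up to 20 iterations or until stable,
  from a seeded random initial assignment; an emptied cluster seizes the
  worst-reconstructed sample. At test time a patch takes a majority vote over
  the cluster labels of its K = 32 nearest training patches (ties: larger
  summed inverse distance, then lower index). The trainer records both the
  plain reconstruction SSE and the ridge-penalized objective; only the latter
  is a true Lyapunov function of the implemented alternation (each half-step
  minimizes it), so monotonicity is asserted on it. Optional seeded restarts
  keep the best final objective; EM from random assignments is sensitive to
  its local minimum.
- **SRF**: T regression trees, each grown by choosing among 32 random
  (feature, threshold) candidates — feature uniform, threshold uniform in the
  node's range — the split minimizing the sample-weighted mean of the
  regularized quality `E = mean(‖x_h − m(x_l)‖² + κ‖x_l − x̄_l‖²)` with
  κ = 1, where `m(·)` during the structure search is the child's mean HR
  vector (refitting a ridge per candidate would be quadratically more
  expensive; leaves are refit once the structure is fixed, consistent with
  fitting leaf models after tree construction). Growth stops at depth ξ_max,
  at `min_leaf = S_l + 1` samples (so leaf ridge systems are overdetermined),
  or at zero gain. Leaves hold the closed-form ridge map; the forest averages
  the routed leaf predictions. No bootstrap: per-tree randomness comes from
  candidate sampling (a config flag can enable bagging). Default operating
  point T = 6, ξ_max = 15.

Published operating points are the package defaults throughout: NE K = 24;
B = 2048, λ = 0.1 for both sparse trainers; ANR K = 40, A+ K = 2048;
JOR O = 32, 20 iterations, K = 32; SRF T = 6, depth 15, λ = 0.1, κ = 1. The
one exception is the K-SVD sparsity L, which defaults to 3 per-code atoms
(the classical operating point of this trainer, exposed as a config knob):
with 9-dimensional raw LR patches, any active set of 9 independent atoms
represents any patch *exactly*, so an L ≥ 9 budget makes OMP an exact
interpolator — the training MSE collapses to machine zero, the codes carry
no structure, and the pseudo-inverse HR dictionary becomes ill-conditioned
enough to destabilize the anchored regressors built on top of it.

## The ridge/lasso scale convention

The λ values above originate in reference implementations of this method
family that operate on normalized feature spaces (unit-norm patch features
are the de facto standard). Raw mean-removed intensity patches on [0, 1]
data have per-sample energies of roughly 0.01–0.2, so applying λ = 0.1
literally makes the penalty comparable to — or larger than — the data term
and visibly over-smooths every local regressor. The package therefore treats
λ as dimensionless: every trainer multiplies it once by the mean per-sample
energy of its training pool (`λ_eff = λ · mean‖x_l‖²`), fixed before
optimization starts. For ANR, whose anchors are unit-normalized atoms, this
is exactly the identity; for Yang the analogous choice is the unit-norm
coding described above. The scale is a single global constant per trainer,
never adapted per node or per query, which keeps JOR's penalized objective a
valid Lyapunov function and keeps all cross-module ridge equivalences exact.

## Synthetic fundus phantoms

The clinical dataset this toolkit targets (groups of "homologous" angiogram
frames per eye) is emulated by a phantom generator: a bright optic disc, a
dark macular region, a branching vessel tree of quadratic Bézier segments
with shrinking widths (bright vessels, as in an angiogram's filling phases),
a smooth linear illumination gradient, and additive Gaussian noise
(σ = 0.01), rendered hard-edged at 128² and clipped to [0, 1]. Per-vessel
randomness is drawn from spawned seed streams so a fixed seed makes the
first k vessels identical regardless of the vessel count. Homologous frames
are seeded perturbations of a group's base phantom: translation ≤ 5 px,
rotation ≤ 3°, multiplicative illumination in [0.9, 1.1] — the variation the
clinical protocol attributes to acquisition conditions. The default dataset
is 10 groups × 4 frames, split 2 train / 2 test per group following the
23:14 train:test proportion of the clinical protocol; the
homologous-exclusion experiment drops four groups' training shares entirely
and compares models on those groups' unchanged test images.

What the phantom does *not* emulate: dye-transit dynamics, capillary-scale
texture, pathology, optics blur, or sensor nonlinearity. Its consequences
show up in the benchmark: because every test frame has near-duplicate
training frames from the same simulated eye, exact nearest-neighbor lookup
(the NE family) is close to optimal on this data and outranks the regression
forests — the opposite of the ordering reported on clinical data, where LR
patches are far more ambiguous. Passing the synthetic benchmark therefore
demonstrates pipeline correctness and the learned-versus-baseline direction,
not the clinical ranking of methods. Similarly, the jointly-trained coupled
dictionary (SB-Yang) sits at baseline level here: with raw 3×3 LR patches
its well-known train/test coding inconsistency (codes are trained on stacked
LR+HR signals but inferred from LR alone — the defect the Zeyde variant
removes) is not offset by the richer feature pipelines its reference
implementation uses.

## Problem sizes and numerics

The default benchmark (`run_benchmark`, and `scripts/acceptance.py`) uses
desk-scale reductions chosen as the package's own operating point: B = 512
dictionary atoms, A+ neighborhood pool capped at 20 000 patches, SRF with
T = 3 trees at depth 10; dictionary learning subsamples the patch pool
(10 000 patches for K-SVD, 5 000 for the joint trainer with 5 alternations —
subsampling for dictionary learning is standard in this family). Everything
is seeded: dataset generation, subsampling, initializations and candidate
draws all derive from one seed via spawned `SeedSequence` streams, and the
`train → super-resolve → evaluate` chain is hash-stable.

Numerical conventions worth knowing: PSNR uses peak 1.0 on the normalized
scale (≡ 255 for 8-bit sources) and reports `inf` for identical images; SSIM
is the standard Gaussian-window parameterization (σ = 1.5, K1 = 0.01,
K2 = 0.03, dynamic range 1) via scikit-image and requires images of at least
11×11. Ridge solves pick the better-conditioned side of the push-through
identity (primal for small neighborhoods, dual otherwise). kNN ties break to
the lower pool index, including exact boundary ties. OMP stops early once
the residual norm drops below 1e−10, and an active set never exceeds the
signal dimension. Degenerate inputs are defined everywhere: zero-norm
patches reconstruct to the zero (DC-only) patch, empty JOR clusters are
repaired, dead or duplicated K-SVD atoms are re-seeded.

## Known limitations

- The phantom's homology is stronger than clinical homology; method rankings
  on it do not transfer (see above).
- SB-Yang inherits the coupled-coding inconsistency of its formulation and
  should be expected to trail the Zeyde variant everywhere.
- The degradation model deliberately omits a blur kernel; models trained
  under it will not match sensors with significant optical blur.
- ×4 reconstruction maps 9-dimensional LR patches to 144-dimensional HR
  patches; all linear patch models are strongly underdetermined there and
  lean on the overlap averaging.
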