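# Methods

## Model

sglrr clusters the `n` sample columns of an expression matrix
`X ∈ ℝ^{m×n}` under the union-of-subspaces assumption: samples from the
same biological group lie near a shared low-dimensional linear subspace.
The representation `Z ∈ ℝ^{n×n}` is estimated from

```
min_{Z,E}  ‖Z‖* + λ‖Z‖₁ + β tr(Z L Zᵀ) + γ‖E‖₁
s.t.       X = XZ + E,   Z = Zᵀ ,
```

with `L = D − W` the unnormalized Laplacian of the binary k-nearest-neighbor
graph of the samples. The model assumes (i) approximate self-expressiveness
`X ≈ XZ` with the data matrix itself as the dictionary, (ii) corruption that
is sparse and element-wise (absorbed by `E` under `‖·‖₁`), and (iii) locally
smooth geometry, encoded by the neighbor graph. Because the dictionary is
the observed `X`, heavy corruption degrades both the dictionary and the
neighbor graph; the `E` term models additive error in the fidelity
constraint only.

## Graph construction

Neighbors are found by Euclidean distance between raw sample columns
(configurable metric; Euclidean default). `w_ij = 1` if either sample is
among the other's `k` nearest (the OR rule, which forces symmetry), the
diagonal is fixed at zero, distance ties break toward the lower sample
index so the graph is deterministic, and duplicate columns neighbor each
other (distance zero sorts first). Default `k = 5`. The unnormalized
Laplacian is used; its rows sum to zero exactly and it is positive
semi-definite.

## Solver

The constrained problem is split with an auxiliary `J = Z` carrying the
`λ‖J‖₁` term (kept nonnegative, so `J` reads as a sparse similarity), and
solved by linearized ADMM with adaptive penalty:

1. **Z step.** The smooth coupling term is linearized at `Z_k` with step
   `η₁ = 2β‖L‖₂ + μ(1 + ‖X‖₂²)` and gradient
   `∇q = β(Z Lᵀ + Z L) + μ(Z − J + Y₂/μ) + μ Xᵀ(XZ − X + E − Y₁/μ)`.
   The update is the proximal operator of the nuclear norm over symmetric
   matrices at `Q = Z_k − ∇q/η₁`: symmetrize `Q`, skinny SVD, soft-threshold
   the singular values at `1/η₁`. For a symmetric point this singular-value
   thresholding is the unique minimizer of
   `ε‖P‖* + ½‖P − Q‖_F²` over symmetric `P`; the implementation is verified
   against a direct numerical minimizer of that objective (smoothed
   eigenvalue formulation with continuation) in the test suite.
2. **E step.** Element-wise shrinkage of `X − XZ + Y₁/μ` at `γ/μ`.
3. **J step.** Element-wise shrinkage of `Z + Y₂/μ` at `λ/μ`, clipped at
   zero.
4. **Multipliers and penalty.** `Y₁ += μ(X − XZ − E)`, `Y₂ += μ(Z − J)`,
   then `μ ← min(ρμ, μ_max)`.

All variables start at zero — with `X = 0` this makes the first iterate the
exact solution, so the degenerate case converges in one iteration. The
stopping rule requires both the relative primal residual
`‖X − XZ − E‖_F/‖X‖_F ≤ tol_primal` and
`max(‖Z − J‖_∞, ‖ΔZ‖_∞) ≤ tol_change`. Non-convergence at `max_iter`
returns a flagged solution with a warning rather than raising; a NaN in
any iterate raises immediately with the iteration index. The solver is
fully deterministic.

Numerical choices: `‖X‖₂` and `‖L‖₂` are computed once; `η₁` is recomputed
whenever `μ` changes; singular values ≤ 1e-10·σ_max are treated as zero
(skinny SVD cut); the Z iterate is re-symmetrized after reconstruction to
remove SVD round-off (the stored asymmetry is exactly zero in practice).

### Defaults and their rationale

| parameter | default | role |
|---|---|---|
| λ | 0.1 | sparsity of Z; 0 disables the J-coupling penalty's shrinkage |
| β | 1.0 | weight of the manifold term |
| γ | 0.5 | weight of the sparse error; size to the expected outlier level |
| μ₀, ρ, μ_max | 1e-2, 1.1, 1e6 | adaptive penalty schedule |
| tol_primal, tol_change | 1e-4 | stopping tolerances |
| max_iter | 500 | iteration cap |
| k | 5 | neighbor count |

λ, β and γ are starting points, not calibrated constants: the objective
weights are data-dependent, which is why all three are mandatory-visible
CLI flags. On the package's reference synthetic conditions the defaults
converge in ≈150 iterations and recover the generating clusters exactly.

## Affinity and clustering

`Z*` is factored by skinny SVD, `Z* = U* Σ* (V*)ᵀ` over positive singular
values, and the affinity is the squared cosine between the rows of
`M = U*(Σ*)^{1/2}`. Squaring removes the singular-vector sign ambiguity;
cosines make `H` invariant to positive rescaling of `Z*`. For symmetric
`Z*` the row factor `N = (Σ*)^{1/2}(V*)ᵀ` yields the same `H` (asserted in
a test; `M` is used in production). Rows of `M` that are exactly zero
(samples outside the span of `Z*`) receive unit self-affinity and zero
edges, so every node keeps positive degree. No affinity exponent is
exposed: the square is fixed.

Clustering is the Ng–Jordan–Weiss realization of normalized cuts: the
symmetric normalized Laplacian `I − D_H^{-1/2} H D_H^{-1/2}`, the `k`
eigenvectors of smallest eigenvalue, row-normalization of the embedding,
then k-means with k-means++ initialization and squared Euclidean distance
(20 restarts by default, best inertia kept; dense eigendecomposition up to
n = 2000, an iterative shifted solver above). Because k-means++ seeds
randomly, evaluation reruns the clustering (default 50 repeats, seeds
derived from a master seed) and reports mean ± std of the four metrics.

## Metrics

* **Acc** — best match rate under a one-to-one cluster-to-class mapping,
  found by the Kuhn–Munkres algorithm on the contingency table.
* **MCC, RI** — pair-counting over all `n(n−1)/2` unordered pairs:
  TP same/same, FP different-true/same-predicted, TN different/different,
  FN same-true/different-predicted. MCC returns 0 when any marginal factor
  of its denominator vanishes (the "no association" value);
  RI = (TP+TN)/total.
* **NMI** — `2·I(Ξ;Ω)/(H(Ξ)+H(Ω))` with plug-in probabilities and base-2
  logarithms; two identical trivial partitions score 1, and if exactly one
  partition has zero entropy the score is 0.

Internally all metrics live on the 0–1 (MCC −1..1) scale; the CLI and the
acceptance script multiply by 100 for display, following the percentage
convention of the field's comparison tables.

## Synthetic data

The generator draws, for each of `g` groups, an orthonormal basis of a
`d`-dimensional subspace of ℝ^m — in the independent regime
(`g·d ≤ m`) the bases are disjoint blocks of one random orthonormal frame,
so spans are mutually orthogonal — and samples standard-normal
coefficients in it. Element-wise Gaussian noise (σ) and sparse corruption
(each entry independently hit with probability `p`, additive uniform
±scale) are applied on top; an optional shift-and-clip mimics nonnegative
intensity scales (off by default). Coefficients are standard normal
because the downstream affinity is cosine-based and therefore scale-free;
corruption is uniform-magnitude to mimic heavy-tailed artifacts.

The reference study conditions used throughout the tests and the
acceptance script are: 3 subspaces, dimension 4, ambient dimension 50,
40 samples per subspace (n = 120), σ = 0.01; the corruption variant adds
5% corruption at scale 5. These sizes keep a full solve under a second
while leaving the subspace structure non-trivial (the noisy matrix is
full-rank at 50, with block low-rank structure underneath).

What the generator does *not* emulate: count distributions (negative
binomial), library-size variation, batch effects, dropout. Passing tests
therefore demonstrate correctness of the algorithm on data satisfying its
own geometric assumptions, not performance on real sequencing data.

## The corruption experiment

With 5% corruption at scale 5, a typical column's corruption has larger
Euclidean norm than its signal (entry std ≈ 0.27 against outliers up to
±5), and nearly every column is hit. Two consequences follow. First, γ
must be sized to the corruption: at γ ≈ 0.025 the shrinkage threshold lets
`E` absorb the outliers without swallowing the signal (γ below ≈ 0.02
starts absorbing signal even on clean data; γ above ≈ 0.05 leaves
corruption in the fidelity term). Second, the kNN graph — built on the
corrupted columns — no longer reflects the true geometry, so the manifold
term propagates wrong neighborhoods; the corruption experiment therefore
runs with β = 0, and both its arms (clean and corrupted) use the same
weights so the comparison isolates the corruption effect. Under these
conditions mean accuracy over ten seeds drops from 1.00 to ≈ 0.91,
which is the robustness the `‖E‖₁` term buys; with default weights the
corrupted problem is substantially harder (accuracy ≈ 0.5), which is a
genuine property of graph-regularized models under dictionary corruption,
not an implementation artifact.

## Limitations

* Dense `n×n` SVD per iteration: O(n³) per step; practical to a few
  thousand samples on one core.
* λ, β, γ have no automatic selection; results on real data depend on
  them materially.
* The sparse error model addresses element-wise outliers only; structured
  (column-wise) corruption would need an `‖E‖₂,₁` variant, which is not
  implemented.
* The kNN graph is built on the observed (possibly corrupted) data;
  robustifying the graph itself is out of scope.
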