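# sglrr

Subspace clustering of expression matrices by **graph-regularized low-rank
representation with symmetric and sparse constraints** (sgLRR), combined
with normalized-cuts spectral clustering.

## The problem

Bulk and single-cell expression studies often pool samples from several
biological conditions (for example, several tumor types). Each condition's
samples tend to lie near their own low-dimensional linear subspace of
feature space, so recovering the conditions is a *union-of-subspaces*
clustering problem. Plain k-means or PCA ignores that structure; low-rank
self-representation exploits it: expressing every sample as a linear
combination of all samples, `X ≈ XZ`, with `Z` of minimal rank, makes `Z`
approximately block-diagonal with one block per subspace.

## The model

Given a features × samples matrix `X ∈ ℝ^{m×n}`, sglrr solves

```
min_{Z,E}  ‖Z‖* + λ‖Z‖₁ + β tr(Z L Zᵀ) + γ‖E‖₁
s.t.       X = XZ + E,   Z = Zᵀ
```

* `‖Z‖*` — nuclear norm, the convex surrogate for rank;
* `λ‖Z‖₁` — sparsity, localizing each sample's representation;
* `β tr(Z L Zᵀ)` — manifold regularization through the unnormalized
  Laplacian `L = D − W` of the k-nearest-neighbor graph of the samples,
  preserving local geometry;
* `γ‖E‖₁` — element-wise sparse error absorbing gross corruption;
* `Z = Zᵀ` — a symmetric representation, so mutual similarities agree
  without lossy post-hoc symmetrization.

The problem is solved by linearized ADMM with adaptive penalty (LADMAP);
the `Z` step is a symmetric singular-value thresholding (the closed-form
proximal operator of the nuclear norm over symmetric matrices). From the
solution `Z*`, the affinity `H_ij = (cos angle between principal-direction
rows of U*(Σ*)^{1/2})²` feeds normalized-cuts spectral clustering, and
agreement with ground truth is scored by Acc (Kuhn–Munkres optimal
mapping), pairwise MCC, Rand index and NMI, averaged over repeated
k-means++ runs.

## Worked example

Simulate a three-subspace dataset (three clusters of 40 samples on
4-dimensional subspaces of ℝ⁵⁰, noise σ = 0.01) and cluster it:

```sh
$ sglrr simulate --seed 0 --output-dir demo_fixture
wrote 50x120 matrix to .../demo_fixture

$ sglrr run demo_fixture/matrix.tsv --n-clusters 3 \
      --labels demo_fixture/labels.csv --repeats 50 --seed 0 \
      --output-dir demo_out
solver: converged in 153 iterations
 ACC: 100.00 (std 0.00)
 MCC: 100.00 (std 0.00)
  RI: 100.00 (std 0.00)
 NMI: 100.00 (std 0.00)
outputs written to .../demo_out
```

The solver satisfied `X = XZ + E` to the 1e-4 relative tolerance after 153
iterations, and all 50 repeated normalized-cuts runs assigned every sample
to its generating subspace (metrics are printed as percentages; std is the
spread over the 50 k-means++ repetitions). `demo_out/` contains the
per-sample cluster labels (`labels.csv`), the metric summary
(`metrics.json`) and the solver residual trace (`residuals.csv`).

The same pipeline is available as a library:

```python
from sglrr import (SubspaceSpec, generate_subspace_data, build_knn_graph,
                   SgLRRParams, solve_sglrr, build_affinity,
                   repeated_cluster_metrics)

X, labels = generate_subspace_data(SubspaceSpec(seed=0))
params = SgLRRParams()                      # lambda=0.1, beta=1.0, gamma=0.5
graph = build_knn_graph(X, params.k_neighbors)
sol = solve_sglrr(X, graph, params)
H = build_affinity(sol.Z)
print(repeated_cluster_metrics(H, 3, labels, n_repeats=50, seed=0)["acc"])
# {'mean': 1.0, 'std': 0.0}
```

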