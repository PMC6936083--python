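"""Union-of-subspaces synthetic expression data.

Emulates the structure the method assumes: each cluster of samples lives
on its own low-dimensional linear subspace of feature space, with
additive Gaussian measurement noise and sparse gross corruption on top.
In the independent regime (sum of subspace dimensions <= ambient
dimension) the subspaces are drawn with mutually orthogonal spans from a
single random orthonormal frame, so the clean matrix has exactly
block-structured low rank. This captures the geometry that drives
subspace clustering while deliberately ignoring count noise, library
size and batch effects of real expression data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph import ExpressionMatrix

__all__ = ["SubspaceSpec", "generate_subspace_data", "write_fixture"]


@dataclass
class SubspaceSpec:
    """Parameters of the union-of-subspaces generator.

    noise_sigma is the standard deviation of the element-wise Gaussian
    noise; each entry is independently corrupted with probability
    corruption_fraction by an additive value uniform on
    [-corruption_scale, corruption_scale]. nonneg_shift > 0 adds a
    constant and clips at zero to mimic an intensity scale (off by
    default).
    """

    n_subspaces: int = 3
    subspace_dim: int = 4
    ambient_dim: int = 50
    samples_per_subspace: int = 40
    noise_sigma: float = 0.01
    corruption_fraction: float = 0.0
    corruption_scale: float = 0.0
    seed: int = 0
    nonneg_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subspaces < 1 or self.subspace_dim < 1:
            raise ValueError("n_subspaces and subspace_dim must be >= 1")
        if self.samples_per_subspace < 1:
            raise ValueError("samples_per_subspace must be >= 1")
        if self.subspace_dim > self.ambient_dim:
            raise ValueError("subspace_dim cannot exceed ambient_dim")
        if self.noise_sigma < 0 or self.corruption_scale < 0:
            raise ValueError("noise_sigma and corruption_scale must be >= 0")
        if not (0.0 <= self.corruption_fraction <= 1.0):
            raise ValueError("corruption_fraction must be in [0, 1]")

    @property
    def independent_regime(self) -> bool:
        return self.n_subspaces * self.subspace_dim <= self.ambient_dim

    @property
    def n_samples(self) -> int:
        return self.n_subspaces * self.samples_per_subspace


def generate_subspace_data(spec: SubspaceSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw samples from a union of random linear subspaces.

    Returns the features-x-samples matrix and the generating subspace
    label per sample. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m, d, g = spec.ambient_dim, spec.subspace_dim, spec.n_subspaces

    if spec.independent_regime:
        # one orthonormal frame, split into disjoint (orthogonal) spans
        frame, _ = np.linalg.qr(rng.standard_normal((m, g * d)))
        bases = [frame[:, i * d : (i + 1) * d] for i in range(g)]
    else:
        bases = [np.linalg.qr(rng.standard_normal((m, d)))[0] for _ in range(g)]

    blocks = [
        basis @ rng.standard_normal((d, spec.samples_per_subspace)) for basis in bases
    ]
    X = np.concatenate(blocks, axis=1)
    labels = np.repeat(np.arange(g), spec.samples_per_subspace)

    if spec.noise_sigma > 0:
        X = X + spec.noise_sigma * rng.standard_normal(X.shape)
    if spec.corruption_fraction > 0 and spec.corruption_scale > 0:
        mask = rng.random(X.shape) < spec.corruption_fraction
        X = X + mask * rng.uniform(-spec.corruption_scale, spec.corruption_scale, X.shape)
    if spec.nonneg_shift > 0:
        X = np.maximum(X + spec.nonneg_shift, 0.0)

    matrix = ExpressionMatrix(
        values=X,
        feature_ids=[f"feature_{i:04d}" for i in range(m)],
        sample_ids=[f"sample_{j:04d}" for j in range(X.shape[1])],
    )
    return matrix, labels


def write_fixture(
    spec: SubspaceSpec, matrix_path: str | Path, labels_path: str | Path
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Generate a fixture and write it in the TSV format the CLI reads."""
    from .io import write_expression_tsv, write_labels_csv

    matrix, labels = generate_subspace_data(spec)
    write_expression_tsv(matrix, matrix_path)
    write_labels_csv(matrix.sample_ids, labels, labels_path)
    return matrix, labels
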