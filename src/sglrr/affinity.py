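"""Affinity matrix from the principal directions of the representation Z*.

The symmetric lowest-rank representation is factored by skinny SVD,
Z* = U* S* V*^T over the positive singular values, and each sample gets
the principal-direction row m_i of M = U* (S*)^{1/2}. The affinity is the
squared cosine between rows,

    H_ij = ( m_i^T m_j / (||m_i|| ||m_j||) )^2,

which is symmetric, scale-free in Z, in [0, 1], and insensitive to the
sign ambiguity of singular vectors. Samples with a zero principal row
(outside the span of Z*) keep unit self-affinity and zero edges so the
downstream graph stays valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AffinityMatrix", "build_affinity"]

_RANK_RTOL = 1e-10
_SYM_TOL = 1e-6


@dataclass
class AffinityMatrix:
    """Squared-cosine affinity H (n x n) and the skinny-SVD rank used."""

    H: np.ndarray
    rank_used: int

    @property
    def n_samples(self) -> int:
        return self.H.shape[0]


def build_affinity(Z: np.ndarray) -> AffinityMatrix:
    """Squared-cosine affinity of the principal-direction rows of Z.

    Z must be symmetric to within 1e-6 (it is symmetrized internally);
    a larger asymmetry raises ``ValueError``.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise ValueError("Z must be square")
    asym = np.abs(Z - Z.T).max(initial=0.0)
    if asym > _SYM_TOL:
        raise ValueError(f"Z asymmetric beyond tolerance ({asym:.3g} > {_SYM_TOL})")
    Zs = 0.5 * (Z + Z.T)
    n = Zs.shape[0]

    U, s, _ = np.linalg.svd(Zs, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > _RANK_RTOL * s[0]
    else:
        keep = np.zeros_like(s, dtype=bool)
    r = int(keep.sum())
    if r == 0:
        return AffinityMatrix(H=np.eye(n), rank_used=0)

    M = U[:, keep] * np.sqrt(s[keep])
    norms = np.linalg.norm(M, axis=1)
    nonzero = norms > 0
    Mn = np.zeros_like(M)
    Mn[nonzero] = M[nonzero] / norms[nonzero, None]
    H = (Mn @ Mn.T) ** 2
    np.clip(H, 0.0, 1.0, out=H)
    H = 0.5 * (H + H.T)
    np.fill_diagonal(H, 1.0)  # zero rows get unit self-affinity too
    return AffinityMatrix(H=H, rank_used=r)
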