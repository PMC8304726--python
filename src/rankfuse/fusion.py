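"""Similarity network fusion and spectral partitioning of subjects.

The per-omics similarity matrices are merged by iterative cross-network
diffusion: each network is row-normalized into a full transition kernel
(half the mass on the diagonal), a sparse K-nearest-neighbor kernel carries
the diffusion locally, and every network is repeatedly updated towards the
average of the others, P_v <- S_v @ mean(P_w, w != v) @ S_v^T.  After a fixed
number of rounds the networks are averaged and symmetrized.  Subjects are
then partitioned with normalized spectral clustering on the fused network;
when the cluster count is not fixed by the user it is picked by the eigengap
of the symmetric normalized Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .containers import ClusterAssignment, SimilarityMatrix

__all__ = ["FusionConfig", "snf_fuse", "eigengap_k", "spectral_clusters"]


@dataclass
class FusionConfig:
    """Diffusion hyperparameters.

    ``k_neighbors`` is capped at n/3 at run time; ``self_affinity`` is the
    identity stabilizer added after each diffusion round.
    """

    k_neighbors: int = 20
    iterations: int = 20
    self_affinity: float = 1.0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Row normalization with half the mass on the diagonal."""
    off = W.sum(axis=1) - np.diag(W)
    off[off == 0] = 1.0
    P = W / (2.0 * off[:, None])
    np.fill_diagonal(P, 0.5)
    return 0.5 * (P + P.T)

def _local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic kernel keeping only each row's K largest neighbors."""
    n = W.shape[0]
    S = np.array(W, copy=True)
    np.fill_diagonal(S, 0.0)
    for i in range(n):
        drop = np.argsort(S[i])[: n - K]
        S[i, drop] = 0.0
    rs = S.sum(axis=1)
    rs[rs == 0] = 1.0
    return S / rs[:, None]


def snf_fuse(networks: Sequence[SimilarityMatrix], cfg: FusionConfig | None = None) -> SimilarityMatrix:
    """Fuse >= 2 similarity networks over identical subjects into one."""
    cfg = cfg or FusionConfig()
    if len(networks) < 2:
        raise ValueError("fusion requires at least 2 networks")
    subjects = networks[0].subject_ids
    for net in networks[1:]:
        if net.subject_ids != subjects:
            raise ValueError("all networks must share subjects and order")
    n = len(subjects)
    K = min(cfg.k_neighbors, max(1, n // 3))
    if K >= n:
        raise ValueError(f"k_neighbors={K} must be smaller than n={n}")

    P = [_full_kernel(net.values) for net in networks]
    S = [_local_kernel(net.values, K) for net in networks]
    L = len(P)
    eye = cfg.self_affinity * np.eye(n)
    for _ in range(cfg.iterations):
        nxt = []
        for v in range(L):
            rest = sum(P[w] for w in range(L) if w != v) / (L - 1)
            nxt.append(S[v] @ rest @ S[v].T + eye)
        P = [_full_kernel(m) for m in nxt]
    fused = sum(P) / L
    fused = _full_kernel(fused)
    fused = 0.5 * (fused + fused.T)
    return SimilarityMatrix(
        subject_ids=list(subjects), values=fused, layer_name="fused", side="fused"
    )


def _normalized_laplacian(W: np.ndarray) -> np.ndarray:
    d = W.sum(axis=1)
    d[d == 0] = 1.0
    inv_sqrt = 1.0 / np.sqrt(d)
    return np.eye(W.shape[0]) - inv_sqrt[:, None] * W * inv_sqrt[None, :]


def eigengap_k(W: SimilarityMatrix, k_min: int = 2, k_max: int | None = None) -> tuple[int, bool]:
    """Cluster count by the largest eigengap of the normalized Laplacian.

    Returns ``(k, degenerate)``; when every gap in the scanned range ties
    (e.g. one uniform block) ``k_min`` is returned with the degenerate flag
    set.
    """
    n = W.n_subjects
    k_max = k_max if k_max is not None else min(10, n - 1)
    if not 2 <= k_min <= k_max < n:
        raise ValueError(f"need 2 <= k_min <= k_max < n, got ({k_min}, {k_max}, {n})")
    vals = np.asarray(W.values)
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise ValueError("affinity matrix must be symmetric")
    lam = eigh(_normalized_laplacian(vals), eigvals_only=True)
    gaps = lam[k_min : k_max + 1] - lam[k_min - 1 : k_max]  # gap after the k-th eigenvalue
    degenerate = bool(np.ptp(gaps) < 1e-12)
    if degenerate:
        return k_min, True
    return int(k_min + np.argmax(gaps)), False


def spectral_clusters(W: SimilarityMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Normalized spectral clustering with a seeded k-means step.

    Bottom-k eigenvectors of the symmetric normalized Laplacian are
    row-normalized and clustered with k-means (50 restarts, fixed seed), so
    the partition is deterministic for a fixed seed and equivariant under
    subject permutation up to label names.
    """
    n = W.n_subjects
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    vals = np.asarray(W.values)
    L = _normalized_laplacian(vals)
    lam, vec = eigh(L)
    n_components = int(np.sum(lam < 1e-10))
    if n_components > k:
        raise ValueError(
            f"graph has {n_components} connected components but k={k}; increase k"
        )
    U = vec[:, :k]
    norms = np.linalg.norm(U, axis=1)
    norms[norms == 0] = 1.0
    U = U / norms[:, None]
    km = KMeans(n_clusters=k, n_init=50, random_state=seed % (2**31)).fit(U)
    # canonicalize label names by first appearance so relabeling is stable
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(km.labels_):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return ClusterAssignment(
        subject_ids=list(W.subject_ids),
        labels=labels,
        k=k,
        method="user-fixed",
        metadata={"seed": seed, "inertia": float(km.inertia_)},
    )
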