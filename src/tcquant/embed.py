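"""Probabilistic regularized embedding (PRE).

Cluster centers are laid out in 2-D from the cluster-cluster relationship
H^T H (similar clusters close together), and each cell is placed by the
membership-weighted attraction to the centers with a pairwise repulsion term
that keeps cells spread out:

    min_X  sum_i sum_j p_ij ||x_i - a_j||^2  -  (lambda1/n) sum_{i,l} ||x_i - x_l||^2

The objective is quadratic, so the embedding is the exact solution of the
stationarity system rather than an iterative layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PREmbedding", "cluster_centers", "embed_cells", "pre_embedding"]


@dataclass
class PREmbedding:
    centers: np.ndarray  # k x 2
    coords: np.ndarray  # n x 2
    lambda1: float
    converged: bool = True


def cluster_centers(H: np.ndarray) -> np.ndarray:
    """2-D cluster centers from the cluster-cluster relationship H^T H.

    H^T H is normalized to a cosine-style similarity S (unit diagonal), the
    induced metric d_ij = sqrt(s_ii + s_jj - 2 s_ij) is embedded by classical
    multidimensional scaling, and the configuration is rigidly oriented
    (center 1 at the origin, center 2 on the positive x-axis, center 3 with
    positive y) so the layout is deterministic.
    """
    H = np.asarray(H, dtype=float)
    k = H.shape[1]
    if k == 1:
        return np.zeros((1, 2))
    G = H.T @ H
    d = np.sqrt(np.maximum(np.diag(G), 1e-300))
    S = G / np.outer(d, d)
    D2 = np.maximum(np.add.outer(np.diag(S), np.diag(S)) - 2.0 * S, 0.0)
    centers = _classical_mds(D2, dim=2)
    return _orient(centers)


def _classical_mds(D2: np.ndarray, dim: int = 2) -> np.ndarray:
    """Torgerson scaling: double-center -D2/2 and take top eigenpairs."""
    k = D2.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1][:dim]
    lam = np.maximum(evals[order], 0.0)
    X = evecs[:, order] * np.sqrt(lam)[None, :]
    if X.shape[1] < dim:  # degenerate: pad with zeros
        X = np.hstack([X, np.zeros((k, dim - X.shape[1]))])
    return X


def _orient(X: np.ndarray) -> np.ndarray:
    """Translate/rotate/reflect to a canonical pose."""
    X = X - X[0]
    if X.shape[0] >= 2 and np.linalg.norm(X[1]) > 1e-12:
        c, s = X[1] / np.linalg.norm(X[1])
        R = np.array([[c, s], [-s, c]])
        X = X @ R.T
    if X.shape[0] >= 3 and X[2, 1] < 0:
        X = X * np.array([1.0, -1.0])
    return X


def embed_cells(P: np.ndarray, centers: np.ndarray, lambda1: float = 0.3) -> np.ndarray:
    """Place cells by solving the PRE stationarity system exactly.

    With row-stochastic P, the first-order conditions are
    ``(1 - 2 lambda1) x_i + (2 lambda1 / n) sum_l x_l = (P a)_i`` per
    coordinate.  Boundedness of the objective requires ``lambda1 < 1/2``
    (the repulsion term acts on the zero-sum subspace with coefficient
    ``1 - 2 lambda1``); at ``lambda1 = 0`` every cell sits at its
    membership-weighted centroid of the centers.
    """
    P = np.asarray(P, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if lambda1 < 0:
        raise ValueError("lambda1 must be non-negative")
    if lambda1 >= 0.5:
        raise ValueError(
            "lambda1 >= 1/2 makes the embedding objective unbounded below"
        )
    n = P.shape[0]
    B = P @ centers  # n x 2 attraction targets
    if lambda1 == 0:
        return B
    s = B.sum(axis=0)  # column sums are preserved: sum_i x_i = sum_i (Pa)_i
    return (B - (2.0 * lambda1 / n) * s[None, :]) / (1.0 - 2.0 * lambda1)


def pre_embedding(H: np.ndarray, P: np.ndarray, lambda1: float = 0.3) -> PREmbedding:
    centers = cluster_centers(H)
    coords = embed_cells(P, centers, lambda1=lambda1)
    return PREmbedding(centers=centers, coords=coords, lambda1=lambda1)
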