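"""Consensus (cell-cell similarity) matrix and spectral cluster-count estimate.

An ensemble of base k-means clusterings is run on principal-component
projections of the expression matrix.  Each base partition yields a binary
co-membership matrix (1 where two cells share a cluster); the consensus
matrix M is the elementwise mean over the ensemble, i.e. the fraction of
runs in which each pair of cells co-clusters.  The number of clusters is
then read off the spectrum of the symmetric normalized graph Laplacian of M
as the position of the largest gap between consecutive eigenvalues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusMatrix",
    "ClusterCountEstimate",
    "ConsensusConfig",
    "build_consensus",
    "consensus_from_labels",
    "estimate_k",
]


@dataclass
class ConsensusMatrix:
    """Symmetric n x n co-clustering frequency matrix with unit diagonal."""

    values: np.ndarray
    cell_names: list[str]
    n_runs: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("consensus matrix must be square")
        if v.shape[0] != len(self.cell_names):
            raise ValueError("cell_names length does not match matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("consensus matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterCountEstimate:
    k: int
    laplacian_eigenvalues: np.ndarray
    gap_index: int
    k_max: int


@dataclass
class ConsensusConfig:
    """Ensemble definition: k-means over several PCA depths, base cluster
    numbers and seeded restarts.  The grid is clipped to the data size."""

    n_pcs: Sequence[int] = (5, 10, 15, 20, 30)
    k_range: Sequence[int] = tuple(range(2, 13))
    n_restarts: int = 3
    subsample: float = 0.8  # cell fraction per run (resampling-based consensus)
    log1p: bool = True
    standardize: bool = True


def consensus_from_labels(
    labels_list: Iterable[np.ndarray], cell_names: Sequence[str]
) -> ConsensusMatrix:
    """Average binary co-membership matrices of the given hard partitions.

    A label of -1 marks a cell left out of that run (subsampled ensembles);
    each pair's co-clustering frequency is then normalized by the number of
    runs in which both cells were present.
    """
    labels_list = [np.asarray(lab) for lab in labels_list]
    if len(labels_list) == 0:
        raise ValueError("need at least one base partition")
    n = len(labels_list[0])
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for lab in labels_list:
        if lab.shape != (n,):
            raise ValueError("all partitions must label the same cells")
        inc = lab >= 0
        both = np.outer(inc, inc)
        den += both
        num += both & (lab[:, None] == lab[None, :])
    with np.errstate(invalid="ignore"):
        M = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0
    return ConsensusMatrix(values=M, cell_names=list(cell_names), n_runs=len(labels_list))


def build_consensus(
    X: ExpressionMatrix,
    run_spec: ConsensusConfig | None = None,
    seed: int | None = 0,
) -> ConsensusMatrix:
    """Cluster-ensemble consensus matrix for the cells of ``X``.

    Base clusterings are k-means on the top-d principal components for every
    (d, k, restart) combination of ``run_spec``; failures are skipped with a
    warning.  Averaging the binary co-membership matrices gives M.
    """
    if X.n_cells < 2:
        raise ValueError("need at least 2 cells to build a consensus")
    cfg = run_spec or ConsensusConfig()
    rng = np.random.default_rng(seed)

    Z = X.values.T.astype(float)  # cells x genes
    if cfg.log1p:
        Z = np.log1p(Z)
    if cfg.standardize:
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=0)) / sd

    max_d = min(X.n_cells - 1, Z.shape[1])
    depths = sorted({min(d, max_d) for d in cfg.n_pcs if d >= 1})
    if not depths:
        raise ValueError("no usable PCA depth in run_spec")
    pca = PCA(n_components=max(depths), svd_solver="auto", random_state=int(rng.integers(2**31 - 1)))
    comps = pca.fit_transform(Z)

    n = X.n_cells
    n_sub = max(2, int(round(cfg.subsample * n)))
    labels_list = []
    for d in depths:
        Y = comps[:, :d]
        for k in cfg.k_range:
            if k < 2 or k >= n_sub:
                continue
            for _ in range(cfg.n_restarts):
                rs = int(rng.integers(0, 2**31 - 1))
                sub = (
                    np.sort(rng.choice(n, size=n_sub, replace=False))
                    if n_sub < n
                    else np.arange(n)
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        km = KMeans(n_clusters=k, n_init=1, random_state=rs).fit(Y[sub])
                    lab = np.full(n, -1)
                    lab[sub] = km.labels_
                    labels_list.append(lab)
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning("base clustering (d=%d, k=%d) failed: %s", d, k, exc)
    if len(labels_list) == 0:
        raise RuntimeError("every base clustering failed")
    if len(labels_list) < 2:
        logger.warning("consensus built from a single base clustering")
    return consensus_from_labels(labels_list, X.cell_names)


def estimate_k(M: ConsensusMatrix, k_max: int = 10) -> ClusterCountEstimate:
    """Estimate the cluster count from the normalized-Laplacian eigengap.

    L = I - D^{-1/2} M D^{-1/2} with D the diagonal of row sums of M.  With
    eigenvalues sorted ascending, k is the j in [2, k_max] maximizing
    lambda_{j+1} - lambda_j; ties go to the smaller j.
    """
    n = M.n_cells
    if n <= k_max:
        raise ValueError(f"need more cells ({n}) than k_max ({k_max})")
    d = M.values.sum(axis=1)
    zero = np.flatnonzero(d <= 0)
    if zero.size:
        raise ValueError(
            f"isolated cell(s) with zero similarity row sum: "
            f"{[M.cell_names[i] for i in zero[:5]]}"
        )
    dis = 1.0 / np.sqrt(d)
    L = np.eye(n) - dis[:, None] * M.values * dis[None, :]
    evals = np.linalg.eigvalsh((L + L.T) / 2.0)
    evals = np.clip(evals, 0.0, 2.0)
    gaps = evals[2 : k_max + 1] - evals[1:k_max]  # gap after position j for j=2..k_max
    j = int(np.argmax(gaps)) + 2
    return ClusterCountEstimate(
        k=j, laplacian_eigenvalues=evals, gap_index=j, k_max=k_max
    )
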