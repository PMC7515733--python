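"""Soft clustering of the consensus matrix and the Cell Plasticity Index.

The consensus matrix M is factorized by symmetric non-negative matrix
factorization, min_{H >= 0} ||M - H H^T||_F^2 with H of shape n x k.  Rows
of H are unnormalized cluster memberships; row-normalizing gives a
probability-like matrix P.  The Cell Plasticity Index (CPI) of a cell is the
entropy of its membership row scaled by 1/log k, so CPI = 0 for a committed
cell and CPI = 1 for a maximally mixed one.  Cells above a CPI threshold are
flagged as transition cells (TC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .consensus import ConsensusMatrix

__all__ = ["SoftClustering", "symnmf", "to_probabilities", "cpi", "identify_tc"]


@dataclass
class SoftClustering:
    """Result bundle of the symmetric-NMF soft clustering."""

    H: np.ndarray
    k: int
    objective_value: float
    objective_history: np.ndarray
    cell_names: list[str] = field(default_factory=list)
    P: np.ndarray | None = None
    hard_labels: np.ndarray | None = None
    cpi: np.ndarray | None = None
    tc_mask: np.ndarray | None = None

    def finalize(self, tc_threshold: float | str = "auto") -> "SoftClustering":
        """Fill P, hard labels, CPI and the TC mask from H."""
        self.P = to_probabilities(self.H, cell_names=self.cell_names)
        self.hard_labels = np.argmax(self.P, axis=1)
        self.cpi = cpi(self.P)
        self.tc_mask = identify_tc(self.cpi, threshold=tc_threshold)
        return self


def _objective(M: np.ndarray, H: np.ndarray) -> float:
    R = M - H @ H.T
    return float(np.sum(R * R))


def _standardize_columns(H: np.ndarray) -> np.ndarray:
    """Deterministic column order: sort clusters by the row index of their
    highest-membership cell (symNMF is invariant to column permutation)."""
    anchors = np.argmax(H, axis=0)
    order = np.lexsort((-H.max(axis=0), anchors))
    return H[:, order]


def symnmf(
    M: ConsensusMatrix | np.ndarray,
    k: int,
    seed: int | None = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SoftClustering:
    """Factorize M ~ H H^T with H >= 0 by projected gradient descent.

    Each restart starts from the absolute values of the top-k eigenvectors
    of M (scaled by sqrt of eigenvalues), perturbed multiplicatively, and
    descends with Armijo backtracking, so the objective is non-increasing
    along every run; the best restart by final objective is returned.
    """
    if isinstance(M, ConsensusMatrix):
        cell_names = M.cell_names
        A = M.values
    else:
        A = np.asarray(M, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("M must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("M must be symmetric")
        if A.min() < 0:
            raise ValueError("M must be non-negative")
        cell_names = [str(i) for i in range(A.shape[0])]
    if k < 2:
        raise ValueError("k must be >= 2")
    n = A.shape[0]
    rng = np.random.default_rng(seed)

    evals, evecs = np.linalg.eigh(A)
    top = np.argsort(evals)[::-1][:k]
    base = np.abs(evecs[:, top]) * np.sqrt(np.maximum(evals[top], 1e-12))[None, :]

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for r in range(n_restarts):
        H0 = base if r == 0 else base * rng.uniform(0.8, 1.2, size=base.shape)
        H0 = np.maximum(H0, 1e-10)
        H, hist = _pgd(A, H0, tol=tol, max_iter=max_iter)
        if best is None or hist[-1] < best[0]:
            best = (hist[-1], H, hist)
    assert best is not None
    obj, H, hist = best
    H = _standardize_columns(H)
    return SoftClustering(
        H=H, k=k, objective_value=obj, objective_history=np.asarray(hist), cell_names=cell_names
    )


def _pgd(A: np.ndarray, H: np.ndarray, tol: float, max_iter: int):
    """Projected gradient with backtracking line search; monotone by design."""
    f = _objective(A, H)
    hist = [f]
    step = 1.0 / (4.0 * max(np.linalg.norm(A, 2), 1e-12))
    for _ in range(max_iter):
        G = 4.0 * (H @ (H.T @ H) - A @ H)
        for _ls in range(40):
            Hn = np.maximum(H - step * G, 0.0)
            fn = _objective(A, Hn)
            if fn <= f - 1e-4 * np.sum(G * (H - Hn)) or fn <= f:
                break
            step *= 0.5
        if fn > f:  # no admissible step: converged
            hist.append(f)
            break
        rel = (f - fn) / max(f, 1e-300)
        H, f = Hn, fn
        hist.append(f)
        step *= 1.2
        if rel < tol:
            break
    return H, hist


def to_probabilities(H: np.ndarray, cell_names: list[str] | None = None) -> np.ndarray:
    """Row-normalize a non-negative membership matrix to row sums of one."""
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("H must be non-negative")
    s = H.sum(axis=1)
    zero = np.flatnonzero(s <= 0)
    if zero.size:
        names = (
            [cell_names[i] for i in zero[:5]] if cell_names else list(zero[:5])
        )
        raise ValueError(f"cell(s) with all-zero membership row: {names}")
    return H / s[:, None]


def cpi(P: np.ndarray) -> np.ndarray:
    """Cell Plasticity Index: normalized entropy of each membership row.

    CPI_i = -(1/log k) * sum_j P_ij log P_ij, with 0 log 0 taken as 0.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("P must be n x k with k >= 2")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of P must sum to 1")
    k = P.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return np.clip(-terms.sum(axis=1) / np.log(k), 0.0, 1.0)


def identify_tc(cpi_values: np.ndarray, threshold: float | str = "auto") -> np.ndarray:
    """Flag transition cells as those with CPI strictly above a threshold.

    ``threshold="auto"`` picks the cut by Otsu's method on the CPI
    distribution, which suits the typical bimodal committed-vs-plastic shape.
    """
    c = np.asarray(cpi_values, dtype=float)
    if threshold == "auto":
        if np.unique(c).size < 2:
            return np.zeros(c.shape, dtype=bool)
        thr = float(threshold_otsu(c))
    else:
        thr = float(threshold)
        if not 0.0 <= thr <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
    return c > thr
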