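"""Cluster marker genes and transition genes.

Markers come from a regularized NMF of the expression submatrix restricted
to the cells of one trajectory:

    min_{Hbar >= 0, W >= 0}  ||D_s - Hbar W||_F^2  -  lambda2 Tr(Hbar^T H_s)

where H_s is the soft-clustering factor restricted to the same cells.  The
trace reward ties Hbar to the consensus-derived memberships, so each row of
the gene-cluster matrix W scores how specifically every gene marks that
cluster.  A gene is a marker of the cluster holding the largest entry of its
column-normalized W profile provided the top-two gap exceeds ``min_gap``.

Transition genes between two neighboring clusters are the candidate genes
whose expression varies monotonically along the aligned cell ordering:
|Spearman rho| of expression vs. rank position above ``rho_threshold``, the
sign giving the direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneClusterResult",
    "TransitionGeneSet",
    "fit_gene_cluster",
    "marker_genes",
    "transition_genes",
]


@dataclass
class GeneClusterResult:
    W: np.ndarray  # k x m, non-negative
    H_bar: np.ndarray  # n_s x k, non-negative
    lambda2: float
    objective_history: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    markers: dict[int, list[tuple[str, float]]] | None = None
    min_gap: float | None = None


@dataclass
class TransitionGeneSet:
    pairs: dict[tuple[int, int], list[tuple[str, float, str]]] = field(
        default_factory=dict
    )


def _obj(
    D: np.ndarray, Hb: np.ndarray, W: np.ndarray, lam2: float, Hs: np.ndarray,
    ridge: float = 0.0,
) -> float:
    R = D - Hb @ W
    return float(np.sum(R * R) - lam2 * np.sum(Hb * Hs) + ridge * np.sum(Hb * Hb))


def fit_gene_cluster(
    D_s: np.ndarray,
    H_s: np.ndarray,
    lambda2: float = 10.0,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    gene_names: list[str] | None = None,
    update_h: bool = True,
    ridge: float = 1e-3,
) -> GeneClusterResult:
    """Alternating multiplicative updates for the regularized factorization.

    ``D_s`` is genes x cells (transposed internally to cells x genes);
    ``H_s`` is cells x k.  Both half-steps are standard multiplicative rules
    — the trace reward enters the Hbar numerator since its gradient
    contribution is the non-negative constant ``lambda2 H_s`` — so the
    objective is non-increasing per alternating step.  ``update_h=False``
    freezes Hbar at H_s and fits W only (plain per-gene non-negative
    regression).

    The raw objective is unbounded below along the joint rescaling
    Hbar -> c Hbar, W -> W/c (the trace reward grows linearly in c while the
    residual is invariant), so a small quadratic penalty ``ridge ||Hbar||^2``
    anchors the scale; it is included in the reported objective.
    """
    D = np.asarray(D_s, dtype=float).T  # cells x genes
    Hs = np.asarray(H_s, dtype=float)
    if D.shape[0] != Hs.shape[0]:
        raise ValueError(
            f"cells of D_s ({D.shape[0]}) and H_s ({Hs.shape[0]}) do not align"
        )
    if lambda2 < 0:
        raise ValueError("lambda2 must be non-negative")
    n, m = D.shape
    k = Hs.shape[1]
    eps = 1e-12
    rng = np.random.default_rng(seed)

    Hb = np.maximum(Hs.copy(), eps)
    scale = (np.abs(D).mean() + eps) / (Hb.mean() * k + eps)
    W = rng.uniform(0.5, 1.5, size=(k, m)) * scale
    hist = [_obj(D, Hb, W, lambda2, Hs, ridge)]
    for _ in range(max_iter):
        # W step: W <- W * (Hb^T D) / (Hb^T Hb W)
        num = Hb.T @ D
        den = (Hb.T @ Hb) @ W + eps
        W = W * (num / den)
        if update_h:
            # Hbar step: Hb <- Hb * (2 D W^T + lambda2 Hs) / (2 Hb (W W^T + ridge I))
            num_h = 2.0 * (D @ W.T) + lambda2 * Hs
            den_h = 2.0 * Hb @ (W @ W.T + ridge * np.eye(k)) + eps
            Hb = Hb * (num_h / den_h)
        f = _obj(D, Hb, W, lambda2, Hs, ridge)
        hist.append(f)
        denom = max(abs(hist[-2]), 1e-300)
        if abs(hist[-2] - f) / denom < tol:
            break
    return GeneClusterResult(
        W=W,
        H_bar=Hb,
        lambda2=lambda2,
        objective_history=np.asarray(hist),
        gene_names=gene_names or [str(i) for i in range(m)],
    )


def _normalize_columns(W: np.ndarray) -> np.ndarray:
    s = W.sum(axis=0)
    s[s == 0] = 1.0
    return W / s[None, :]


def marker_genes(
    result: GeneClusterResult | np.ndarray,
    min_gap: float = 0.03,
    n_top: int | None = None,
    gene_names: list[str] | None = None,
) -> dict[int, list[tuple[str, float]]]:
    """Per-cluster ordered marker lists from the gene-cluster matrix.

    Each gene's W column is normalized to sum one; the gene marks the
    cluster holding its largest entry when that entry beats the runner-up by
    more than ``min_gap``.  Within a cluster, markers are sorted by their
    normalized entry, descending; ``n_top`` truncates each list.  Clusters
    may legitimately have no markers (intermediate states express no unique
    program).
    """
    if isinstance(result, GeneClusterResult):
        W = result.W
        names = result.gene_names
    else:
        W = np.asarray(result, dtype=float)
        names = gene_names or [str(i) for i in range(W.shape[1])]
    k, m = W.shape
    Wn = _normalize_columns(W)
    out: dict[int, list[tuple[str, float]]] = {j: [] for j in range(k)}
    for g in range(m):
        col = Wn[:, g]
        order = np.argsort(-col, kind="stable")
        top, second = col[order[0]], col[order[1]] if k > 1 else 0.0
        if top - second > min_gap:
            out[int(order[0])].append((names[g], float(top)))
    for j in out:
        out[j].sort(key=lambda t: (-t[1], t[0]))
        if n_top is not None:
            out[j] = out[j][:n_top]
    if isinstance(result, GeneClusterResult):
        result.markers = out
        result.min_gap = min_gap
    return out


def transition_genes(
    D: np.ndarray,
    cell_order: list[int],
    candidate_genes: list[int] | list[str],
    gene_names: list[str] | None = None,
    rho_threshold: float = 0.64,
) -> list[tuple[str, float, str]]:
    """Genes varying monotonically along an aligned cell ordering.

    ``D`` is genes x cells on the full cell indexing; ``cell_order`` selects
    and orders the cells between the two clusters of interest.  For each
    candidate gene the Spearman correlation between its expression along the
    ordering and the rank positions is computed (average ranks on ties);
    genes with ``|rho| >= rho_threshold`` are reported as ("up" for positive
    rho, "down" for negative).  Constant genes are skipped with a warning.
    """
    D = np.asarray(D, dtype=float)
    if len(cell_order) < 3:
        raise ValueError("need at least 3 ordered cells")
    names = gene_names or [str(i) for i in range(D.shape[0])]
    name_to_idx = {nm: i for i, nm in enumerate(names)}
    idx = [
        name_to_idx[g] if isinstance(g, str) else int(g) for g in candidate_genes
    ]
    pos = np.arange(len(cell_order))
    out = []
    for gi in idx:
        expr = D[gi, cell_order]
        if np.all(expr == expr[0]):
            logger.warning("gene %s constant along ordering; skipped", names[gi])
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = sstats.spearmanr(expr, pos).statistic
        if not np.isfinite(rho):
            continue
        if abs(rho) >= rho_threshold:
            out.append((names[gi], float(rho), "up" if rho > 0 else "down"))
    out.sort(key=lambda t: (-abs(t[1]), t[0]))
    return out
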