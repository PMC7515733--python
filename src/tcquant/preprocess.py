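"""Expression-matrix input, quality filters and bimodality-based gene selection.

The pipeline input is a genes x cells matrix of non-negative expression
values (counts, TPM or qPCR-style continuous values).  Before clustering we
discard near-empty cells and uninformative genes, then rank the surviving
genes by how bimodal their expression distribution looks under a
three-component Gaussian mixture: genes switching between a low and a high
regime across the population are the ones that carry cell-state information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from sklearn.mixture import GaussianMixture

__all__ = [
    "ExpressionMatrix",
    "FeatureSelectionReport",
    "load_expression",
    "filter_cells",
    "filter_genes",
    "select_informative_genes",
]


class EmptyResultError(ValueError):
    """Raised when a filter removes every cell or every gene."""


@dataclass
class ExpressionMatrix:
    """Named genes x cells matrix of non-negative expression values.

    Attributes
    ----------
    values
        Dense array of shape ``(n_genes, n_cells)``; finite and >= 0.
    gene_names, cell_names
        Unique row / column labels.
    metadata
        Optional per-cell annotation table indexed by cell name.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_names = [str(c) for c in self.cell_names]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_names), len(self.cell_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_names)} gene and {len(self.cell_names)} cell names"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names")
        if len(set(self.cell_names)) != len(self.cell_names):
            raise ValueError("duplicate cell names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.metadata is not None and not self.metadata.index.equals(
            pd.Index(self.cell_names)
        ):
            self.metadata = self.metadata.reindex(self.cell_names)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(
        self, genes: np.ndarray | list | None = None, cells: np.ndarray | list | None = None
    ) -> "ExpressionMatrix":
        """Return a copy restricted to the given gene/cell index arrays."""
        gi = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        ci = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        meta = None
        if self.metadata is not None:
            meta = self.metadata.iloc[ci].copy()
        return ExpressionMatrix(
            values=self.values[np.ix_(gi, ci)],
            gene_names=[self.gene_names[i] for i in gi],
            cell_names=[self.cell_names[i] for i in ci],
            metadata=meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_names)

    def save(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)


@dataclass
class FeatureSelectionReport:
    """Outcome of mixture-model gene ranking.

    ``gmm_stats`` holds one row per surviving gene with the fitted component
    weights ``w1..w3`` and means ``mu1..mu3`` (sorted by descending weight)
    plus the two ranks that were aggregated.
    """

    removed_genes: list[str]
    gmm_stats: pd.DataFrame
    selected_genes: list[str]
    removed_cells: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        self.gmm_stats.to_csv(path, sep="\t")


def load_expression(
    path: str | Path,
    format: Literal["csv", "tsv", "mtx"] = "csv",
    orientation: Literal["genes_by_cells", "cells_by_genes"] = "genes_by_cells",
    gene_file: str | Path | None = None,
    cell_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or MatrixMarket triplets.

    For ``mtx`` input, ``gene_file`` and ``cell_file`` are sidecar text files
    with one name per line (defaulting to ``genes.tsv`` / ``barcodes.tsv``
    next to the matrix).  Whatever the on-disk orientation, the returned
    matrix is genes x cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        row_names = [str(i) for i in df.index]
        col_names = [str(c) for c in df.columns]
    elif format == "mtx":
        gene_file = Path(gene_file) if gene_file else path.parent / "genes.tsv"
        cell_file = Path(cell_file) if cell_file else path.parent / "barcodes.tsv"
        for f in (gene_file, cell_file):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar name file: {f}")
        mat = spio.mmread(path)
        values = np.asarray(
            mat.todense() if sparse.issparse(mat) else mat, dtype=float
        )
        row_names = [ln.split("\t")[0] for ln in _read_lines(gene_file)]
        col_names = [ln.split("\t")[0] for ln in _read_lines(cell_file)]
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "cells_by_genes":
        values = values.T
        row_names, col_names = col_names, row_names
    if values.shape != (len(row_names), len(col_names)):
        raise ValueError(
            f"matrix of shape {values.shape} does not match {len(row_names)} "
            f"gene names and {len(col_names)} cell names"
        )
    return ExpressionMatrix(values=values, gene_names=row_names, cell_names=col_names)


def _read_lines(path: Path) -> list[str]:
    return [ln for ln in path.read_text().splitlines() if ln.strip()]


def filter_cells(X: ExpressionMatrix, min_gene_fraction: float = 0.05) -> ExpressionMatrix:
    """Drop cells expressing fewer than ``min_gene_fraction`` of all genes.

    A gene counts as expressed in a cell when its value is strictly positive.
    """
    if not 0.0 <= min_gene_fraction <= 1.0:
        raise ValueError("min_gene_fraction must lie in [0, 1]")
    n_expressed = np.count_nonzero(X.values > 0, axis=0)
    keep = n_expressed >= min_gene_fraction * X.n_genes
    if not keep.any():
        raise EmptyResultError("cell filter removed every cell")
    if keep.all():
        return X
    return X.subset(cells=np.flatnonzero(keep))


def filter_genes(
    X: ExpressionMatrix,
    min_cell_fraction: float = 0.10,
    min_variance: float = 0.005,
) -> ExpressionMatrix:
    """Drop rare genes (expressed in < ``min_cell_fraction`` of cells) and
    near-constant genes (population variance < ``min_variance``)."""
    if min_cell_fraction < 0 or min_variance < 0:
        raise ValueError("thresholds must be non-negative")
    frac = np.count_nonzero(X.values > 0, axis=1) / X.n_cells
    var = X.values.var(axis=1)  # population variance (ddof=0)
    keep = (frac >= min_cell_fraction) & (var >= min_variance)
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene")
    if keep.all():
        return X
    return X.subset(genes=np.flatnonzero(keep))


def select_informative_genes(
    X: ExpressionMatrix,
    n_top: int = 3000,
    zero_weight_cutoff: float = 0.90,
    seed: int | None = 0,
    log_transform: bool = False,
    n_restarts: int = 5,
) -> FeatureSelectionReport:
    """Rank genes by bimodality under a 3-component Gaussian mixture.

    Per gene, a univariate mixture of three Gaussians is fitted to the
    expression values across cells (optionally after ``log1p``).  Genes whose
    near-zero-mean component carries more than ``zero_weight_cutoff`` of the
    weight are discarded as dropout-dominated.  The remaining genes get two
    ranks — descending separation of the two heaviest components' means, and
    ascending difference of their weights (balanced modes rank first) — and
    the rank sum picks the ``n_top`` most informative genes.

    Components are ordered by weight; the "zero" component is the one whose
    fitted mean is smallest in absolute value, accepted only within 10% of
    the gene's value range (fitted means are never exactly zero).  Rank ties
    break lexicographically on gene name so the selection is deterministic.
    """
    rng = np.random.default_rng(seed)
    rows = []
    removed = []
    for gi, gene in enumerate(X.gene_names):
        x = X.values[gi]
        if log_transform:
            x = np.log1p(x)
        stats = _fit_gene_gmm(x, rng, n_restarts)
        if stats is None:
            removed.append(gene)
            continue
        weights, means = stats
        rng_span = max(x.max() - x.min(), 1e-12)
        zero_idx = int(np.argmin(np.abs(means)))
        is_zero_comp = abs(means[zero_idx]) < 0.1 * rng_span
        if is_zero_comp and weights[zero_idx] > zero_weight_cutoff:
            removed.append(gene)
            continue
        rows.append(
            {
                "gene": gene,
                "w1": weights[0],
                "w2": weights[1],
                "w3": weights[2],
                "mu1": means[0],
                "mu2": means[1],
                "mu3": means[2],
                "mean_diff": abs(means[0] - means[1]),
                "weight_diff": abs(weights[0] - weights[1]),
            }
        )
    if not rows:
        raise EmptyResultError("no gene survived mixture-model screening")
    stats_df = pd.DataFrame(rows).set_index("gene")
    # two rank criteria aggregated by summation; smaller sum = more informative
    stats_df["rank_mean_diff"] = (
        stats_df["mean_diff"].rank(ascending=False, method="min").astype(int)
    )
    stats_df["rank_weight_diff"] = (
        stats_df["weight_diff"].rank(ascending=True, method="min").astype(int)
    )
    stats_df["rank_sum"] = stats_df["rank_mean_diff"] + stats_df["rank_weight_diff"]
    # stable sort after index sort -> ties broken by gene name
    order = stats_df.sort_index().sort_values("rank_sum", kind="mergesort")
    selected = list(order.index[:n_top])
    if len(stats_df) < n_top:
        warnings.warn(
            f"only {len(stats_df)} genes survive screening; requested {n_top}",
            stacklevel=2,
        )
    return FeatureSelectionReport(
        removed_genes=removed, gmm_stats=stats_df, selected_genes=selected
    )


def _fit_gene_gmm(
    x: np.ndarray, rng: np.random.Generator, n_restarts: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Fit a 3-component univariate GMM; returns (weights, means) sorted by
    descending weight, or None when the data are too degenerate to fit."""
    if np.unique(x).size < 3:
        return None
    xs = x.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=3,
        n_init=n_restarts,
        reg_covar=1e-6,
        init_params="k-means++",
        random_state=int(rng.integers(0, 2**31 - 1)),
        max_iter=200,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(xs)
    w = gm.weights_.ravel()
    m = gm.means_.ravel()
    order = np.argsort(-w)
    return w[order], m[order]
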