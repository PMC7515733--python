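import numpy as np
import pandas as pd
import pytest
from scipy import io as spio
from scipy import sparse

from tcquant.preprocess import (
    EmptyResultError,
    ExpressionMatrix,
    filter_cells,
    filter_genes,
    load_expression,
    select_informative_genes,
)


def _em(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    g = genes or [f"g{i}" for i in range(values.shape[0])]
    c = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values=values, gene_names=g, cell_names=c)


class TestLoad:
    def test_csv_round_trip(self, tmp_path):
        X = _em([[1, 2], [0, 3], [4, 0]])
        p = tmp_path / "m.csv"
        X.to_frame().to_csv(p)
        Y = load_expression(p, format="csv")
        np.testing.assert_array_equal(Y.values, X.values)
        assert Y.gene_names == X.gene_names and Y.cell_names == X.cell_names

    def test_cells_by_genes_transposed(self, tmp_path):
        X = _em([[1, 2], [0, 3], [4, 0]])
        p = tmp_path / "m.tsv"
        X.to_frame().T.to_csv(p, sep="\t")
        Y = load_expression(p, format="tsv", orientation="cells_by_genes")
        np.testing.assert_array_equal(Y.values, X.values)
        assert Y.gene_names == X.gene_names

    def test_mtx_sparse_dense_equivalence(self, tmp_path):
        X = _em([[1, 0, 2], [0, 3, 0]])
        spio.mmwrite(tmp_path / "m.mtx", sparse.csr_matrix(X.values))
        (tmp_path / "genes.tsv").write_text("g0\ng1\n")
        (tmp_path / "barcodes.tsv").write_text("c0\nc1\nc2\n")
        Y = load_expression(tmp_path / "m.mtx", format="mtx")
        np.testing.assert_array_equal(Y.values, X.values)

    def test_mtx_missing_sidecar(self, tmp_path):
        spio.mmwrite(tmp_path / "m.mtx", sparse.eye(2))
        with pytest.raises(FileNotFoundError):
            load_expression(tmp_path / "m.mtx", format="mtx")

    def test_name_mismatch_rejected(self, tmp_path):
        spio.mmwrite(tmp_path / "m.mtx", sparse.eye(2))
        (tmp_path / "genes.tsv").write_text("g0\n")  # 1 name for 2 rows
        (tmp_path / "barcodes.tsv").write_text("c0\nc1\n")
        with pytest.raises(ValueError):
            load_expression(tmp_path / "m.mtx", format="mtx")

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _em([[1, -2]])


class TestFilters:
    def test_all_zero_cell_removed(self):
        vals = np.ones((10, 3))
        vals[:, 1] = 0.0
        out = filter_cells(_em(vals), min_gene_fraction=0.05)
        assert out.n_cells == 2 and "c1" not in out.cell_names

    def test_zero_threshold_is_identity(self):
        X = _em(np.zeros((4, 3)))
        assert filter_cells(X, min_gene_fraction=0.0).n_cells == 3

    def test_all_expressing_unchanged(self):
        X = _em(np.ones((5, 4)))
        assert filter_cells(X) is X

    def test_all_cells_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_cells(_em(np.zeros((10, 2))), min_gene_fraction=0.5)

    def test_rare_gene_removed(self):
        vals = np.ones((2, 20))
        vals[1] = 0.0
        vals[1, 0] = 5.0  # expressed in 1/20 = 5% < 10%
        out = filter_genes(_em(vals), min_variance=0.0)
        assert out.gene_names == ["g0"]

    def test_constant_gene_removed_by_variance(self):
        vals = np.vstack([np.ones(10), np.linspace(1, 2, 10)])
        out = filter_genes(_em(vals))
        assert out.gene_names == ["g1"]

    def test_variable_ubiquitous_gene_kept(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, size=(1, 12)) ** 2
        assert filter_genes(_em(vals)).n_genes == 1

    @pytest.mark.parametrize("which", ["cells", "genes"])
    def test_idempotent_and_matches_brute_force(self, rng, which):
        for _ in range(5):
            vals = rng.poisson(0.7, size=(50, 50)).astype(float)
            X = _em(vals)
            if which == "cells":
                once = filter_cells(X)
                twice = filter_cells(once)
                keep = [(vals[:, j] > 0).sum() >= 0.05 * 50 for j in range(50)]
                assert once.n_cells == sum(keep)
            else:
                once = filter_genes(X)
                twice = filter_genes(once)
                keep = [
                    (vals[i] > 0).sum() >= 0.10 * 50 and vals[i].var() >= 0.005
                    for i in range(50)
                ]
                assert once.n_genes == sum(keep)
            np.testing.assert_array_equal(once.values, twice.values)


class TestInformativeGenes:
    def test_dropout_dominated_gene_removed(self, rng):
        n = 500
        zero_heavy = np.where(rng.uniform(size=n) < 0.95, 0.0, rng.normal(5, 1, n))
        bimodal = np.where(rng.uniform(size=n) < 0.5, rng.normal(0.2, 0.05, n), rng.normal(5, 0.3, n))
        X = _em(np.abs(np.vstack([zero_heavy, bimodal])))
        rep = select_informative_genes(X, n_top=10, seed=0)
        assert "g0" in rep.removed_genes
        assert "g1" in rep.selected_genes

    def test_bimodal_ranks_before_unimodal(self, rng):
        n = 400
        bimodal = np.where(rng.uniform(size=n) < 0.5, rng.normal(0.5, 0.1, n), rng.normal(5, 0.1, n))
        unimodal = rng.normal(2, 0.1, n)
        X = _em(np.abs(np.vstack([unimodal, bimodal])), genes=["uni", "bi"])
        rep = select_informative_genes(X, n_top=2, seed=0)
        assert rep.selected_genes[0] == "bi"

    def test_n_top_larger_than_gene_count_warns(self, rng):
        vals = np.abs(rng.normal(2, 1, size=(3, 100)))
        with pytest.warns(UserWarning, match="survive"):
            rep = select_informative_genes(_em(vals), n_top=50, seed=0)
        assert len(rep.selected_genes) <= 3

    def test_reproducible_with_seed(self, rng):
        vals = np.abs(rng.normal(2, 1, size=(6, 200)))
        X = _em(vals)
        a = select_informative_genes(X, n_top=6, seed=7)
        b = select_informative_genes(X, n_top=6, seed=7)
        assert a.selected_genes == b.selected_genes
        pd.testing.assert_frame_equal(a.gmm_stats, b.gmm_stats)
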