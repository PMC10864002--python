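import math

import numpy as np
import pytest

from ifnsig.core_io import (
    ExpressionMatrix,
    FormatError,
    GeneSet,
    SampleMetadata,
    filter_cells,
    normalize,
    read_expression,
    read_gmt,
    write_expression,
    write_gmt,
)
import pandas as pd


class TestExpressionMatrix:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate gene id"):
            ExpressionMatrix(["A", "A"], ["S1"], np.zeros((2, 1)))

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate sample id"):
            ExpressionMatrix(["A", "B"], ["S", "S"], np.zeros((2, 2)))

    def test_negative_values_rejected(self):
        with pytest.raises(FormatError, match="negative"):
            ExpressionMatrix(["A"], ["S"], np.array([[-1.0]]))

    def test_counts_layer_requires_integers(self):
        with pytest.raises(FormatError, match="integral"):
            ExpressionMatrix(["A"], ["S"], np.array([[1.5]]), layer="counts")
        ExpressionMatrix(["A"], ["S"], np.array([[1.5]]), layer="cpm")  # fine

    def test_shape_mismatch(self):
        with pytest.raises(FormatError, match="shape"):
            ExpressionMatrix(["A", "B"], ["S"], np.zeros((1, 1)))


class TestReadExpression:
    def test_csv_integer_entries_infer_counts(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,S1,S2\nG1,1,2\nG2,3,4\nG3,0,5\n")
        m = read_expression(p)
        assert m.layer == "counts"
        assert m.gene_ids == ["G1", "G2", "G3"]
        assert m.values[2, 1] == 5

    def test_csv_fractional_entries_infer_cpm(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,S1\nG1,1.25\nG2,3\n")
        assert read_expression(p).layer == "cpm"

    def test_mtx_round_trip_matches_csv(self, tmp_path, small_counts):
        csv_path, mtx_path = tmp_path / "m.csv", tmp_path / "m.mtx"
        write_expression(small_counts, csv_path)
        write_expression(small_counts, mtx_path)
        from_csv = read_expression(csv_path)
        from_mtx = read_expression(mtx_path)
        np.testing.assert_array_equal(from_csv.values, from_mtx.values)
        assert from_csv.gene_ids == from_mtx.gene_ids
        assert from_csv.sample_ids == from_mtx.sample_ids

    def test_duplicate_gene_row_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,S1\nG1,1\nG1,2\n")
        with pytest.raises(FormatError, match="duplicate gene id"):
            read_expression(p)

    def test_missing_mtx_sidecar(self, tmp_path, small_counts):
        mtx = tmp_path / "m.mtx"
        write_expression(small_counts, mtx)
        (tmp_path / "m.genes.txt").unlink()
        with pytest.raises(FormatError, match="sidecar"):
            read_expression(mtx)


class TestGmt:
    def test_packaged_signatures(self):
        from ifnsig import packaged_gmt

        neut = packaged_gmt("neut_ifn15")[0]
        ifng = packaged_gmt("ifng6")[0]
        assert len(neut.genes) == 15
        assert len(ifng.genes) == 6

    def test_deduplication_preserves_first_occurrence(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\tdesc\tA\tA\tB\n")
        (s,) = read_gmt(p)
        assert s.genes == ("A", "B")

    def test_case_insensitive_dedup(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\tdesc\tLy6e\tLY6E\tB\n")
        (s,) = read_gmt(p)
        assert s.genes == ("Ly6e", "B")

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\tdesc\n")
        with pytest.raises(FormatError, match="<3"):
            read_gmt(p)

    def test_round_trip(self, tmp_path):
        sets = [GeneSet("a", ("X", "Y")), GeneSet("b", ("Z",))]
        p = tmp_path / "rt.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets


class TestGeneSet:
    def test_duplicate_after_case_normalization_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            GeneSet("s", ("Ly6e", "LY6E"))

    def test_case_insensitive_matrix_matching(self, small_counts):
        s = GeneSet("s", ("g1", "g3"))
        assert s.present_in(small_counts) == [0, 2]


class TestNormalize:
    def test_cpm_proportionality(self):
        m = ExpressionMatrix(["A", "B"], ["S"], np.array([[1.0], [3.0]]))
        out = normalize(m, "cpm")
        np.testing.assert_allclose(out.values[:, 0], [250000.0, 750000.0])

    def test_cpm_of_cpm_errors(self, small_counts):
        with pytest.raises(ValueError, match="layer must be counts"):
            normalize(normalize(small_counts, "cpm"), "cpm")

    def test_logcpm_direct_arithmetic(self):
        # oracle: column [0, 0, 4] -> cpm [0, 0, 1e6] -> log2(1e6 + 1)
        m = ExpressionMatrix(["A", "B", "C"], ["S"], np.array([[0.0], [0.0], [4.0]]))
        out = normalize(m, "logcpm")
        expected = [0.0, 0.0, math.log2(1e6 + 1)]
        np.testing.assert_allclose(out.values[:, 0], expected)

    def test_all_zero_column_names_sample(self, small_counts):
        m = ExpressionMatrix(["A"], ["GOOD", "BAD"], np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="BAD"):
            normalize(m, "cpm")

    def test_cpm_preserves_within_column_rank_order(self, rng):
        vals = rng.integers(0, 50, size=(20, 5)).astype(float)
        vals[:, 0] += 1  # avoid an all-zero column
        m = ExpressionMatrix([f"G{i}" for i in range(20)], [f"S{j}" for j in range(5)], vals)
        out = normalize(m, "cpm")
        for j in range(5):
            assert (np.argsort(vals[:, j], kind="stable")
                    == np.argsort(out.values[:, j], kind="stable")).all()


class TestFilterCells:
    @pytest.fixture
    def toy(self):
        # 6 genes x 4 cells; cell C2 expresses only 2 genes
        vals = np.array(
            [
                [5, 1, 2, 3],
                [4, 0, 1, 2],
                [3, 0, 1, 1],
                [2, 0, 2, 1],
                [1, 0, 1, 2],
                [0, 3, 0, 1],
            ],
            dtype=float,
        )
        return ExpressionMatrix(
            [f"G{i}" for i in range(1, 6)] + ["mt-Nd1"],
            ["C1", "C2", "C3", "C4"],
            vals,
        )

    def test_min_genes_drops_sparse_cell(self, toy):
        out = filter_cells(toy, min_genes=3, max_genes=100, max_mito_frac=1.0)
        assert out.sample_ids == ["C1", "C3", "C4"]

    def test_high_mito_cell_removed(self):
        # cell "mito": 50% of counts on mt-Nd1; cell "ok": exactly 10%
        m = ExpressionMatrix(["G1", "mt-Nd1"], ["ok", "mito"], np.array([[9.0, 5.0], [1.0, 5.0]]))
        out = filter_cells(m, min_genes=1, max_genes=10, max_mito_frac=0.10)
        assert out.sample_ids == ["ok"]

    def test_permissive_thresholds_identity(self, toy):
        out = filter_cells(toy, min_genes=0, max_genes=10**9, max_mito_frac=1.0)
        np.testing.assert_array_equal(out.values, toy.values)

    def test_idempotent(self, toy):
        once = filter_cells(toy, min_genes=3, max_genes=100, max_mito_frac=1.0)
        twice = filter_cells(once, min_genes=3, max_genes=100, max_mito_frac=1.0)
        assert once.sample_ids == twice.sample_ids
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_removed_is_error(self, toy):
        with pytest.raises(ValueError, match="every cell"):
            filter_cells(toy, min_genes=6, max_genes=6, max_mito_frac=0.0)


class TestSampleMetadata:
    def test_valid(self):
        SampleMetadata(
            pd.DataFrame(
                {"sample_id": ["a", "b"], "group": ["NR", "R"],
                 "dataset": ["d", "d"], "timing": ["PRE", "POST"]}
            )
        )

    def test_bad_group(self):
        with pytest.raises(FormatError, match="group"):
            SampleMetadata(
                pd.DataFrame(
                    {"sample_id": ["a"], "group": ["X"], "dataset": ["d"], "timing": ["PRE"]}
                )
            )

    def test_duplicate_sample(self):
        with pytest.raises(FormatError, match="duplicate"):
            SampleMetadata(
                pd.DataFrame(
                    {"sample_id": ["a", "a"], "group": ["NR", "R"],
                     "dataset": ["d", "d"], "timing": ["PRE", "PRE"]}
                )
            )
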