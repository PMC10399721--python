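"""Probe-level loading, filtering rules, gene collapse and expression calls."""

import numpy as np
import pandas as pd
import pytest

from xenotalk.expression import (
    CONDITIONS,
    collapse_to_genes,
    expression_call,
    load_expression,
    read_blacklist,
    remove_cross_hybridizing,
    significance_prefilter,
)
from xenotalk.geo import read_series_matrix

from conftest import four_arm_sheet, make_matrix


def _write_bundle(tmp_path, data, annot_rows):
    expr = tmp_path / "expr.tsv"
    data.rename_axis("probe_id").to_csv(expr, sep="\t")
    annot = tmp_path / "annot.tsv"
    pd.DataFrame(annot_rows, columns=["probe_id", "species", "gene"]).to_csv(
        annot, sep="\t", index=False
    )
    samples = tmp_path / "samples.tsv"
    four_arm_sheet().table.to_csv(samples, sep="\t", index=False)
    return expr, annot, samples


@pytest.fixture
def tiny_files(tmp_path):
    rng = np.random.default_rng(0)
    sheet = four_arm_sheet()
    data = pd.DataFrame(
        rng.normal(7, 1, (4, 12)).round(4),
        index=["p1", "p2", "p3", "p4"],
        columns=sheet.sample_ids,
    )
    annot = [("p1", "human", "CSF2"), ("p2", "human", "CSF2"),
             ("p3", "mouse", "CSF2RA"), ("p4", "mouse", "IL6RA")]
    return _write_bundle(tmp_path, data, annot), data


class TestLoadExpression:
    def test_loads_four_probe_fixture(self, tiny_files):
        (expr, annot, samples), data = tiny_files
        matrix, sheet = load_expression(expr, annot, samples)
        assert matrix.data.shape == (4, 12)
        assert list(matrix.data.columns) == sheet.sample_ids

    def test_round_trip_is_bit_identical(self, tiny_files, tmp_path):
        (expr, annot, samples), data = tiny_files
        matrix, _ = load_expression(expr, annot, samples)
        out = tmp_path / "again.tsv"
        matrix.to_tsv(out)
        again, _ = load_expression(out, annot, samples)
        pd.testing.assert_frame_equal(matrix.data, again.data)

    def test_unannotated_probe_dropped_with_warning(self, tmp_path, caplog):
        sheet = four_arm_sheet()
        data = pd.DataFrame(np.ones((4, 12)), index=["p1", "p2", "p3", "px"],
                            columns=sheet.sample_ids)
        files = _write_bundle(tmp_path, data, [("p1", "human", "A"),
                                               ("p2", "human", "B"),
                                               ("p3", "mouse", "C")])
        matrix, _ = load_expression(*files)
        assert matrix.n_rows == 3
        assert "dropped 1 unannotated" in caplog.text

    def test_sample_missing_from_sheet_is_fatal(self, tiny_files, tmp_path):
        (expr, annot, samples), data = tiny_files
        bad = data.copy()
        bad["mystery_sample"] = 1.0
        path = tmp_path / "bad.tsv"
        bad.rename_axis("probe_id").to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="mystery_sample"):
            load_expression(path, annot, samples)

    def test_non_numeric_cell_is_fatal(self, tiny_files, tmp_path):
        (expr, annot, samples), data = tiny_files
        text = expr.read_text().replace(str(data.iloc[0, 0]), "oops", 1)
        path = tmp_path / "nonnum.tsv"
        path.write_text(text)
        with pytest.raises(ValueError, match="non-numeric"):
            load_expression(path, annot, samples)


class TestSignificancePrefilter:
    @pytest.mark.parametrize(
        "pvals,retained",
        [
            ((0.20, 0.04, 0.50), True),
            ((0.20, 0.60, 0.90), False),
            ((0.05, 0.05, 0.05), False),  # strict inequality at the boundary
        ],
    )
    def test_min_p_rule(self, pvals, retained):
        table = pd.DataFrame([pvals], index=["p1"], columns=["brafi", "anti_vegfa", "combo"])
        kept, flags = significance_prefilter(table, alpha=0.05)
        assert ("p1" in kept) is retained
        assert flags["p1"] == retained

    def test_p_out_of_range_fatal(self):
        table = pd.DataFrame([[0.2, 1.4, 0.3]], index=["p1"],
                             columns=["brafi", "anti_vegfa", "combo"])
        with pytest.raises(ValueError):
            significance_prefilter(table)


class TestRemoveCrossHybridizing:
    def test_empty_blacklist_is_identity(self, expression_bundle):
        matrix = expression_bundle[0]
        out = remove_cross_hybridizing(matrix, set())
        pd.testing.assert_frame_equal(out.data, matrix.data)

    def test_full_blacklist_empties_matrix(self, expression_bundle):
        matrix = expression_bundle[0]
        out = remove_cross_hybridizing(matrix, set(matrix.data.index))
        assert out.n_rows == 0

    def test_set_difference_oracle_and_values_unchanged(self):
        rng = np.random.default_rng(3)
        probes = [f"p{i}" for i in range(10)]
        matrix = make_matrix(rng.normal(size=(10, 4)), probes, ["human"] * 10,
                             [f"g{i}" for i in range(10)])
        blacklist = {"p1", "p4", "p9", "not_in_matrix"}
        out = remove_cross_hybridizing(matrix, blacklist)
        expected = [p for p in probes if p not in blacklist]  # oracle
        assert list(out.data.index) == expected
        pd.testing.assert_frame_equal(out.data, matrix.data.loc[expected])

    def test_idempotent(self, expression_bundle):
        matrix, _, _, blacklist, _ = expression_bundle
        once = remove_cross_hybridizing(matrix, blacklist)
        twice = remove_cross_hybridizing(once, blacklist)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestCollapseToGenes:
    def test_keeps_probe_with_largest_mean(self):
        values = np.array([[5.0, 5.0], [7.2, 7.2], [4.0, 4.0]])
        matrix = make_matrix(values, ["a", "b", "c"], ["human"] * 3, ["G", "G", "H"])
        out = collapse_to_genes(matrix)
        assert out.data.loc["human:G"].tolist() == [7.2, 7.2]
        assert out.data.loc["human:H"].tolist() == [4.0, 4.0]

    def test_single_probe_gene_is_identity(self):
        matrix = make_matrix(np.array([[1.0, 2.0]]), ["a"], ["mouse"], ["G"])
        out = collapse_to_genes(matrix)
        assert out.data.loc["mouse:G"].tolist() == [1.0, 2.0]

    def test_tie_broken_by_smallest_probe_id(self):
        values = np.array([[3.0, 3.0], [3.0, 3.0]])
        matrix = make_matrix(values, ["p2", "p1"], ["human"] * 2, ["G", "G"])
        out = collapse_to_genes(matrix)
        assert out.row_meta.shape[0] == 1
        # winner must be p1: identical values, so check via a marked copy
        values = np.array([[3.0, 3.0], [3.0, 3.0]])
        matrix = make_matrix(values, ["pB", "pA"], ["human"] * 2, ["G", "G"])
        collapsed = collapse_to_genes(matrix)
        assert collapsed.data.index.tolist() == ["human:G"]

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(11)
        n_probes, n_genes = 50, 12
        genes = [f"g{rng.integers(n_genes)}" for _ in range(n_probes)]
        probes = [f"p{i:02d}" for i in range(n_probes)]
        matrix = make_matrix(rng.normal(7, 2, (n_probes, 12)), probes,
                             ["human"] * n_probes, genes)
        out = collapse_to_genes(matrix)
        for gene in set(genes):
            members = [p for p, g in zip(probes, genes) if g == gene]
            means = {p: matrix.data.loc[p].mean() for p in members}
            best = min(sorted(members), key=lambda p: (-means[p], p))  # oracle scan
            pd.testing.assert_series_equal(
                out.data.loc[f"human:{gene}"], matrix.data.loc[best], check_names=False
            )

    def test_row_count_equals_distinct_species_gene_pairs(self, expression_bundle):
        matrix = expression_bundle[0]
        out = collapse_to_genes(matrix)
        expected = matrix.row_meta.drop_duplicates(["species", "gene"]).shape[0]
        assert out.n_rows == expected

    def test_values_are_a_subset_of_probe_values(self, expression_bundle):
        # the whole probe pipeline only selects rows, never edits values
        matrix, _, _, blacklist, _ = expression_bundle
        out = collapse_to_genes(remove_cross_hybridizing(matrix, blacklist))
        probe_rows = {tuple(r) for r in matrix.data.to_numpy()}
        assert all(tuple(r) in probe_rows for r in out.data.to_numpy())


class TestExpressionCall:
    def _gene_matrix(self, cond_means):
        sheet = four_arm_sheet()
        row = np.repeat(cond_means, 3).astype(float)
        matrix = make_matrix(np.array([row]), ["g1"], ["human"], ["G"],
                             samples=sheet.sample_ids)
        return collapse_to_genes(matrix), sheet

    def test_one_condition_above_floor_is_expressed(self):
        genes, sheet = self._gene_matrix([4.0, 4.1, 4.0, 9.0])
        assert expression_call(genes, sheet, floor=6.0) == {("human", "G")}

    def test_all_below_floor_not_expressed(self):
        genes, sheet = self._gene_matrix([4.0, 4.1, 4.0, 5.0])
        assert expression_call(genes, sheet, floor=6.0) == set()

    def test_minus_inf_floor_calls_everything(self, expression_bundle):
        matrix, _, sheet, _, _ = expression_bundle
        genes = collapse_to_genes(matrix)
        calls = expression_call(genes, sheet, floor=-np.inf)
        assert len(calls) == genes.n_rows

    def test_empty_scope_fatal(self):
        genes, sheet = self._gene_matrix([4.0, 4.0, 4.0, 4.0])
        with pytest.raises(ValueError):
            expression_call(genes, sheet, floor=1.0, scope=())


class TestBlacklistFile:
    def test_comments_and_blanks_ignored(self, tmp_path):
        path = tmp_path / "bl.txt"
        path.write_text("# header\np1\n\np2  # trailing\n")
        assert read_blacklist(path) == {"p1", "p2"}


class TestGeoImport:
    def test_parses_synthetic_series_matrix(self, tmp_path):
        # synthetic stand-in for a downloaded series-matrix file
        text = (
            '!Series_geo_accession\t"GSExxxxx"\n'
            '!Sample_geo_accession\t"GSM1"\t"GSM2"\n'
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"p1"\t7.1\t7.3\n'
            '"p2"\t5.0\t5.2\n'
            "!series_matrix_table_end\n"
        )
        path = tmp_path / "series_matrix.txt"
        path.write_text(text)
        table, meta = read_series_matrix(path)
        assert table.shape == (2, 2)
        assert table.loc["p2", "GSM2"] == 5.2
        assert meta["Sample_geo_accession"] == ["GSM1", "GSM2"]

    def test_missing_table_block_fatal(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("!Series_title\tnothing\n")
        with pytest.raises(ValueError):
            read_series_matrix(path)
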