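"""Parsing, validation, round-tripping and cell-line matching."""

import io

import numpy as np
import pandas as pd
import pytest

from pharmforest.data_io import (
    DriverGeneSet,
    ResponseMatrix,
    load_driver_genes,
    match_cell_lines,
    normalize_cell_line_name,
    parse_alteration_gct,
    parse_response_table,
)

from conftest import TOY_GCT, binary_matrix


class TestAlterationGCT:
    def test_declared_shape_and_orientation(self, toy_gct_stream):
        alt = parse_alteration_gct(toy_gct_stream)
        assert alt.values.shape == (2, 3)  # cell lines x alterations
        assert alt.alterations == ["BRAF_MUT", "TP53_DEL", "MYC_AMP"]
        assert alt.cell_lines == ["A549_LUNG", "SKMEL2_SKIN"]

    def test_values_preserved_exactly(self, toy_gct_stream):
        alt = parse_alteration_gct(toy_gct_stream)
        assert alt.values.to_numpy().sum() == TOY_GCT.count("\t1")

    @pytest.mark.parametrize(
        "mangle, message",
        [
            (lambda t: t.replace("3\t2", "4\t2"), "dimension mismatch"),
            (lambda t: t.replace("\t0\t1\n", "\t2\t1\n"), "non-binary"),
            (lambda t: t.replace("TP53_DEL", "BRAF_MUT"), "duplicate alteration"),
            (lambda t: t.replace("#1.2", "1.2"), "version"),
        ],
    )
    def test_malformed_inputs_rejected(self, mangle, message):
        with pytest.raises(ValueError, match=message):
            parse_alteration_gct(io.StringIO(mangle(TOY_GCT)))

    def test_gct_round_trip(self, toy_gct_stream):
        alt = parse_alteration_gct(toy_gct_stream)
        buf = io.StringIO()
        alt.to_gct(buf)
        again = parse_alteration_gct(io.StringIO(buf.getvalue()))
        pd.testing.assert_frame_equal(alt.values, again.values)


class TestResponseTable:
    def test_blank_cell_becomes_missing(self, toy_response_stream):
        resp = parse_response_table(toy_response_stream)
        assert resp.values.shape == (3, 2)  # cell lines x compounds
        assert resp.n_missing == 1
        assert np.isnan(resp.values.at["HT29", "Erlotinib"])

    def test_complete_table_has_no_missing(self):
        resp = parse_response_table(io.StringIO("Compound,A,B\nd1,0.5,0.75\n"))
        assert resp.n_missing == 0

    def test_out_of_range_auc_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            parse_response_table(io.StringIO("Compound,A,B\nd1,1.2,0.5\n"))

    def test_duplicate_compound_rejected(self):
        with pytest.raises(ValueError, match="duplicate compound"):
            parse_response_table(io.StringIO("Compound,A\nd1,0.5\nd1,0.6\n"))

    def test_tab_separated_dialect(self):
        resp = parse_response_table(io.StringIO("Compound\tA\tB\nd1\t0.5\tNA\n"))
        assert resp.n_missing == 1


class TestDriverGenes:
    def test_deduplication(self):
        drivers = load_driver_genes(io.StringIO("BRAF\nTP53\nBRAF\n"))
        assert len(drivers) == 2 and "BRAF" in drivers

    def test_header_line_skipped(self):
        drivers = load_driver_genes(io.StringIO("symbol\nBRAF\n"))
        assert drivers.genes == frozenset({"BRAF"})

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            load_driver_genes(io.StringIO("\n\n"))

    def test_blank_symbol_rejected(self):
        with pytest.raises(ValueError):
            DriverGeneSet(frozenset({" BRAF"}))


class TestMatching:
    def test_tissue_suffix_stripping(self):
        assert normalize_cell_line_name("A549_LUNG") == ("A549", "LUNG")
        assert normalize_cell_line_name(
            "KMH2_HAEMATOPOIETIC_AND_LYMPHOID_TISSUE"
        ) == ("KMH2", "HAEMATOPOIETIC_AND_LYMPHOID_TISSUE")
        assert normalize_cell_line_name("NCI_H2087_LUNG")[0] == "NCI_H2087"
        assert normalize_cell_line_name("HT29") == ("HT29", None)

    def test_intersection_with_suffix_normalization(self, toy_gct_stream, toy_response_stream):
        study = match_cell_lines(
            parse_alteration_gct(toy_gct_stream), parse_response_table(toy_response_stream)
        )
        assert study.cell_lines == ["A549", "SKMEL2"]
        assert study.alterations.tissue.tolist() == ["LUNG", "SKIN"]
        assert list(study.responses.values.index) == ["A549", "SKMEL2"]

    def test_disjoint_sets_rejected(self, toy_gct_stream):
        resp = parse_response_table(io.StringIO("Compound,ZZ1,ZZ2\nd1,0.5,0.6\n"))
        with pytest.raises(ValueError, match="no shared cell lines"):
            match_cell_lines(parse_alteration_gct(toy_gct_stream), resp)

    def test_identical_sets_keep_alteration_order(self):
        alt = binary_matrix(np.eye(5, 3, dtype=int), cells=list("EDCBA"))
        resp = ResponseMatrix(
            pd.DataFrame({"d1": [0.1, 0.2, 0.3, 0.4, 0.5]}, index=list("ABCDE"))
        )
        study = match_cell_lines(alt, resp)
        assert study.cell_lines == list("EDCBA")

    def test_matching_is_idempotent(self, toy_gct_stream, toy_response_stream):
        study = match_cell_lines(
            parse_alteration_gct(toy_gct_stream), parse_response_table(toy_response_stream)
        )
        again = match_cell_lines(study.alterations, study.responses)
        pd.testing.assert_frame_equal(study.alterations.values, again.alterations.values)
        pd.testing.assert_frame_equal(study.responses.values, again.responses.values)
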