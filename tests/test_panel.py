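"""Reference panel: ingestion, filtering, ortholog mapping, enrichment
scores and specificity classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eshrd import (
    MIXED,
    build_classification,
    classify_gene,
    collapse_oligo,
    enrichment_score_frame,
    filter_low_expression,
    load_expression_panel,
    load_ortholog_map,
    map_orthologs,
)
from eshrd.errors import DataValueError, FormatError, StructureError
from eshrd.panel import (
    CellClassLabel,
    collapsed_cell_order,
    compute_enrichment_scores,
    format_label,
    parse_label,
)

from conftest import CELLS, brute_force_classify, brute_force_es, make_panel, write_panel_tsv


# ---------------------------------------------------------------------------
# ingestion


class TestLoadPanel:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "panel.tsv"
        write_panel_tsv(p, {"g1": [1] * 7, "g2": [2] * 7, "g3": [0.5] * 7})
        panel = load_expression_panel(p, namespace="mouse_symbol")
        assert panel.n_genes == 3
        assert panel.cell_types == CELLS
        assert panel.namespace == "mouse_symbol"

    def test_negative_value_names_row_and_column(self, tmp_path):
        p = tmp_path / "panel.tsv"
        write_panel_tsv(p, {"g1": [1] * 7, "g2": [1, 1, "-1.0", 1, 1, 1, 1]})
        with pytest.raises(DataValueError, match="g2.*'M'"):
            load_expression_panel(p, namespace="mouse_symbol")

    def test_non_numeric_value_rejected(self, tmp_path):
        p = tmp_path / "panel.tsv"
        write_panel_tsv(p, {"g1": [1, "abc", 1, 1, 1, 1, 1]})
        with pytest.raises(DataValueError, match="abc"):
            load_expression_panel(p, namespace="mouse_symbol")

    def test_duplicate_gene_rows_averaged(self, tmp_path, caplog):
        p = tmp_path / "panel.tsv"
        with open(p, "w") as fh:
            fh.write("gene_id\tN\tA\n")
            fh.write("Gfap\t2.0\t10.0\n")
            fh.write("Gfap\t4.0\t30.0\n")
        with caplog.at_level("WARNING"):
            panel = load_expression_panel(p, namespace="mouse_symbol")
        assert panel.n_genes == 1
        # per-column arithmetic mean of the two rows
        np.testing.assert_allclose(panel.values.loc["Gfap"], [3.0, 20.0])
        assert any("duplicate" in r.message for r in caplog.records)

    def test_too_few_cell_columns(self, tmp_path):
        p = tmp_path / "panel.tsv"
        with open(p, "w") as fh:
            fh.write("gene_id\tN\ng1\t1.0\n")
        with pytest.raises(StructureError):
            load_expression_panel(p, namespace="mouse_symbol")


# ---------------------------------------------------------------------------
# floor filter


class TestFilterLowExpression:
    def test_all_at_floor_removed(self):
        panel = make_panel({"flat": [0.1] * 7, "ok": [0.1, 0.1, 0.2, 0.1, 0.1, 0.1, 0.1]})
        kept = filter_low_expression(panel, floor=0.1)
        assert kept.gene_ids == ["ok"]

    def test_one_value_above_floor_retained(self):
        panel = make_panel({"g": [0.1, 0.1, 0.2, 0.1, 0.1, 0.1, 0.1]})
        assert filter_low_expression(panel).n_genes == 1

    def test_below_floor_also_removed(self):
        panel = make_panel({"dead": [0.0, 0.05, 0.1, 0.0, 0.1, 0.1, 0.1],
                            "live": [5.0] * 7})
        assert filter_low_expression(panel).gene_ids == ["live"]

    def test_everything_removed_is_an_error(self):
        panel = make_panel({"flat": [0.1] * 7})
        with pytest.raises(DataValueError, match="every gene"):
            filter_low_expression(panel)


# ---------------------------------------------------------------------------
# ortholog mapping


def _omap(pairs):
    return pd.DataFrame(pairs, columns=["source_id", "target_id"])


class TestMapOrthologs:
    def test_one_to_one_identity(self):
        panel = make_panel({"Gfap": [1, 2, 3, 4, 5, 6, 7]})
        mapped = map_orthologs(panel, _omap([("Gfap", "ENSG_A")]))
        assert mapped.gene_ids == ["ENSG_A"]
        assert mapped.namespace == "human_ensembl"
        np.testing.assert_allclose(mapped.values.loc["ENSG_A"],
                                   panel.values.loc["Gfap"])

    def test_unmapped_gene_dropped(self):
        panel = make_panel({"Gfap": [1] * 7, "Xyz": [2] * 7})
        mapped = map_orthologs(panel, _omap([("Gfap", "ENSG_A")]))
        assert mapped.gene_ids == ["ENSG_A"]

    def test_many_to_one_averaged(self):
        panel = make_panel({"m1": [2.0] * 7, "m2": [4.0] * 7})
        mapped = map_orthologs(panel, _omap([("m1", "ENSG_B"), ("m2", "ENSG_B")]))
        np.testing.assert_allclose(mapped.values.loc["ENSG_B"], [3.0] * 7)

    def test_one_to_many_duplicated(self):
        panel = make_panel({"m1": [2.0] * 7})
        mapped = map_orthologs(panel, _omap([("m1", "ENSG_A"), ("m1", "ENSG_B")]))
        assert sorted(mapped.gene_ids) == ["ENSG_A", "ENSG_B"]

    def test_many_to_many_dropped(self):
        panel = make_panel({"m1": [1.0] * 7, "m2": [2.0] * 7, "m3": [9.0] * 7})
        # m1 -> {A, B}, m2 -> B: the m1/B pair is many-to-many, so m1 goes
        omap = _omap([("m1", "ENSG_A"), ("m1", "ENSG_B"),
                      ("m2", "ENSG_B"), ("m3", "ENSG_C")])
        mapped = map_orthologs(panel, omap)
        assert sorted(mapped.gene_ids) == ["ENSG_B", "ENSG_C"]
        np.testing.assert_allclose(mapped.values.loc["ENSG_B"], [2.0] * 7)

    def test_zero_mapped_is_an_error(self):
        panel = make_panel({"Gfap": [1] * 7})
        with pytest.raises(DataValueError, match="namespace"):
            map_orthologs(panel, _omap([("Nope", "ENSG_A")]))

    def test_loader_rejects_missing_columns(self, tmp_path):
        p = tmp_path / "omap.tsv"
        p.write_text("a\tb\nx\ty\n")
        with pytest.raises(FormatError):
            load_ortholog_map(p)

    def test_loader_drops_duplicate_pairs(self, tmp_path):
        p = tmp_path / "omap.tsv"
        p.write_text("source_id\ttarget_id\nGfap\tE1\nGfap\tE1\n")
        assert len(load_ortholog_map(p)) == 1


# ---------------------------------------------------------------------------
# enrichment scores


class TestEnrichmentScores:
    def test_uniform_gene_is_all_ones(self):
        panel = make_panel({"g": [5.0] * 7})
        es = enrichment_score_frame(panel)
        np.testing.assert_allclose(es.loc["g"], 1.0)

    def test_two_cell_ratios(self):
        panel = make_panel({"g": [4.0, 2.0]}, cells=("c1", "c2"))
        es = enrichment_score_frame(panel)
        np.testing.assert_allclose(es.loc["g"], [2.0, 0.5])

    def test_seven_cell_hand_computed(self):
        vals = [70.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        panel = make_panel({"g": vals})
        es = enrichment_score_frame(panel)
        assert es.loc["g", "N"] == pytest.approx(70.0 / (0.6 / 6))  # 700.0
        expected_other = 0.1 / ((70 + 5 * 0.1) / 6)  # ~0.008511
        np.testing.assert_allclose(es.loc["g"][1:], expected_other)

    def test_matches_brute_force_on_random_panels(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.1, 100, size=(15, 5))
        panel = make_panel(
            {f"g{i}": list(vals[i]) for i in range(15)},
            cells=("c1", "c2", "c3", "c4", "c5"),
        )
        es = enrichment_score_frame(panel)
        for i in range(15):
            np.testing.assert_allclose(es.iloc[i], brute_force_es(vals[i]))

    def test_values_below_floor_are_raised(self):
        # 0.05 is floored to 0.1 before the ratio, keeping denominators > 0
        panel = make_panel({"g": [10.0, 0.05]}, cells=("c1", "c2"))
        es = enrichment_score_frame(panel, floor=0.1)
        assert es.loc["g", "c1"] == pytest.approx(100.0)

    def test_profile_objects_carry_es_high(self, tiny_panel):
        profiles = compute_enrichment_scores(tiny_panel)
        for prof in profiles:
            assert prof.es_high == pytest.approx(max(prof.es.values()))


# ---------------------------------------------------------------------------
# classification


class TestClassifyGene:
    def _es(self, vals):
        return dict(zip(CELLS, vals))

    def test_uniform_is_mixed(self):
        lab = classify_gene(self._es([1.0] * 7))
        assert lab.label == MIXED

    def test_single_cell_specific(self):
        lab = classify_gene(self._es([700.0] + [0.0085] * 6))
        assert lab.label == frozenset({"N"})

    def test_interior_es_forces_mixed(self):
        # 4 = 0.5 * es_high lies strictly inside (2, 6)
        lab = classify_gene(self._es([8.0, 4.0, 0.5, 0.5, 0.5, 0.5, 0.5]))
        assert lab.label == MIXED

    def test_multiple_cell_specific(self):
        lab = classify_gene(self._es([8.0, 7.0, 0.5, 0.5, 0.5, 0.5, 0.5]))
        assert lab.label == frozenset({"N", "A"})

    def test_boundaries_belong_to_high_and_low(self):
        # exactly 0.75 * es_high is high, exactly 0.25 * es_high is low
        lab = classify_gene(self._es([8.0, 6.0, 2.0, 2.0, 2.0, 2.0, 2.0]))
        assert lab.label == frozenset({"N", "A"})

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(DataValueError):
            classify_gene(self._es([1.0] * 7), alpha_low=0.8, alpha_high=0.3)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.01, max_value=1000), min_size=2,
                    max_size=8))
    def test_agrees_with_brute_force(self, values):
        es = {f"c{i}": v for i, v in enumerate(values)}
        got = classify_gene(es).label
        assert got == brute_force_classify(es)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.01, max_value=1000), min_size=2,
                    max_size=8),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, values, k):
        es_a = {f"c{i}": v for i, v in enumerate(values)}
        es_b = {c: v * k for c, v in es_a.items()}
        assert classify_gene(es_a).label == classify_gene(es_b).label

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.01, max_value=1000), min_size=3,
                    max_size=8, unique=True),
           st.randoms(use_true_random=False))
    def test_cell_order_invariance(self, values, rnd):
        cells = [f"c{i}" for i in range(len(values))]
        es = dict(zip(cells, values))
        shuffled = list(es.items())
        rnd.shuffle(shuffled)
        assert classify_gene(es).label == classify_gene(dict(shuffled)).label

    def test_threshold_monotonicity(self):
        """Raising alpha_low (alpha_high fixed) shrinks the strictly-interior
        band: non-MIXED labels are preserved exactly, and genes can only
        leave MIXED, never enter it."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            es = dict(zip(CELLS, rng.uniform(0.01, 10, size=7)))
            loose = classify_gene(es, alpha_low=0.25, alpha_high=0.75).label
            tight = classify_gene(es, alpha_low=0.6, alpha_high=0.75).label
            if loose != MIXED:
                assert tight == loose


class TestCollapseOligo:
    @pytest.mark.parametrize("label,expected", [
        (frozenset({"MO", "NFO"}), frozenset({"O"})),
        (frozenset({"MO"}), frozenset({"O"})),
        (frozenset({"MO", "OPC"}), frozenset({"O"})),
        (frozenset({"OPC", "M"}), frozenset({"O", "M"})),
        (frozenset({"N"}), frozenset({"N"})),
        (MIXED, MIXED),
    ])
    def test_collapsing_rules(self, label, expected):
        out = collapse_oligo(CellClassLabel("g", label, label))
        assert out.collapsed_label == expected

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(DataValueError, match="unknown"):
            collapse_oligo(CellClassLabel("g", frozenset({"XX"}), frozenset()))


class TestLabelFormatting:
    def test_slash_join_in_canonical_order(self):
        assert format_label(frozenset({"NFO", "MO"}), CELLS) == "MO/NFO"
        assert format_label(MIXED, CELLS) == "mixed"
        assert parse_label("MO/NFO") == frozenset({"MO", "NFO"})

    def test_collapsed_cell_order(self):
        assert collapsed_cell_order(CELLS) == ("N", "A", "M", "O", "EC")


# ---------------------------------------------------------------------------
# full classification build


class TestBuildClassification:
    def test_covers_every_retained_gene(self, noise_free_classified):
        panel, truth, table = noise_free_classified
        assert len(table) == panel.n_genes
        assert not table.df.index.duplicated().any()

    def test_proportions_sum_to_one(self, noise_free_classified):
        _, _, table = noise_free_classified
        assert table.class_proportions().sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_planted_labels(self, noise_free_classified):
        _, truth, table = noise_free_classified
        got = table.df["label"]
        assert all(got[g] == lab for g, lab in truth.items())

    def test_scale_invariance_of_labels(self, noise_free_classified):
        panel, _, table = noise_free_classified
        scaled = panel.values.copy()
        rng = np.random.default_rng(7)
        scaled = scaled.mul(rng.uniform(0.5, 20, size=len(scaled)), axis=0)
        from eshrd import ExpressionPanel
        table2 = build_classification(ExpressionPanel(scaled, panel.namespace))
        # floor interacts with scaling; compare genes kept in both
        shared = table.df.index.intersection(table2.df.index)
        assert len(shared) == len(table)
        pd.testing.assert_series_equal(table.df.loc[shared, "label"],
                                       table2.df.loc[shared, "label"])

    def test_column_permutation_invariance(self, noise_free_classified):
        panel, _, table = noise_free_classified
        from eshrd import ExpressionPanel
        perm = ["EC", "M", "N", "OPC", "A", "MO", "NFO"]
        table2 = build_classification(
            ExpressionPanel(panel.values[perm], panel.namespace)
        )
        # labels are sets; slash order differs but set content must match
        for g in table.df.index:
            assert parse_label(table.df.loc[g, "label"]) == \
                parse_label(table2.df.loc[g, "label"])

    def test_empty_panel_rejected(self):
        df = pd.DataFrame(columns=["N", "A"], dtype=float)
        from eshrd import ExpressionPanel
        with pytest.raises(DataValueError):
            build_classification(ExpressionPanel(df, "mouse_symbol"))

    def test_tsv_round_trip(self, noise_free_classified, tmp_path):
        _, _, table = noise_free_classified
        out = tmp_path / "classification.tsv"
        table.to_tsv(out)
        back = type(table).from_tsv(out)
        pd.testing.assert_frame_equal(table.df, back.df)
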