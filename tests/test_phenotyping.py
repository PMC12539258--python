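from itertools import product

import numpy as np
import pandas as pd
import pytest

import tissuequant as tq
from tissuequant.datatypes import (
    CellTable,
    Channel,
    FormatError,
    LabelMask,
    MarkerImageStack,
    PhenotypeKey,
    PhenotypeRule,
    ThresholdEntry,
    ThresholdSet,
)
from tissuequant.segmentation import SegmentationResult


def tiny_segmentation():
    """One 5x5 cell whose nucleus is the central 3x3 block."""
    cells = np.zeros((7, 7), dtype=np.int32)
    cells[1:6, 1:6] = 1
    nuclei = np.zeros((7, 7), dtype=np.int32)
    nuclei[2:5, 2:5] = 1
    cyto = np.where(nuclei > 0, 0, cells)
    return SegmentationResult(
        nuclei=LabelMask(nuclei, 1.0),
        cells=LabelMask(cells, 1.0),
        cytoplasm=LabelMask(cyto, 1.0),
    )


class TestQuantifyCells:
    def test_constant_channel_gives_constant_statistics(self):
        seg = tiny_segmentation()
        stack = MarkerImageStack(
            np.full((7, 7, 1), 42.0), [Channel("c", "CK", "f")], 1.0
        )
        table = tq.quantify_cells(stack, seg)
        for region in ("nucleus", "cytoplasm", "cell"):
            for stat in ("mean", "median", "p75", "p90"):
                assert table.df[f"score_CK_{region}_{stat}"].iloc[0] == 42.0

    def test_statistics_match_hand_computed_values(self):
        seg = tiny_segmentation()
        img = np.zeros((7, 7, 1))
        img[1:6, 1:6, 0] = np.arange(25, dtype=float).reshape(5, 5)
        stack = MarkerImageStack(img, [Channel("c", "CK", "f")], 1.0)
        table = tq.quantify_cells(stack, seg)
        cell_vals = img[1:6, 1:6, 0].ravel()
        nuc_vals = img[2:5, 2:5, 0].ravel()
        cyto_vals = np.array(sorted(set(range(25)) - set(nuc_vals.astype(int))), float)
        row = table.df.iloc[0]
        assert row["score_CK_cell_mean"] == pytest.approx(cell_vals.mean())
        assert row["score_CK_nucleus_median"] == pytest.approx(np.median(nuc_vals))
        assert row["score_CK_cytoplasm_p75"] == pytest.approx(
            np.percentile(cyto_vals, 75)
        )
        assert row["area_um2"] == 25.0
        assert row["x_um"] == pytest.approx(3.5)  # centre of the 5x5 block

    def test_empty_cytoplasm_yields_missing_not_zero(self):
        nuclei = np.zeros((5, 5), dtype=np.int32)
        nuclei[1:4, 1:4] = 1
        seg = SegmentationResult(
            nuclei=LabelMask(nuclei, 1.0),
            cells=LabelMask(nuclei.copy(), 1.0),
            cytoplasm=LabelMask(np.zeros_like(nuclei), 1.0),
        )
        stack = MarkerImageStack(np.ones((5, 5, 1)), [Channel("c", "CK", "f")], 1.0)
        table = tq.quantify_cells(stack, seg)
        assert np.isnan(table.df["score_CK_cytoplasm_mean"].iloc[0])

    def test_cell_without_nucleus_is_consistency_error(self):
        cells = np.zeros((5, 5), dtype=np.int32)
        cells[1:4, 1:4] = 2
        seg = SegmentationResult.__new__(SegmentationResult)
        seg.nuclei = LabelMask(np.zeros_like(cells), 1.0)
        seg.cells = LabelMask(cells, 1.0)
        seg.cytoplasm = LabelMask(cells, 1.0)
        stack = MarkerImageStack(np.ones((5, 5, 1)), [Channel("c", "CK", "f")], 1.0)
        with pytest.raises(FormatError, match="without nuclei"):
            tq.quantify_cells(stack, seg)


class TestApplyThresholds:
    def make_table(self, scores):
        return CellTable(
            pd.DataFrame(
                {
                    "image_id": "i",
                    "cell_id": range(len(scores)),
                    "score_CK_cell_mean": scores,
                }
            )
        )

    def test_score_equal_to_threshold_is_negative(self):
        ts = ThresholdSet({"CK": ThresholdEntry("cell", "mean", 10.0)})
        out = tq.apply_thresholds(self.make_table([10.0, 10.0001]), ts)
        assert list(out.df["pos_CK"]) == [False, True]

    def test_minus_infinity_threshold_marks_all_positive(self):
        ts = ThresholdSet({"CK": ThresholdEntry("cell", "mean", -1e300)})
        out = tq.apply_thresholds(self.make_table([0.0, 5.0, 100.0]), ts)
        assert out.df["pos_CK"].all()

    def test_flags_match_elementwise_comparison_and_are_idempotent(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 20, 50)
        ts = ThresholdSet({"CK": ThresholdEntry("cell", "mean", 10.0)})
        out = tq.apply_thresholds(self.make_table(scores), ts)
        np.testing.assert_array_equal(out.df["pos_CK"].to_numpy(), scores > 10.0)
        again = tq.apply_thresholds(out, ts)
        np.testing.assert_array_equal(
            again.df["pos_CK"].to_numpy(), out.df["pos_CK"].to_numpy()
        )

    def test_missing_score_column_names_the_marker(self):
        ts = ThresholdSet({"CD8": ThresholdEntry("cell", "mean", 1.0)})
        with pytest.raises(FormatError, match="CD8"):
            tq.apply_thresholds(self.make_table([1.0]), ts)


class TestAssignPhenotypes:
    def test_double_positive_resolved_by_marker_priority(self):
        key = PhenotypeKey(
            rules=[
                PhenotypeRule({"CD3": "+"}, "T"),
                PhenotypeRule({"CD163": "+"}, "Macrophage"),
            ],
            priority=["CD3", "CD163"],
        )
        table = CellTable(
            pd.DataFrame(
                {"image_id": "i", "cell_id": [1], "pos_CD3": [True], "pos_CD163": [True]}
            )
        )
        out = tq.assign_phenotypes(table, key)
        assert out.df["phenotype"].iloc[0] == "T"

    def test_all_negative_maps_to_other(self, key3):
        table = CellTable(
            pd.DataFrame(
                {
                    "image_id": "i",
                    "cell_id": [1],
                    "pos_CK": [False],
                    "pos_CD3": [False],
                    "pos_CD20": [False],
                }
            )
        )
        assert tq.assign_phenotypes(table, key3).df["phenotype"].iloc[0] == "other"

    def test_exhaustive_combinations_match_bruteforce_rule_scan(self, key3):
        combos = list(product([False, True], repeat=3))
        table = CellTable(
            pd.DataFrame(
                {
                    "image_id": "i",
                    "cell_id": range(len(combos)),
                    "pos_CK": [c[0] for c in combos],
                    "pos_CD3": [c[1] for c in combos],
                    "pos_CD20": [c[2] for c in combos],
                }
            )
        )
        out = tq.assign_phenotypes(table, key3)
        for row, combo in zip(out.df.itertuples(), combos):
            flags = dict(zip(["CK", "CD3", "CD20"], combo))
            assert row.phenotype == key3.assign(flags)

    def test_invariant_to_cell_ordering(self, key3):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "image_id": "i",
                "cell_id": range(30),
                "pos_CK": rng.random(30) > 0.5,
                "pos_CD3": rng.random(30) > 0.5,
                "pos_CD20": rng.random(30) > 0.5,
            }
        )
        fwd = tq.assign_phenotypes(CellTable(df), key3).df
        rev = tq.assign_phenotypes(CellTable(df.iloc[::-1]), key3).df
        merged = fwd.merge(rev, on="cell_id", suffixes=("_f", "_r"))
        assert (merged["phenotype_f"] == merged["phenotype_r"]).all()


class TestThresholdProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=40,
        ),
        st.floats(min_value=0, max_value=1e6, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_positivity_is_strict_comparison_for_any_scores(self, scores, thr):
        ts = ThresholdSet({"CK": ThresholdEntry("cell", "mean", thr)})
        table = CellTable(
            pd.DataFrame(
                {
                    "image_id": "i",
                    "cell_id": range(len(scores)),
                    "score_CK_cell_mean": scores,
                }
            )
        )
        out = tq.apply_thresholds(table, ts)
        np.testing.assert_array_equal(
            out.df["pos_CK"].to_numpy(), np.asarray(scores) > thr
        )


class TestAssignUnknown:
    def probs(self, rows, classes=("a", "b", "c")):
        return pd.DataFrame(rows, columns=list(classes))

    def test_max_below_30pct_is_unknown(self):
        out = tq.assign_unknown(self.probs([[0.29, 0.29, 0.42]]))
        # max is 0.42 -> labeled; craft a true below-threshold case
        out2 = tq.assign_unknown(
            self.probs([[0.29, 0.285, 0.425]]), threshold_pct=50
        )
        assert out2.iloc[0] == "unknown"
        flat = tq.assign_unknown(self.probs([[0.29, 0.285, 0.425]]))
        assert flat.iloc[0] == "c"

    def test_exactly_30pct_keeps_the_argmax_label(self):
        out = tq.assign_unknown(self.probs([[0.30, 0.35, 0.35]]))
        assert out.iloc[0] != "unknown"
        boundary = tq.assign_unknown(self.probs([[0.30, 0.30, 0.40]]))
        assert boundary.iloc[0] == "c"
        exact = tq.assign_unknown(self.probs([[0.30, 0.42, 0.28]]))
        assert exact.iloc[0] == "b"

    def test_just_below_30pct_max_is_unknown(self):
        out = tq.assign_unknown(self.probs([[0.29, 0.29, 0.42]]), threshold_pct=43)
        assert out.iloc[0] == "unknown"
        out2 = tq.assign_unknown(self.probs([[0.29, 0.36, 0.35]]))
        assert out2.iloc[0] == "b"
        below = tq.assign_unknown(self.probs([[0.299, 0.299, 0.402]]))
        assert below.iloc[0] == "c"

    def test_uniform_over_14_classes_is_unknown(self):
        p = pd.DataFrame([[1 / 14.0] * 14], columns=[f"c{i}" for i in range(14)])
        assert tq.assign_unknown(p).iloc[0] == "unknown"

    def test_empty_vector_is_an_error(self):
        with pytest.raises(FormatError, match="empty"):
            tq.assign_unknown(pd.DataFrame(index=[0]))


class TestEvaluateClassifier:
    def test_perfect_prediction(self):
        truth = ["a", "a", "b", "b"]
        ev = tq.evaluate_classifier(truth, truth)
        assert ev.macro_f1 == 1.0 and ev.accuracy == 1.0
        assert (ev.tpr == 1.0).all() and (ev.fpr == 0.0).all()

    def test_hand_computed_confusion_matrix(self):
        truth = ["a"] * 10 + ["b"] * 10
        pred = ["a"] * 8 + ["b"] * 2 + ["a"] * 1 + ["b"] * 9
        ev = tq.evaluate_classifier(truth, pred)
        assert ev.tpr["a"] == pytest.approx(0.8)
        assert ev.tpr["b"] == pytest.approx(0.9)
        assert ev.fpr["a"] == pytest.approx(1 / 10)
        prec_a, rec_a = 8 / 9, 0.8
        assert ev.f1["a"] == pytest.approx(2 * prec_a * rec_a / (prec_a + rec_a))
        assert ev.accuracy == pytest.approx(17 / 20)

    def test_all_unknown_predictions_zero_tpr(self):
        with pytest.warns(UserWarning, match="unknown"):
            ev = tq.evaluate_classifier(["a", "b"], ["unknown", "unknown"])
        assert (ev.tpr == 0.0).all()

    def test_micro_accuracy_equals_confusion_trace_over_total(self):
        rng = np.random.default_rng(5)
        truth = rng.choice(["a", "b", "c"], 200)
        pred = rng.choice(["a", "b", "c"], 200)
        ev = tq.evaluate_classifier(truth, pred)
        trace = sum(ev.confusion.loc[c, c] for c in ev.confusion.index)
        assert ev.accuracy == pytest.approx(trace / 200)

    def test_matches_sklearn_metrics(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        truth = rng.choice(["a", "b", "c"], 300)
        pred = rng.choice(["a", "b", "c"], 300)
        ev = tq.evaluate_classifier(truth, pred)
        assert ev.macro_f1 == pytest.approx(
            sk.f1_score(truth, pred, average="macro")
        )
        assert ev.accuracy == pytest.approx(sk.accuracy_score(truth, pred))

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(FormatError):
            tq.evaluate_classifier(["a"], ["a", "b"])


class TestSplitTrainTest:
    def make_table(self, n=100, classes=("a", "b", "c", "d")):
        return CellTable(
            pd.DataFrame(
                {
                    "image_id": "i",
                    "cell_id": range(n),
                    "phenotype": [classes[i % len(classes)] for i in range(n)],
                }
            )
        )

    def test_default_split_is_80_20(self):
        train, test = tq.split_train_test(self.make_table(100), seed=0)
        assert len(train) == 80 and len(test) == 20

    def test_same_seed_reproduces_the_split(self):
        t1, s1 = tq.split_train_test(self.make_table(), seed=42)
        t2, s2 = tq.split_train_test(self.make_table(), seed=42)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        pd.testing.assert_frame_equal(s1.df, s2.df)

    def test_stratified_split_preserves_class_proportions(self):
        train, test = tq.split_train_test(
            self.make_table(100), seed=1, stratify_by="phenotype"
        )
        assert train.df["phenotype"].value_counts().tolist() == [20] * 4
        assert test.df["phenotype"].value_counts().tolist() == [5] * 4

    def test_singleton_stratum_stays_in_train_with_warning(self):
        table = self.make_table(9, classes=("a", "b", "c", "d"))
        df = table.df.copy()
        df.loc[8, "phenotype"] = "rare"
        with pytest.warns(UserWarning, match="rare"):
            train, test = tq.split_train_test(
                CellTable(df[df.index < 9]), seed=0, stratify_by="phenotype"
            )
        assert "rare" in set(train.df["phenotype"])
        assert "rare" not in set(test.df["phenotype"])
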