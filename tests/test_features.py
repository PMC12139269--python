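import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutgraph.cohort_io import CASE, CONTROL, CohortLabels, GeneCatalog, MutationMatrix, ValidationError
from mutgraph.features import (
    BM25Params,
    bm25_tf,
    compute_feature_matrix,
    compute_nm_features,
    compute_rf_table,
)


def make_matrix(counts, catalog=None):
    counts = np.asarray(counts)
    if catalog is None:
        genes = tuple(f"G{j}" for j in range(counts.shape[1]))
        catalog = GeneCatalog(genes, {g: f"P{g}" for g in genes})
    patients = tuple(f"p{i}" for i in range(counts.shape[0]))
    return MutationMatrix(patients, counts, catalog)


class TestBM25:
    @pytest.mark.parametrize("k", [0.5, 1.2, 3.0])
    def test_zero_and_fixed_point(self, k):
        assert bm25_tf(0, k) == 0.0
        assert bm25_tf(1, k) == pytest.approx(1.0)

    def test_hand_value(self):
        assert bm25_tf(3, 1.2) == pytest.approx(6.6 / 4.2, abs=1e-12)

    def test_negative_tf_rejected(self):
        with pytest.raises(ValueError):
            bm25_tf(-1, 1.2)

    @settings(max_examples=200, derandomize=True)
    @given(
        tf1=st.floats(0, 1e3, allow_nan=False),
        delta=st.floats(0.01, 1e3),
        k=st.floats(0.01, 10),
    )
    def test_monotone_and_bounded(self, tf1, delta, k):
        lo, hi = bm25_tf(tf1, k), bm25_tf(tf1 + delta, k)
        assert lo < hi < k + 1


class TestRFTable:
    def test_zero_support_gives_unit_rf(self):
        # one gene mutated only in controls: case support a=0 -> rf_case = log2(2) = 1
        m = make_matrix([[0], [0], [3], [1]])
        labels = CohortLabels({"p0": CASE, "p1": CASE, "p2": CONTROL, "p3": CONTROL})
        rf = compute_rf_table(m, labels)
        assert rf.rf_case[0] == pytest.approx(1.0)

    def test_hand_values_patient_support(self):
        # gene 0: mutated in both cases, no controls -> a=2, b=0 -> log2(4) = 2
        m = make_matrix([[1], [5], [0], [0]])
        labels = CohortLabels({"p0": CASE, "p1": CASE, "p2": CONTROL, "p3": CONTROL})
        rf = compute_rf_table(m, labels)
        assert rf.rf_case[0] == pytest.approx(2.0, abs=1e-9)

    def test_hand_value_a6_b2(self):
        counts = [[1]] * 6 + [[0]] * 2 + [[1], [1], [0], [0], [0], [0], [0], [0]]
        labels = CohortLabels(
            {f"p{i}": (CASE if i < 8 else CONTROL) for i in range(16)}
        )
        rf = compute_rf_table(make_matrix(counts), labels)
        assert rf.rf_case[0] == pytest.approx(np.log2(5), abs=1e-9)  # a=6, b=2
        assert rf.rf_control[0] == pytest.approx(np.log2(2 + 2 / 6), abs=1e-9)

    def test_events_mode_counts_events(self):
        m = make_matrix([[3], [0], [1], [0]])
        labels = CohortLabels({"p0": CASE, "p1": CASE, "p2": CONTROL, "p3": CONTROL})
        rf = compute_rf_table(m, labels, support_mode="events")
        assert rf.a_case[0] == 3 and rf.b_case[0] == 1
        assert rf.rf_case[0] == pytest.approx(np.log2(5))

    def test_single_class_cohort_rejected(self):
        m = make_matrix([[1], [2]])
        with pytest.raises(ValidationError):
            compute_rf_table(m, CohortLabels({"p0": CASE, "p1": CASE}))

    def test_bad_log_base_rejected(self):
        m = make_matrix([[1], [0]])
        labels = CohortLabels({"p0": CASE, "p1": CONTROL})
        with pytest.raises(ValueError):
            compute_rf_table(m, labels, log_base=1.0)

    @settings(max_examples=100, derandomize=True)
    @given(a=st.integers(0, 50), b=st.integers(0, 50), bump=st.integers(1, 10))
    def test_rf_monotone_in_supports(self, a, b, bump):
        def rf(a_, b_):
            return np.log2(2 + a_ / max(1, b_))

        assert rf(a + bump, b) > rf(a, b)
        assert rf(a, b + bump) <= rf(a, b)


class TestFeatureMatrix:
    def labels4(self):
        return CohortLabels({"p0": CASE, "p1": CASE, "p2": CONTROL, "p3": CONTROL})

    def test_product_of_saturated_tf_and_rf(self):
        # gene mutated in both cases only: rf_case = 2; count 3, k=1.2
        m = make_matrix([[3], [5], [0], [0]])
        rf = compute_rf_table(m, self.labels4())
        feats = compute_feature_matrix(m, rf, {p: CASE for p in m.patients} | {"p2": CONTROL, "p3": CONTROL})
        assert feats.values[0, 0] == pytest.approx(bm25_tf(3, 1.2) * 2.0, abs=1e-9)
        assert feats.values[0, 0] == pytest.approx(3.142857142857, abs=1e-9)

    def test_zero_count_zero_feature_regardless_of_rf(self):
        m = make_matrix([[0], [4], [1], [0]])
        rf = compute_rf_table(m, self.labels4())
        feats = compute_feature_matrix(m, rf, dict(self.labels4().label))
        assert feats.values[0, 0] == 0.0 and feats.values[3, 0] == 0.0

    def test_assumption_changes_row_only_when_rf_differs(self):
        m = make_matrix([[2, 1], [1, 1], [0, 1], [0, 1]])
        rf = compute_rf_table(m, self.labels4())
        base = dict(self.labels4().label)
        as_case = compute_feature_matrix(m, rf, base | {"p0": CASE})
        as_control = compute_feature_matrix(m, rf, base | {"p0": CONTROL})
        # gene 0 separates classes -> rf differs -> row differs
        assert not np.allclose(as_case.values[0], as_control.values[0])
        # other rows are untouched by p0's assumption
        assert np.allclose(as_case.values[1:], as_control.values[1:])

    def test_missing_assumption_rejected(self):
        m = make_matrix([[1], [1], [0], [1]])
        rf = compute_rf_table(m, self.labels4())
        with pytest.raises(ValueError, match="assumption"):
            compute_feature_matrix(m, rf, {"p0": CASE})

    @settings(max_examples=50, derandomize=True)
    @given(scale=st.integers(2, 9))
    def test_row_support_invariant_under_count_scaling(self, scale):
        counts = np.array([[0, 1, 3], [2, 0, 1], [1, 1, 0], [0, 2, 2]])
        m = make_matrix(counts)
        rf = compute_rf_table(m, self.labels4())
        f1 = compute_feature_matrix(m, rf, dict(self.labels4().label))
        scaled = counts.copy()
        scaled[0] *= scale
        m2 = make_matrix(scaled)
        f2 = compute_feature_matrix(m2, rf, dict(self.labels4().label))
        assert np.array_equal(f1.values[0] > 0, f2.values[0] > 0)


class TestNormalizedCounts:
    @pytest.mark.parametrize(
        "row,expected",
        [([2, 2], [0.5, 0.5]), ([0, 0], [0.0, 0.0]), ([1, 3], [0.25, 0.75])],
    )
    def test_total_normalization(self, row, expected):
        m = make_matrix([row, [1, 0]])
        feats = compute_nm_features(m)
        assert feats.values[0].tolist() == pytest.approx(expected)

    def test_l2_option(self):
        m = make_matrix([[3, 4]])
        feats = compute_nm_features(m, norm="l2")
        assert feats.values[0].tolist() == pytest.approx([0.6, 0.8])


class TestSerialization:
    def test_tsv_and_sidecar_round_trip(self, tmp_path):
        from mutgraph.cohort_io import CohortLabels

        m = make_matrix([[2, 0], [1, 3], [0, 1], [1, 0]])
        labels = CohortLabels({"p0": 1, "p1": 1, "p2": 0, "p3": 0})
        rf = compute_rf_table(m, labels)
        feats = compute_feature_matrix(m, rf, dict(labels.label))
        path = tmp_path / "features.tsv"
        feats.save(path, genes=m.catalog.genes)
        import json

        import pandas as pd

        back = pd.read_csv(path, sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), feats.values)
        sidecar = json.loads((tmp_path / "features.tsv.json").read_text())
        assert sidecar["meta"]["k"] == 1.2
        assert sidecar["meta"]["support_mode"] == "patients"
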