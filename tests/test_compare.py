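import numpy as np
import pytest
from scipy.stats import ks_2samp

from _reference import ks_brute_force
from conftest import make_table
from randnet import (
    NetworkData,
    compare_multi,
    compare_single,
    ks_statistic,
    shared_attributes,
)


class TestKSStatistic:
    def test_replicated_series_is_identical(self):
        assert ks_statistic([1, 2, 3], [1, 1, 2, 2, 3, 3]) == 0.0

    def test_disjoint_ordered_supports(self):
        assert ks_statistic([1, 2], [3, 4]) == 1.0

    def test_interleaved_half(self):
        # pooled points 1,2,3,4: ECDF gaps 1/2, 0, 1/2, 0
        assert ks_statistic([1, 3], [2, 4]) == 0.5

    def test_matches_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = rng.normal(size=rng.integers(1, 60))
            b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(1, 60))
            expected = ks_2samp(a, b, method="asymp").statistic
            assert ks_statistic(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = list(rng.integers(0, 10, size=rng.integers(1, 30)))
            b = list(rng.integers(0, 10, size=rng.integers(1, 30)))
            assert ks_statistic(a, b) == pytest.approx(ks_brute_force(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_statistic([], [1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ks_statistic([1.0, float("nan")], [1.0])

    def test_value_sum_normalization(self):
        # identical samples are identical under either normalisation
        assert ks_statistic([1, 2, 3], [1, 2, 3], normalization="value_sum") == 0.0
        # disjoint ordered supports still give the maximal gap
        assert ks_statistic([1, 2], [3, 4], normalization="value_sum") == pytest.approx(1.0)
        with pytest.raises(ValueError, match="positive"):
            ks_statistic([-1, 1], [1, 2], normalization="value_sum")


class TestSharedAttributes:
    def test_intersection(self, toy_tables):
        t1, t2 = toy_tables
        assert shared_attributes([t1, t2]) == ["Degree"]

    def test_case_mismatch_is_empty(self):
        t1 = make_table({"Degree": {"a": 1}})
        t2 = make_table({"degree": {"a": 1}})
        with pytest.raises(ValueError, match="case-sensitive"):
            shared_attributes([t1, t2])

    def test_identical_tables_share_everything(self, toy_tables):
        t1, _ = toy_tables
        assert shared_attributes([t1, t1]) == ["Degree", "Eccentricity"]


def _net(name, attr_values):
    return NetworkData(name, make_table(attr_values))


class TestCompareSingle:
    def test_self_comparison_average_zero(self):
        real = _net("real", {"Degree": {"a": 1, "b": 2}})
        rand = _net("rand", {"Degree": {"x": 1, "y": 2}})
        report = compare_single(real, [rand], ["Degree"])
        avg_field = report.field_by_label(
            "average distance between the real network and each random network, "
            "across all attributes"
        )
        assert avg_field.rows == [["rand", "0"]]

    def test_matrix_shape_and_consistency(self):
        real = _net("real", {"Degree": {"a": 1, "b": 5}, "Ecc": {"a": 2, "b": 2}})
        randoms = [
            _net("r1", {"Degree": {"x": 1, "y": 5}, "Ecc": {"x": 9, "y": 9}}),
            _net("r2", {"Degree": {"x": 7, "y": 8}, "Ecc": {"x": 2, "y": 2}}),
        ]
        report = compare_single(real, randoms, ["Degree", "Ecc"])
        matrix = report.field_by_label(
            "distance between the real network and each random network, "
            "for each attribute"
        )
        header, *rows = matrix.rows
        assert header == ["attribute", "r1", "r2"]
        assert len(rows) == 2 and all(len(r) == 3 for r in rows)
        # average field = column means of the matrix field
        avg = report.field_by_label(
            "average distance between the real network and each random network, "
            "across all attributes"
        )
        for col, (name, value) in enumerate(avg.rows, start=1):
            column = [float(r[col]) for r in rows]
            assert float(value) == pytest.approx(sum(column) / len(column), abs=1e-6)

    def test_empty_randoms_rejected(self):
        real = _net("real", {"Degree": {"a": 1}})
        with pytest.raises(ValueError, match="at least one random"):
            compare_single(real, [], ["Degree"])

    def test_unshared_attribute_rejected(self):
        real = _net("real", {"Degree": {"a": 1}})
        rand = _net("rand", {"Degree": {"a": 1}})
        with pytest.raises(ValueError, match="not shared"):
            compare_single(real, [rand], ["Betweenness"])


class TestCompareMulti:
    def _inputs(self):
        reals = [
            _net("real1", {"Degree": {"a": 1, "b": 2}}),
            _net("real2", {"Degree": {"a": 8, "b": 9}}),
        ]
        randoms = [
            _net("r1", {"Degree": {"x": 1, "y": 2}}),
            _net("r2", {"Degree": {"x": 5, "y": 6}}),
            _net("r3", {"Degree": {"x": 8, "y": 9}}),
        ]
        return reals, randoms

    def test_matrix_shape(self):
        reals, randoms = self._inputs()
        report = compare_multi(reals, randoms, ["Degree"])
        matrix = report.field_by_label(
            "real-random distance matrix (average distance across all attributes)"
        )
        header, *rows = matrix.rows
        assert header == ["real network", "r1", "r2", "r3"]
        assert len(rows) == 2 and all(len(r) == 4 for r in rows)

    def test_identical_pair_gives_zero_cell(self):
        reals, randoms = self._inputs()
        report = compare_multi(reals, randoms, ["Degree"])
        matrix = report.field_by_label(
            "real-random distance matrix (average distance across all attributes)"
        )
        rows = {r[0]: r[1:] for r in matrix.rows[1:]}
        assert float(rows["real1"][0]) == 0.0  # real1 == r1
        assert float(rows["real2"][2]) == 0.0  # real2 == r3

    def test_summary_is_row_minimum(self):
        reals, randoms = self._inputs()
        report = compare_multi(reals, randoms, ["Degree"])
        matrix = report.field_by_label(
            "real-random distance matrix (average distance across all attributes)"
        )
        mins = {r[0]: min(float(c) for c in r[1:]) for r in matrix.rows[1:]}
        summary = report.field_by_label(
            "average distance to the most similar random network, "
            "for each real network"
        )
        for name, value in summary.rows:
            assert float(value) == pytest.approx(mins[name], abs=1e-6)

    def test_needs_two_reals(self):
        reals, randoms = self._inputs()
        with pytest.raises(ValueError, match=">= 2"):
            compare_multi(reals[:1], randoms, ["Degree"])


def test_missing_attribute_values_skipped_with_warning():
    real = _net("real", {"Degree": {"a": 1, "b": 2}})
    rand = NetworkData("rand", {"x": {"Degree": 1.0}, "y": {}})
    with pytest.warns(UserWarning, match="missing attribute"):
        report = compare_single(real, [rand], ["Degree"])
    assert report.mode == "single_real"
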