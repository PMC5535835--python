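import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fingerpls.chromatography import (
    AlkaneLadder,
    PeakTable,
    normalize_to_internal_standard,
    read_alkane_ladder,
    read_peak_table,
    retention_index,
    write_alkane_ladder,
    write_peak_table,
)


@pytest.fixture
def small_table():
    return PeakTable(
        sample_ids=["a", "b", "c"],
        component_ids=["c1", "c2", "IS", "c3"],
        areas=np.array(
            [
                [10.0, 20.0, 5.0, 2.5],
                [4.0, 8.0, 2.0, 1.0],
                [9.0, 3.0, 3.0, 3.0],
            ]
        ),
        internal_standard_id="IS",
    )


@pytest.fixture
def ladder():
    return AlkaneLadder(
        carbon_numbers=np.arange(8, 21),
        retention_times=4.0 + 2.0 * np.arange(13) + 0.1 * np.arange(13) ** 1.2,
    )


class TestPeakTableIO:
    def test_round_trip_preserves_values(self, small_table, tmp_path):
        path = tmp_path / "table.csv"
        write_peak_table(small_table, path)
        back = read_peak_table(path, internal_standard_id="IS")
        assert back.sample_ids == small_table.sample_ids
        assert back.component_ids == small_table.component_ids
        assert np.array_equal(back.areas, small_table.areas)

    def test_round_trip_with_retention_times(self, tmp_path):
        table = PeakTable(
            sample_ids=["s1", "s2"],
            component_ids=["c1", "c2"],
            areas=np.ones((2, 2)),
            retention_times=np.array([5.5, 9.25]),
        )
        path = tmp_path / "rt.csv"
        write_peak_table(table, path)
        back = read_peak_table(path)
        assert np.array_equal(back.retention_times, table.retention_times)

    def test_missing_internal_standard_column_is_named(self, small_table, tmp_path):
        path = tmp_path / "t.csv"
        write_peak_table(small_table, path)
        with pytest.raises(ValueError, match="undecane"):
            read_peak_table(path, internal_standard_id="undecane")

    def test_non_numeric_and_missing_areas_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,c1,c2\na,1.0,oops\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_peak_table(path)
        path.write_text("sample_id,c1,c2\na,1.0,\n")
        with pytest.raises(ValueError, match="missing"):
            read_peak_table(path)

    def test_duplicate_component_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("sample_id,c1,c1\na,1.0,2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_peak_table(path)

    def test_full_study_shape_accepted(self, tmp_path, default_dataset):
        path = tmp_path / "full.csv"
        write_peak_table(default_dataset.peak_table, path)
        back = read_peak_table(path)
        assert back.shape == (49, 80)


class TestNormalization:
    def test_matches_elementwise_division_oracle(self, rng):
        areas = rng.uniform(0.5, 50.0, size=(5, 6))
        table = PeakTable(
            sample_ids=[f"s{i}" for i in range(5)],
            component_ids=[f"c{j}" for j in range(5)] + ["IS"],
            areas=areas,
            internal_standard_id="IS",
        )
        rel = normalize_to_internal_standard(table, drop_internal_standard=False)
        expected = areas / areas[:, [5]]
        assert np.allclose(rel.to_numpy(), expected, atol=1e-12)
        assert np.allclose(rel["IS"], 1.0)

    def test_component_equal_to_standard_gives_one(self, small_table):
        rel = normalize_to_internal_standard(small_table)
        assert rel.loc["c", "c3"] == pytest.approx(1.0)

    def test_invariant_to_per_sample_scaling(self, small_table):
        rel = normalize_to_internal_standard(small_table)
        scaled = small_table.areas.copy()
        scaled[1] *= 7.3
        table2 = PeakTable(
            sample_ids=small_table.sample_ids,
            component_ids=small_table.component_ids,
            areas=scaled,
            internal_standard_id="IS",
        )
        rel2 = normalize_to_internal_standard(table2)
        assert np.allclose(rel.to_numpy(), rel2.to_numpy(), atol=1e-12)

    def test_internal_standard_column_dropped_by_default(self, small_table):
        assert "IS" not in normalize_to_internal_standard(small_table).columns

    def test_nonpositive_standard_area_names_sample(self, small_table):
        bad = small_table.areas.copy()
        bad[1, 2] = 0.0
        table = PeakTable(
            sample_ids=small_table.sample_ids,
            component_ids=small_table.component_ids,
            areas=bad,
            internal_standard_id="IS",
        )
        with pytest.raises(ValueError, match="'b'"):
            normalize_to_internal_standard(table)


class TestRetentionIndex:
    def test_alkane_times_map_to_hundred_times_carbon(self, ladder):
        for c, t in zip(ladder.carbon_numbers, ladder.retention_times):
            assert retention_index(t, ladder) == pytest.approx(100.0 * c, abs=1e-9)

    def test_midpoint_between_c10_and_c11(self, ladder):
        t10 = ladder.retention_times[2]
        t11 = ladder.retention_times[3]
        assert retention_index((t10 + t11) / 2, ladder) == pytest.approx(1050.0)

    def test_matches_piecewise_linear_oracle(self, ladder, rng):
        times = ladder.retention_times
        for t in rng.uniform(times[0], times[-1], size=100):
            expected = np.interp(t, times, 100.0 * ladder.carbon_numbers)
            assert retention_index(t, ladder) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_in_retention_time(self, f1, f2):
        ladder = AlkaneLadder(
            carbon_numbers=np.arange(8, 21),
            retention_times=4.0 + 2.1 * np.arange(13),
        )
        lo, hi = ladder.retention_times[0], ladder.retention_times[-1]
        t1, t2 = sorted([lo + f1 * (hi - lo), lo + f2 * (hi - lo)])
        assert retention_index(t1, ladder) <= retention_index(t2, ladder) + 1e-12

    def test_no_extrapolation_outside_ladder(self, ladder):
        with pytest.raises(ValueError, match="outside"):
            retention_index(ladder.retention_times[0] - 1.0, ladder)
        with pytest.raises(ValueError, match="outside"):
            retention_index(ladder.retention_times[-1] + 1.0, ladder)


def test_ladder_requires_strictly_increasing_times():
    with pytest.raises(ValueError):
        AlkaneLadder(carbon_numbers=[8, 9, 10], retention_times=[1.0, 3.0, 3.0])


def test_ladder_csv_round_trip(ladder, tmp_path):
    path = tmp_path / "ladder.csv"
    write_alkane_ladder(ladder, path)
    back = read_alkane_ladder(path)
    assert np.array_equal(back.carbon_numbers, ladder.carbon_numbers)
    assert np.allclose(back.retention_times, ladder.retention_times)
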