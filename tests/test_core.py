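"""Core data model: readers/writers, validation, normalization, filtering."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mullerkit as mk
from mullerkit.errors import (
    ConsistencyError,
    DegenerateInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

from conftest import simulated

LONG_4 = "clone_id,parent_id,time,size\nA,,0,10\nA,,1,8\nB,A,1,2\nB,A,0,0\n"


class TestReadLong:
    def test_direct_transcription(self):
        h = mk.read_long(io.StringIO(LONG_4))
        assert h.clone_ids == ["A", "B"]
        assert h.parent_of == {"A": None, "B": "A"}
        assert np.array_equal(h.times, [0.0, 1.0])
        assert np.array_equal(h.sizes, [[10, 8], [0, 2]])
        assert h.scale == mk.SIZE

    def test_missing_pair_zero_filled(self):
        sparse = "clone_id,parent_id,time,size\nA,,0,10\nA,,1,8\nB,A,1,2\n"
        assert mk.read_long(io.StringIO(sparse)).equals(mk.read_long(io.StringIO(LONG_4)))

    def test_conflicting_parents_rejected(self):
        bad = "clone_id,parent_id,time,size\nA,,0,1\nC,,0,1\nB,A,0,0\nB,C,1,1\n"
        with pytest.raises(ConsistencyError, match="conflicting parents"):
            mk.read_long(io.StringIO(bad))

    def test_duplicate_pair_with_differing_values_rejected(self):
        bad = "clone_id,parent_id,time,size\nA,,0,1\nA,,0,2\n"
        with pytest.raises(ConsistencyError, match="duplicate"):
            mk.read_long(io.StringIO(bad))

    def test_missing_column_names_the_column(self):
        with pytest.raises(FormatError, match="clone_id"):
            mk.read_long(io.StringIO("id,time,size\nA,0,1\n"))
        with pytest.raises(FormatError, match="value"):
            mk.read_long(io.StringIO("clone_id,time,qty\nA,0,1\n"))

    def test_parent_cycle_rejected(self):
        bad = "clone_id,parent_id,time,size\nA,B,0,1\nB,A,0,1\n"
        with pytest.raises(ValidationError, match="cycle"):
            mk.read_long(io.StringIO(bad))

    def test_frequency_column_sets_scale(self):
        h = mk.read_long(io.StringIO("clone_id,parent_id,time,frequency\nA,,0,1.0\n"))
        assert h.scale == mk.FREQUENCY

    def test_tab_delimiter_autodetected(self):
        h = mk.read_long(io.StringIO(LONG_4.replace(",", "\t")))
        assert np.array_equal(h.sizes, [[10, 8], [0, 2]])

    def test_attribute_column_captured(self):
        text = "clone_id,parent_id,time,size,fitness\nA,,0,10,1.0\nB,A,0,1,1.5\n"
        h = mk.read_long(io.StringIO(text))
        assert h.attributes["fitness"] == {"A": 1.0, "B": 1.5}


class TestReadWide:
    def test_equivalent_to_long(self):
        sizes = "clone_id,0,1\nA,10,8\nB,0,2\n"
        parents = "clone_id,parent_id\nA,\nB,A\n"
        assert mk.read_wide(io.StringIO(sizes), io.StringIO(parents)).equals(
            mk.read_long(io.StringIO(LONG_4))
        )

    def test_passage_labels_become_ordered_axis(self):
        sizes = "clone_id,T,X1,X2\nA,5,4,3\n"
        parents = "clone_id,parent_id\nA,\n"
        h = mk.read_wide(io.StringIO(sizes), io.StringIO(parents))
        assert np.array_equal(h.times, [0.0, 1.0, 2.0])
        assert h.time_labels == ["T", "X1", "X2"]

    def test_minimal_one_by_one(self):
        h = mk.read_wide(io.StringIO("clone_id,0\nA,5\n"), io.StringIO("clone_id,parent_id\nA,\n"))
        assert h.sizes.shape == (1, 1)

    def test_clone_missing_from_parent_mapping(self):
        with pytest.raises(ValidationError, match="B"):
            mk.read_wide(
                io.StringIO("clone_id,0\nA,5\nB,1\n"),
                io.StringIO("clone_id,parent_id\nA,\n"),
            )

    def test_embedded_parent_column(self):
        h = mk.read_wide(io.StringIO("clone_id,parent_id,0,1\nA,,10,8\nB,A,0,2\n"))
        assert h.parent_of == {"A": None, "B": "A"}


class TestRoundTrips:
    def test_long_round_trip_preserves_matrix(self, two_clone_history):
        assert mk.from_long_frame(mk.to_long(two_clone_history)).equals(two_clone_history)

    def test_round_trip_preserves_attributes(self, two_clone_history):
        two_clone_history.attributes["fitness"] = {"A": 1.0, "B": 1.3}
        back = mk.from_long_frame(mk.to_long(two_clone_history))
        assert back.attributes["fitness"] == {"A": 1.0, "B": 1.3}

    def test_plain_history_gives_four_columns(self, two_clone_history):
        assert list(mk.to_long(two_clone_history).columns) == [
            "clone_id", "parent_id", "time", "size",
        ]

    def test_wide_round_trip(self, two_clone_history):
        assert mk.from_wide_frame(*mk.to_wide(two_clone_history)).equals(two_clone_history)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trips_on_random_histories(self, seed):
        h = simulated(seed, n_steps=12)
        assert mk.from_long_frame(mk.to_long(h)).equals(h)
        assert mk.from_wide_frame(*mk.to_wide(h)).equals(h)

    def test_csv_file_round_trip(self, tmp_path, two_clone_history):
        path = tmp_path / "h.csv"
        mk.write_long(two_clone_history, path)
        assert mk.read_long(path).equals(two_clone_history)


class TestValidate:
    def test_cycle_reported(self):
        h = mk.CloneHistory(["A", "B"], {"A": "B", "B": "A"}, [0], np.zeros((2, 1)))
        [violation] = [v for v in mk.validate(h) if "cycle" in v]
        assert "A" in violation and "B" in violation

    def test_negative_size_names_clone_and_time(self, two_clone_history):
        two_clone_history.sizes[1, 1] = -2.0
        [violation] = mk.validate(two_clone_history)
        assert "'B'" in violation and "1" in violation

    def test_valid_history_yields_no_violations(self, chain_history):
        assert mk.validate(chain_history) == []

    def test_frequency_column_sum_checked(self):
        h = mk.CloneHistory(["A"], {"A": None}, [0], [[1.5]], scale=mk.FREQUENCY)
        assert any("sums to" in v for v in mk.validate(h))


class TestNormalize:
    def test_divides_by_column_totals(self):
        h = mk.CloneHistory(["A", "B"], {"A": None, "B": "A"}, [0, 1], [[10, 8], [0, 2]])
        f = mk.normalize_frequencies(h)
        assert f.scale == mk.FREQUENCY
        assert np.allclose(f.sizes, [[1.0, 0.8], [0.0, 0.2]])

    def test_zero_column_stays_zero(self):
        h = mk.CloneHistory(["A"], {"A": None}, [0, 1], [[0, 5]])
        assert np.allclose(mk.normalize_frequencies(h).sizes, [[0.0, 1.0]])

    def test_renormalizing_frequencies_is_an_error(self, two_clone_history):
        f = mk.normalize_frequencies(two_clone_history)
        with pytest.raises(ParameterError):
            mk.normalize_frequencies(f)

    def test_all_zero_history_is_degenerate(self):
        h = mk.CloneHistory(["A"], {"A": None}, [0], [[0.0]])
        with pytest.raises(DegenerateInputError):
            mk.normalize_frequencies(h)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_columns_sum_to_one(self, seed):
        f = mk.normalize_frequencies(simulated(seed, n_steps=10))
        sums = f.column_sums()
        assert np.all(np.abs(sums[sums > 0] - 1.0) < 1e-12)


class TestFilterClones:
    def make_three_clone(self):
        # max frequencies: A=1.0, B=0.25, C=0.05 (C child of B child of A)
        return mk.CloneHistory(
            ["A", "B", "C"],
            {"A": None, "B": "A", "C": "B"},
            [0, 1, 2],
            [[100.0, 75.0, 76.0], [0.0, 25.0, 20.0], [0.0, 0.0, 4.0]],
        )

    def test_merge_removes_small_clone_into_parent(self):
        h = self.make_three_clone()
        out = mk.filter_clones(h, 0.2, mode="merge")
        assert out.clone_ids == ["A", "B"]
        # C's mass folded into B; column totals conserved exactly
        assert np.allclose(out.row("B"), [0.0, 25.0, 24.0])
        assert np.allclose(out.column_sums(), h.column_sums())

    def test_drop_discards_mass(self):
        out = mk.filter_clones(self.make_three_clone(), 0.2, mode="drop")
        assert out.clone_ids == ["A", "B"]
        assert np.allclose(out.row("B"), [0.0, 25.0, 20.0])

    def test_zero_threshold_removes_nothing(self):
        h = self.make_three_clone()
        assert mk.filter_clones(h, 0.0).equals(h)

    def test_full_threshold_merges_child_into_root(self):
        h = mk.CloneHistory(
            ["A", "B"], {"A": None, "B": "A"}, [0, 1], [[10.0, 6.0], [0.0, 4.0]]
        )
        out = mk.filter_clones(h, 1.0, mode="merge")
        assert out.clone_ids == ["A"]
        assert np.allclose(out.row("A"), h.column_sums())

    def test_chain_collapses_into_nearest_survivor(self):
        # both B and C below threshold: both merge into root A
        h = mk.CloneHistory(
            ["A", "B", "C"],
            {"A": None, "B": "A", "C": "B"},
            [0, 1],
            [[100.0, 90.0], [0.0, 5.0], [0.0, 5.0]],
        )
        out = mk.filter_clones(h, 0.2)
        assert out.clone_ids == ["A"]
        assert np.allclose(out.column_sums(), h.column_sums())

    def test_children_reparented_to_survivor(self):
        # B is small but its child D is large: D must become A's child
        h = mk.CloneHistory(
            ["A", "B", "D"],
            {"A": None, "B": "A", "D": "B"},
            [0, 1],
            [[100.0, 50.0], [0.0, 1.0], [0.0, 49.0]],
        )
        out = mk.filter_clones(h, 0.1)
        assert out.parent_of == {"A": None, "D": "A"}

    def test_threshold_out_of_range(self, two_clone_history):
        with pytest.raises(ParameterError):
            mk.filter_clones(two_clone_history, 1.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_merge_conserves_mass_and_keeps_forest(self, seed):
        h = simulated(seed, n_steps=15)
        out = mk.filter_clones(h, 0.2, mode="merge")
        assert np.allclose(out.column_sums(), h.column_sums(), atol=1e-9)
        assert mk.validate(out) == []
        assert set(out.roots()) == set(h.roots())
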