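"""Supply-diary construction: days of supply, shifting, truncation, counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polypharm.supply_diary import (
    CoverageSegment,
    PrescriptionRecord,
    SupplyDiary,
    build_diary,
    build_segments,
    covered_days_in,
    days_supply,
    truncate,
)

from conftest import ATC_CHOICES, DDD_CHOICES, random_patient_fills
from oracles import diary_covered_sets


def segments_covered(diary: SupplyDiary) -> dict[str, set[int]]:
    return {
        atc4: {d for s in segs for d in range(s.start_day, s.end_day)}
        for atc4, segs in diary.segments.items()
    }


class TestDaysSupply:
    @pytest.mark.parametrize(
        "n_packages, ddd, expected",
        [
            (2, 28.0, 56),   # whole number of DDD-days
            (1, 0.4, 1),     # any dispensed amount covers at least one day
            (3, 16.5, 50),   # 49.5 rounds half-up
            (1, 30.0, 30),
            (2, 45.25, 91),  # 90.5 rounds half-up
        ],
    )
    def test_round_half_up_default(self, n_packages, ddd, expected):
        assert days_supply(n_packages, ddd) == expected

    @pytest.mark.parametrize(
        "mode, expected", [("round", 50), ("floor", 49), ("ceil", 50)]
    )
    def test_rounding_modes(self, mode, expected):
        assert days_supply(3, 16.5, rounding=mode) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            days_supply(0, 28.0)
        with pytest.raises(ValueError):
            days_supply(1, -1.0)
        with pytest.raises(ValueError):
            days_supply(1, 28.0, rounding="banker")


class TestBuildDiary:
    def test_overlapping_same_class_fills_abut(self):
        """An early refill is shifted to start the day after prior coverage."""
        recs = [
            PrescriptionRecord("p", 0, "C10AA05", 1, 30.0, 0),
            PrescriptionRecord("p", 20, "C10AA05", 1, 30.0, 1),
        ]
        d = build_diary(recs)
        assert [(s.start_day, s.end_day) for s in d.segments["C10AA"]] == [
            (0, 30),
            (30, 60),
        ]

    def test_interchangeability_is_within_class_only(self):
        """Same-day fills of different classes both start at dispensing."""
        recs = [
            PrescriptionRecord("p", 10, "C10AA05", 1, 30.0, 0),
            PrescriptionRecord("p", 10, "A02BC01", 1, 30.0, 1),
        ]
        d = build_diary(recs)
        assert d.segments["C10AA"][0].start_day == 10
        assert d.segments["A02BC"][0].start_day == 10

    def test_same_day_same_class_fills_queue_by_record_id(self):
        recs = [
            PrescriptionRecord("p", 5, "C10AA05", 1, 10.0, 1),
            PrescriptionRecord("p", 5, "C10AA07", 1, 10.0, 0),
        ]
        d = build_diary(recs)
        segs = d.segments["C10AA"]
        assert [(s.start_day, s.end_day) for s in segs] == [(5, 15), (15, 25)]
        assert segs[0].source_record_ids == (0,)

    def test_mixed_patient_ids_rejected(self):
        recs = [
            PrescriptionRecord("p1", 0, "C10AA05", 1, 30.0, 0),
            PrescriptionRecord("p2", 0, "C10AA05", 1, 30.0, 1),
        ]
        with pytest.raises(ValueError, match="multiple patients"):
            build_diary(recs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_diary([])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    fills=st.lists(
        st.tuples(
            st.integers(-60, 364),
            st.sampled_from(ATC_CHOICES),
            st.integers(1, 3),
            st.sampled_from(DDD_CHOICES),
        ),
        min_size=1,
        max_size=20,
    )
)
def test_diary_properties(fills):
    """Conservation, non-overlap, order-invariance, oracle equivalence."""
    recs = [
        PrescriptionRecord("p", day, atc, n, ddd, i)
        for i, (day, atc, n, ddd) in enumerate(fills)
    ]
    diary = build_diary(recs)

    # conservation: per class, total segment length equals total days supply
    for atc4, segs in diary.segments.items():
        expected = sum(
            days_supply(r.n_packages, r.ddd_per_package)
            for r in recs
            if r.atc4 == atc4
        )
        assert sum(s.n_days for s in segs) == expected

    # non-overlap and sortedness within class
    for segs in diary.segments.values():
        for prev, nxt in zip(segs, segs[1:]):
            assert prev.end_day <= nxt.start_day

    # permuting input order (record_id preserved) yields the identical diary
    rng = np.random.default_rng(0)
    shuffled = [recs[i] for i in rng.permutation(len(recs))]
    assert build_diary(shuffled) == diary

    # covered-day sets equal the banked day-by-day consumption oracle
    assert segments_covered(diary) == diary_covered_sets(recs)


def test_shift_free_degenerate_equals_naive_intervals():
    """Without same-class overlap, each fill keeps its naive interval."""
    recs = [
        PrescriptionRecord("p", 0, "C10AA05", 1, 30.0, 0),
        PrescriptionRecord("p", 40, "C10AA05", 1, 30.0, 1),
        PrescriptionRecord("p", 100, "A02BC01", 1, 28.0, 2),
    ]
    d = build_diary(recs)
    assert [(s.start_day, s.end_day) for s in d.segments["C10AA"]] == [
        (0, 30),
        (40, 70),
    ]
    assert [(s.start_day, s.end_day) for s in d.segments["A02BC"]] == [(100, 128)]


def test_vectorised_segments_match_per_patient_diary():
    """Table-level construction agrees with the object API, per patient."""
    rng = np.random.default_rng(42)
    frames = []
    diaries = {}
    for p in range(30):
        pid = f"p{p:03d}"
        recs = random_patient_fills(rng, patient_id=pid)
        diaries[pid] = build_diary(recs)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "dispense_day": [r.dispense_day for r in recs],
                    "atc_code": [r.atc_code for r in recs],
                    "n_packages": [r.n_packages for r in recs],
                    "ddd_per_package": [r.ddd_per_package for r in recs],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    segs = build_segments(table)
    for pid, diary in diaries.items():
        got = {
            atc4: sorted(
                (r.start_day, r.end_day)
                for r in segs[(segs.patient_id == pid) & (segs.atc4 == atc4)]
                .itertuples()
            )
            for atc4 in diary.segments
        }
        want = {
            atc4: [(s.start_day, s.end_day) for s in seglist]
            for atc4, seglist in diary.segments.items()
        }
        assert got == want


class TestTruncate:
    def test_clips_partial_segment(self):
        d = SupplyDiary("p", {"C10AA": [CoverageSegment("C10AA", -10, 5)]})
        t = truncate(d, 0, 365)
        assert [(s.start_day, s.end_day) for s in t.segments["C10AA"]] == [(0, 5)]

    def test_drops_lookback_only_segment(self):
        d = SupplyDiary("p", {"C10AA": [CoverageSegment("C10AA", -40, -10)]})
        assert truncate(d, 0, 365).segments == {}

    def test_lookback_fill_carries_into_year(self):
        """A late-December fill with 60-day supply reaches the new year."""
        recs = [PrescriptionRecord("p", -21, "C10AA05", 2, 30.0, 0)]  # 10 Dec
        t = truncate(build_diary(recs), 0, 365)
        assert covered_days_in(t, "C10AA", (0, 365)) == 60 - 21

    def test_inverted_period_rejected(self):
        d = SupplyDiary("p", {})
        with pytest.raises(ValueError):
            truncate(d, 10, 0)


class TestCoveredDaysIn:
    def test_month_straddling_segment(self):
        # 25 Jan - 5 Feb inclusive: day indices 24..35
        d = SupplyDiary("p", {"C10AA": [CoverageSegment("C10AA", 24, 36)]})
        assert covered_days_in(d, "C10AA", (0, 31)) == 7    # January
        assert covered_days_in(d, "C10AA", (31, 59)) == 5   # February
        assert covered_days_in(d, "C10AA", (59, 90)) == 0   # March

    def test_unknown_class_returns_zero(self):
        d = SupplyDiary("p", {})
        assert covered_days_in(d, "C10AA", (0, 365)) == 0

    def test_full_year_segment(self):
        d = SupplyDiary("p", {"C10AA": [CoverageSegment("C10AA", -5, 400)]})
        assert covered_days_in(d, "C10AA", (0, 365)) == 365
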