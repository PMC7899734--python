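"""Fixation intake, dynamic-AOI geometry, and hit testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnetgaze import (
    FixationRecord,
    TargetTrajectories,
    TimeWindow,
    aoi_regions_at,
    build_raw_sequence,
    format_sequence,
    hit_test,
    read_fixations,
)
from dnetgaze.errors import FormatError, IntegrityError
from dnetgaze.ingest import Box, write_fixations


def make_tracks(rows):
    return TargetTrajectories(
        pd.DataFrame(rows, columns=["time_s", "label", "icon_x", "icon_y", "block_x", "block_y", "block_w", "block_h"])
    )


@pytest.fixture()
def two_static_targets():
    # A around x~100, B around x~160; their margin-0 boxes overlap in x in [150, 190]
    rows = []
    for t in (0.0, 10.0, 20.0):
        rows.append((t, "A", 100.0, 100.0, 110.0, 110.0, 80.0, 40.0))
        rows.append((t, "B", 160.0, 120.0, 170.0, 130.0, 80.0, 40.0))
    return make_tracks(rows)


class TestReadFixations:
    def test_threshold_filters_and_sorts(self, tmp_path):
        path = tmp_path / "fix.csv"
        path.write_text(
            "onset_s,duration_ms,x_px,y_px\n"
            "5.0,150,10,10\n"
            "1.0,120,20,20\n"
            "3.0,80,30,30\n"
        )
        records = read_fixations(path, threshold_ms=100)
        assert [r.onset for r in records] == [1.0, 5.0]
        assert all(r.duration >= 100 for r in records)

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "fix.csv"
        path.write_text("onset_s,duration_ms,x_px,y_px\n")
        assert read_fixations(path) == []

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "fix.csv"
        path.write_text("onset_s,duration_ms,x_px\n1,120,5\n")
        with pytest.raises(FormatError, match="y_px"):
            read_fixations(path)

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "fix.csv"
        path.write_text("onset_s,duration_ms,x_px,y_px\n1,120,5,6\n2,oops,7,8\n")
        with pytest.raises(FormatError, match="row 1"):
            read_fixations(path)

    def test_write_read_round_trip(self, tmp_path):
        fixations = [FixationRecord(1.0, 150.0, 3.0, 4.0), FixationRecord(2.5, 210.0, 8.0, 9.0)]
        path = tmp_path / "fix.csv"
        write_fixations(path, fixations)
        assert read_fixations(path) == fixations


class TestTargetTracks:
    def test_grouped_and_time_sorted(self, two_static_targets):
        assert two_static_targets.labels == ["A", "B"]
        assert two_static_targets.presence_span("A") == (0.0, 20.0)

    def test_no_region_outside_presence_span(self):
        tracks = make_tracks([(60.0, "A", 0, 0, 5, 5, 10, 10), (300.0, "A", 50, 50, 55, 55, 10, 10)])
        assert tracks.geometry_at("A", 30.0) is None
        assert tracks.geometry_at("A", 150.0) is not None

    def test_duplicate_label_time_rejected(self):
        with pytest.raises(IntegrityError):
            make_tracks([(0.0, "A", 0, 0, 5, 5, 10, 10), (0.0, "A", 1, 1, 5, 5, 10, 10)])

    def test_negative_geometry_rejected(self):
        with pytest.raises(FormatError):
            make_tracks([(0.0, "A", 0, 0, 5, 5, -10, 10)])


class TestAOIRegions:
    def test_box_spans_icon_and_block(self):
        tracks = make_tracks([(0.0, "A", 100.0, 100.0, 110.0, 110.0, 80.0, 40.0)])
        [(label, box)] = aoi_regions_at(tracks, 0.0, margin_px=0)
        assert label == "A"
        assert (box.x0, box.y0, box.x1, box.y1) == (100.0, 100.0, 190.0, 150.0)

    def test_margin_inflates_every_side_exactly(self, two_static_targets):
        [base, _] = aoi_regions_at(two_static_targets, 0.0, margin_px=0)
        [inflated, _] = aoi_regions_at(two_static_targets, 0.0, margin_px=30)
        b, i = base[1], inflated[1]
        assert (i.x0, i.y0, i.x1, i.y1) == (b.x0 - 30, b.y0 - 30, b.x1 + 30, b.y1 + 30)

    def test_overlapping_targets_have_intersecting_boxes(self, two_static_targets):
        regions = dict(aoi_regions_at(two_static_targets, 5.0, margin_px=0))
        assert regions["A"].intersects(regions["B"])

    def test_geometry_interpolates_between_samples(self):
        tracks = make_tracks(
            [(0.0, "A", 0.0, 0.0, 10.0, 10.0, 20.0, 10.0), (10.0, "A", 100.0, 0.0, 110.0, 10.0, 20.0, 10.0)]
        )
        [(_, box)] = aoi_regions_at(tracks, 5.0, margin_px=0)
        assert box.x0 == pytest.approx(50.0)

    def test_outside_scenario_span_yields_empty(self, two_static_targets):
        assert aoi_regions_at(two_static_targets, 99.0) == []


class TestHitTest:
    def test_single_containment(self, two_static_targets):
        regions = aoi_regions_at(two_static_targets, 0.0)
        state = hit_test(FixationRecord(0.0, 150, 105.0, 105.0), regions)
        assert state.canonical == "A"

    def test_intersection_yields_overlap_state(self, two_static_targets):
        regions = aoi_regions_at(two_static_targets, 0.0)
        state = hit_test(FixationRecord(0.0, 150, 170.0, 130.0), regions)
        assert state.canonical == "(A;B)"

    def test_outside_all_regions_is_none(self, two_static_targets):
        regions = aoi_regions_at(two_static_targets, 0.0)
        assert hit_test(FixationRecord(0.0, 150, 900.0, 900.0), regions) is None

    def test_independent_of_region_order(self, two_static_targets):
        regions = aoi_regions_at(two_static_targets, 0.0)
        fix = FixationRecord(0.0, 150, 170.0, 130.0)
        assert hit_test(fix, regions) == hit_test(fix, list(reversed(regions)))

    @given(st.floats(0, 50))
    def test_shrinking_margin_never_adds_a_hit(self, margin):
        tracks = make_tracks([(0.0, "A", 100.0, 100.0, 110.0, 110.0, 80.0, 40.0)])
        fix = FixationRecord(0.0, 150, 95.0, 95.0)
        hit_small = hit_test(fix, aoi_regions_at(tracks, 0.0, margin_px=margin))
        hit_large = hit_test(fix, aoi_regions_at(tracks, 0.0, margin_px=margin + 10))
        assert hit_small is None or hit_large is not None


class TestBuildRawSequence:
    def fixations_at(self, points, t0=0.0, step=1.0, duration=150.0):
        return [FixationRecord(t0 + i * step, duration, x, y) for i, (x, y) in enumerate(points)]

    def test_repeat_fixations_stay_raw(self, two_static_targets):
        fixations = self.fixations_at([(105, 105)] * 5)
        seq, counts, _ = build_raw_sequence(fixations, two_static_targets, TimeWindow(0, 10))
        assert format_sequence(seq) == "AAAAA"
        assert counts == {seq.states[0]: 5}

    def test_mixed_targets_in_time_order(self, two_static_targets):
        pts = [(105, 105), (105, 105), (240, 130), (240, 130), (900, 900)]
        seq, counts, dwell = build_raw_sequence(
            self.fixations_at(pts), two_static_targets, TimeWindow(0, 10)
        )
        assert format_sequence(seq) == "AABB"  # off-AOI fixation dropped

    def test_window_end_excluded(self, two_static_targets):
        fixations = [FixationRecord(0.0, 150, 105, 105), FixationRecord(5.0, 150, 105, 105)]
        seq, _, _ = build_raw_sequence(fixations, two_static_targets, TimeWindow(0, 5))
        assert len(seq) == 1

    def test_dwell_totals_conserve_hit_durations(self, two_static_targets):
        pts = [(105, 105), (240, 130), (170, 130), (900, 900)]
        fixations = self.fixations_at(pts, duration=200.0)
        _, _, dwell = build_raw_sequence(fixations, two_static_targets, TimeWindow(0, 10))
        hits = 3  # the (900,900) fixation misses every region
        assert sum(dwell.values()) == pytest.approx(hits * 200.0)

    def test_empty_window_warns_and_returns_empty(self, two_static_targets, caplog):
        seq, counts, dwell = build_raw_sequence([], two_static_targets, TimeWindow(0, 10))
        assert len(seq) == 0 and counts == {} and dwell == {}


class TestBox:
    def test_contains_is_inclusive(self):
        box = Box(0, 0, 10, 10)
        assert box.contains(0, 10) and box.contains(10, 0)
        assert not box.contains(10.1, 5)

    def test_intersects_symmetric(self):
        a, b = Box(0, 0, 10, 10), Box(5, 5, 20, 20)
        c = Box(11, 11, 12, 12)
        assert a.intersects(b) and b.intersects(a)
        assert not a.intersects(c)
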