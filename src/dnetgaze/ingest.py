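"""Fixation and target-trajectory intake, dynamic-AOI geometry, hit testing.

Fixations arrive as already-detected events (onset, duration, display x/y);
targets arrive as per-timestamp samples of each labelled target's icon
position and data-block rectangle.  Each target's AOI region at a query
time is the axis-aligned bounding box covering the icon and the data block
at that time (geometry linearly interpolated between samples), inflated by
a configurable margin that absorbs eye-tracker visual-angle error.

A fixation is resolved to the set of ALL labels whose region contains its
display position: one label gives a single state, several give an overlap
state like ``(A;B)``, and none means the fixation is ignored for sequence
building (but counted in logs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .sequence import AOISequence, TimeWindow
from .states import AOIState

__all__ = [
    "FixationRecord",
    "Box",
    "TargetTrajectories",
    "read_fixations",
    "write_fixations",
    "read_target_tracks",
    "write_target_tracks",
    "aoi_regions_at",
    "hit_test",
    "build_raw_sequence",
]

log = logging.getLogger(__name__)

FIXATION_COLUMNS = ["onset_s", "duration_ms", "x_px", "y_px"]
TRACK_COLUMNS = ["time_s", "label", "icon_x", "icon_y", "block_x", "block_y", "block_w", "block_h"]

DEFAULT_FIXATION_THRESHOLD_MS = 100.0


@dataclass(frozen=True)
class FixationRecord:
    """One detected fixation: onset (s from scenario start), duration (ms), display x/y (px)."""

    onset: float
    duration: float
    x: float
    y: float


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle [x0,x1] x [y0,y1] in display pixels."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def intersects(self, other: "Box") -> bool:
        return not (self.x1 < other.x0 or other.x1 < self.x0 or self.y1 < other.y0 or other.y1 < self.y0)

    def inflate(self, margin: float) -> "Box":
        return Box(self.x0 - margin, self.y0 - margin, self.x1 + margin, self.y1 + margin)


class TargetTrajectories:
    """Per-label, time-sorted samples of target geometry.

    A label is *present* only between its first and last sample time; queries
    outside that span yield no region for it.  Geometry between samples is
    linearly interpolated.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TRACK_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"trajectory data missing columns: {missing}")
        if frame.duplicated(subset=["label", "time_s"]).any():
            dupes = frame[frame.duplicated(subset=["label", "time_s"], keep=False)]
            raise IntegrityError(
                f"duplicate (label, time) trajectory rows: {sorted(set(zip(dupes['label'], dupes['time_s'])))[:5]}"
            )
        if (frame[["block_w", "block_h"]].to_numpy() < 0).any():
            raise FormatError("negative data-block geometry in trajectory data")
        self._frame = frame.sort_values(["label", "time_s"], kind="mergesort").reset_index(drop=True)
        self._by_label: dict[str, pd.DataFrame] = {
            str(label): grp.reset_index(drop=True) for label, grp in self._frame.groupby("label", sort=True)
        }

    @property
    def labels(self) -> list[str]:
        return list(self._by_label)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def presence_span(self, label: str) -> tuple[float, float]:
        grp = self._by_label[label]
        return float(grp["time_s"].iloc[0]), float(grp["time_s"].iloc[-1])

    def present_at(self, t: float) -> list[str]:
        return [lab for lab in self._by_label if self.presence_span(lab)[0] <= t <= self.presence_span(lab)[1]]

    @property
    def time_span(self) -> tuple[float, float]:
        return float(self._frame["time_s"].min()), float(self._frame["time_s"].max())

    def geometry_at(self, label: str, t: float) -> dict[str, float] | None:
        """Linearly interpolated geometry sample for ``label`` at time ``t``, or None if absent."""
        grp = self._by_label.get(label)
        if grp is None:
            return None
        times = grp["time_s"].to_numpy(dtype=float)
        if t < times[0] or t > times[-1]:
            return None
        out = {}
        for col in ("icon_x", "icon_y", "block_x", "block_y", "block_w", "block_h"):
            out[col] = float(np.interp(t, times, grp[col].to_numpy(dtype=float)))
        return out


def read_fixations(path: str | Path, threshold_ms: float = DEFAULT_FIXATION_THRESHOLD_MS) -> list[FixationRecord]:
    """Read a fixation CSV (onset_s,duration_ms,x_px,y_px), sort by onset,
    and drop fixations shorter than ``threshold_ms``."""
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise FormatError(f"cannot parse fixation file {path}: {exc}") from exc
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fixation file {path} missing columns: {missing}")
    for col in FIXATION_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise FormatError(f"non-numeric value in column {col!r} at row {int(bad.idxmax())}")
        df[col] = coerced
    if df.empty:
        log.warning("fixation file %s has an empty data section", path)
        return []
    n_before = len(df)
    df = df[df["duration_ms"] >= threshold_ms]
    dropped = n_before - len(df)
    if dropped:
        log.info("dropped %d fixations below the %.0f ms threshold", dropped, threshold_ms)
    df = df.sort_values("onset_s", kind="mergesort")
    return [
        FixationRecord(onset=float(r.onset_s), duration=float(r.duration_ms), x=float(r.x_px), y=float(r.y_px))
        for r in df.itertuples()
    ]


def write_fixations(path: str | Path, fixations: Iterable[FixationRecord]) -> None:
    rows = [(f.onset, f.duration, f.x, f.y) for f in fixations]
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, index=False)


def read_target_tracks(path: str | Path) -> TargetTrajectories:
    """Read a trajectory CSV (time_s,label,icon_x,...,block_h) grouped by label."""
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise FormatError(f"cannot parse trajectory file {path}: {exc}") from exc
    return TargetTrajectories(df)


def write_target_tracks(path: str | Path, tracks: TargetTrajectories) -> None:
    tracks.frame[TRACK_COLUMNS].to_csv(path, index=False)


def _region_from_geometry(geo: Mapping[str, float], margin_px: float) -> Box:
    xs = [geo["icon_x"], geo["block_x"], geo["block_x"] + geo["block_w"]]
    ys = [geo["icon_y"], geo["block_y"], geo["block_y"] + geo["block_h"]]
    return Box(min(xs), min(ys), max(xs), max(ys)).inflate(margin_px)


def aoi_regions_at(tracks: TargetTrajectories, t: float, margin_px: float = 0.0) -> list[tuple[str, Box]]:
    """AOI bounding boxes of every target present at time ``t``.

    Each region is the axis-aligned box spanning the icon point and the
    data-block rectangle, inflated by ``margin_px`` on all sides.
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    t0, t1 = tracks.time_span if tracks.labels else (0.0, 0.0)
    if not tracks.labels or t < t0 or t > t1:
        log.warning("query time %.3f s is outside the scenario span [%.3f, %.3f]", t, t0, t1)
        return []
    regions = []
    for label in tracks.labels:
        geo = tracks.geometry_at(label, t)
        if geo is not None:
            regions.append((label, _region_from_geometry(geo, margin_px)))
    return regions


def hit_test(fix: FixationRecord, regions: Iterable[tuple[str, Box]]) -> AOIState | None:
    """Resolve a fixation to the state of ALL regions containing it, or None."""
    members = [label for label, box in regions if box.contains(fix.x, fix.y)]
    if not members:
        return None
    return AOIState(members)


def build_raw_sequence(
    fixations: Iterable[FixationRecord],
    tracks: TargetTrajectories,
    window: TimeWindow,
    margin_px: float = 0.0,
) -> tuple[AOISequence, dict[AOIState, int], dict[AOIState, float]]:
    """Map fixations with onset in [window.start, window.end) to AOI states.

    Returns the raw (uncollapsed) sequence plus per-state fixation counts and
    summed dwell durations (ms).  Fixations hitting no AOI are skipped but
    logged; dwell totals cover hit fixations only, so their sum equals the
    total duration of hits (conservation).
    """
    in_window = sorted((f for f in fixations if window.contains(f.onset)), key=lambda f: f.onset)
    states: list[AOIState] = []
    counts: dict[AOIState, int] = {}
    dwell: dict[AOIState, float] = {}
    n_missed = 0
    for fix in in_window:
        state = hit_test(fix, aoi_regions_at(tracks, fix.onset, margin_px))
        if state is None:
            n_missed += 1
            continue
        states.append(state)
        counts[state] = counts.get(state, 0) + 1
        dwell[state] = dwell.get(state, 0.0) + fix.duration
    if not in_window:
        log.warning("no fixations fall in window %d [%s, %s)", window.index, window.start, window.end)
    if n_missed:
        log.info("window %d: %d fixations hit no AOI and were ignored", window.index, n_missed)
    return AOISequence(tuple(states), window=window, collapsed=False), counts, dwell
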