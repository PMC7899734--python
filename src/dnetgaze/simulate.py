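"""Synthetic enroute-like scenarios: moving labelled targets and Markov scanpaths.

The generator emulates the shape of a radar monitoring task: a few dozen
labelled targets (aircraft icon plus attached data block) that enter and
leave a large square display, drift with constant velocity, and can be
forced to overlap pairwise during declared episodes.  On top of the target
layer, a first-order Markov scanpath model emits fixations: the next
fixated target is drawn from a transition matrix, dwell durations are
log-normal (truncated below at the fixation-detection threshold), and the
fixation point lands at the target's region center plus Gaussian jitter,
with an optional rate of off-AOI fixations placed outside every region.

Everything is deterministic given the spec/model seeds, and the writers in
:mod:`dnetgaze.ingest` round-trip the generated data through the same file
formats the ingest layer reads — no external dataset is required anywhere.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import FixationRecord, TargetTrajectories, aoi_regions_at

__all__ = ["ScenarioSpec", "ScanpathModel", "default_labels", "simulate_targets", "simulate_scanpath"]

log = logging.getLogger(__name__)


def default_labels(n: int) -> list[str]:
    """Target labels in assignment order: A..Z then a..z."""
    alphabet = string.ascii_uppercase + string.ascii_lowercase
    if n > len(alphabet):
        raise ValueError(f"at most {len(alphabet)} single-letter labels available")
    return list(alphabet[:n])


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic target scenario.

    Defaults emulate a 20-minute enroute picture on a 2048 x 2048 px display
    with 39 unique targets of which roughly twenty are present in any frame,
    sampled at the 1 s scenario update rate.
    """

    display: tuple[float, float] = (2048.0, 2048.0)
    duration_s: float = 1200.0
    n_targets: int = 39
    sample_dt: float = 1.0
    speed_px_s: tuple[float, float] = (2.0, 12.0)
    block_offset: tuple[float, float] = (18.0, 18.0)
    block_size: tuple[float, float] = (90.0, 40.0)
    overlap_episodes: tuple[tuple[str, str, float, float], ...] = ()
    full_presence: bool = False  # keep every target on-display for the whole run
    presence: dict | None = None  # explicit {label: (entry_s, exit_s)}; others randomized
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("need at least one target")
        if self.duration_s <= 0 or self.sample_dt <= 0:
            raise ValueError("duration and sample step must be positive")


@dataclass(frozen=True)
class ScanpathModel:
    """First-order Markov model over planned fixation targets."""

    labels: tuple[str, ...]
    transition: np.ndarray  # row-stochastic (n, n)
    dwell_median_ms: float = 300.0
    dwell_sigma_log: float = 0.5
    dwell_floor_ms: float = 100.0  # fixation-detection threshold; dwells truncated below it
    jitter_px: float = 0.0
    off_aoi_rate: float = 0.0
    saccade_gap_ms: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        trans = np.asarray(self.transition, dtype=float)
        n = len(self.labels)
        if trans.shape != (n, n):
            raise ValueError(f"transition matrix shape {trans.shape} does not match {n} labels")
        if not np.allclose(trans.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if (trans < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not 0.0 <= self.off_aoi_rate <= 1.0:
            raise ValueError("off_aoi_rate must lie in [0, 1]")
        object.__setattr__(self, "transition", trans)
        object.__setattr__(self, "labels", tuple(self.labels))


def _presence_spans(spec: ScenarioSpec, rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    explicit = dict(spec.presence or {})
    spans: dict[str, tuple[float, float]] = {}
    for label in default_labels(spec.n_targets):
        if label in explicit:
            entry, exit_ = map(float, explicit[label])
            if not 0.0 <= entry < exit_ <= spec.duration_s:
                raise ValueError(f"presence span for {label!r} must satisfy 0 <= entry < exit <= duration")
            spans[label] = (entry, exit_)
        elif spec.full_presence:
            spans[label] = (0.0, spec.duration_s)
        else:
            entry = float(rng.uniform(0.0, 0.5 * spec.duration_s))
            length = float(rng.uniform(0.4, 0.6) * spec.duration_s)
            spans[label] = (entry, min(spec.duration_s, entry + length))
    for a, b, _, _ in spec.overlap_episodes:
        for lab in (a, b):
            if lab not in spans:
                raise ValueError(f"overlap episode names unknown target {lab!r}")
    return spans


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a free linear motion back into [lo, hi] (billiard reflection)."""
    span = hi - lo
    phase = np.mod(values - lo, 2 * span)
    return lo + np.where(phase > span, 2 * span - phase, phase)


def simulate_targets(spec: ScenarioSpec) -> TargetTrajectories:
    """Generate per-second target trajectories; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    spans = _presence_spans(spec, rng)
    w, h = spec.display
    pad = 60.0
    rows = []
    positions: dict[str, dict[float, tuple[float, float]]] = {}
    for label in default_labels(spec.n_targets):
        entry, exit_ = spans[label]
        x0, y0 = rng.uniform(pad, w - pad), rng.uniform(pad, h - pad)
        speed = rng.uniform(*spec.speed_px_s)
        heading = rng.uniform(0.0, 2.0 * math.pi)
        vx, vy = speed * math.cos(heading), speed * math.sin(heading)
        times = np.arange(entry, exit_ + 1e-9, spec.sample_dt)
        if times[-1] < exit_ - 1e-9:
            times = np.append(times, exit_)
        xs = _reflect(x0 + vx * (times - entry), pad, w - pad)
        ys = _reflect(y0 + vy * (times - entry), pad, h - pad)
        positions[label] = {float(t): (float(x), float(y)) for t, x, y in zip(times, xs, ys)}

    for a, b, t0, t1 in spec.overlap_episodes:
        if not (spans[a][0] <= t0 and t1 <= spans[a][1] and spans[b][0] <= t0 and t1 <= spans[b][1]):
            raise ValueError(f"overlap episode ({a},{b}) in [{t0},{t1}] outside co-presence spans")
        if t1 <= t0:
            raise ValueError("overlap episode span must have positive length")
        # park b right next to a for the episode so their AOI boxes intersect
        for t in list(positions[b]):
            if t0 <= t <= t1:
                a_t = min(positions[a], key=lambda ta: abs(ta - t))
                ax, ay = positions[a][a_t]
                positions[b][t] = (ax + 10.0, ay + 10.0)

    dx, dy = spec.block_offset
    bw, bh = spec.block_size
    for label, samples in positions.items():
        for t, (x, y) in sorted(samples.items()):
            rows.append((t, label, x, y, x + dx, y + dy, bw, bh))
    frame = pd.DataFrame(
        rows, columns=["time_s", "label", "icon_x", "icon_y", "block_x", "block_y", "block_w", "block_h"]
    )
    return TargetTrajectories(frame)


def _dwell_ms(model: ScanpathModel, rng: np.random.Generator) -> float:
    mu = math.log(model.dwell_median_ms)
    for _ in range(1000):
        d = float(rng.lognormal(mu, model.dwell_sigma_log))
        if d >= model.dwell_floor_ms:
            return d
    return model.dwell_floor_ms


def _region_center(tracks: TargetTrajectories, label: str, t: float) -> tuple[float, float] | None:
    regions = dict(aoi_regions_at(tracks, t, margin_px=0.0))
    box = regions.get(label)
    if box is None:
        return None
    return (0.5 * (box.x0 + box.x1), 0.5 * (box.y0 + box.y1))


def simulate_scanpath(
    tracks: TargetTrajectories,
    model: ScanpathModel,
    n_fixations: int = 500,
) -> list[FixationRecord]:
    """Emit ``n_fixations`` fixations from the Markov model over ``tracks``.

    The planned next target is drawn from the model's transition row; if it
    is absent from the display at emission time the draw is renormalized
    over the currently present model targets (logged).  Time wraps to the
    scenario start if the walk outruns the scenario.  Deterministic given
    ``model.seed``.
    """
    if model.transition.shape[0] == 0:
        raise ValueError("model has no targets")
    rng = np.random.default_rng(model.seed)
    t_start, t_end = tracks.time_span
    label_idx = {lab: i for i, lab in enumerate(model.labels)}
    t = t_start
    current: int | None = None
    fixations: list[FixationRecord] = []
    n_resampled = 0
    while len(fixations) < n_fixations:
        if t > t_end:
            t = t_start  # wrap so long walks keep a populated display
            current = None
        present = [lab for lab in model.labels if lab in tracks.present_at(t)]
        if not present:
            t += 1.0
            continue
        if current is None:
            choice = present[int(rng.integers(len(present)))]
        else:
            row = model.transition[current].copy()
            planned = model.labels[int(rng.choice(len(model.labels), p=row))]
            if planned in present:
                choice = planned
            else:
                n_resampled += 1
                mask = np.array([lab in present for lab in model.labels], dtype=float)
                masked = row * mask
                if masked.sum() <= 0:
                    masked = mask
                masked = masked / masked.sum()
                choice = model.labels[int(rng.choice(len(model.labels), p=masked))]
        dwell = _dwell_ms(model, rng)
        center = _region_center(tracks, choice, t)
        if center is None:  # present_at is span-based; geometry can still be missing at edges
            t += 1.0
            continue
        x, y = center
        if model.jitter_px > 0:
            x += float(rng.normal(0.0, model.jitter_px))
            y += float(rng.normal(0.0, model.jitter_px))
        if model.off_aoi_rate > 0 and rng.uniform() < model.off_aoi_rate:
            point = _off_aoi_point(tracks, t, rng)
            if point is not None:
                x, y = point
        fixations.append(FixationRecord(onset=t, duration=dwell, x=x, y=y))
        current = label_idx[choice]
        t += (dwell + model.saccade_gap_ms) / 1000.0
    if n_resampled:
        log.info("%d planned targets were absent at emission time and were resampled", n_resampled)
    return fixations


def _off_aoi_point(tracks: TargetTrajectories, t: float, rng: np.random.Generator) -> tuple[float, float] | None:
    regions = aoi_regions_at(tracks, t, margin_px=0.0)
    xs = [b.x1 for _, b in regions] + [b.x0 for _, b in regions]
    ys = [b.y1 for _, b in regions] + [b.y0 for _, b in regions]
    hi_x, hi_y = (max(xs) + 500.0, max(ys) + 500.0) if regions else (2048.0, 2048.0)
    for _ in range(100):
        x, y = float(rng.uniform(0.0, hi_x)), float(rng.uniform(0.0, hi_y))
        if not any(box.contains(x, y) for _, box in regions):
            return (x, y)
    return None
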