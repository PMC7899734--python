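"""Run configuration and the end-to-end pipeline.

The pipeline wires the stages together: ingest fixations and target tracks,
partition the timeline, build per-interval scanpath sequences and transition
networks, compute and normalize the importance measures, and render the
three figures.  Every output is written as plain text (CSV/TSV/JSON) next to
the figures, and a manifest records versions, the seed, and all parameters
so a run can be reproduced exactly.

The AOI margin is specified as a visual angle and converted to pixels via
the viewing geometry: margin_px = tan(margin_deg) * viewing_distance_cm *
pixel_pitch_px_per_cm.  Defaults correspond to a 2048 px display spanning
19.83 inches viewed from 60 cm, with a 0.75 degree margin absorbing typical
eye-tracker accuracy error.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ingest import build_raw_sequence, read_fixations, read_target_tracks
from .measures import measure_table
from .network import DynamicNetwork, assemble_dnet, build_interval_network, build_transition_matrix, write_matrix
from .normalize import normalize_measures
from .sequence import AOISequence, collapse, partition_time, read_sequence_file, write_sequence_file
from .viz import grid_positions, order_states, render_barplot, render_dnet, render_dotplot, VisualEncoding

__all__ = ["RunConfig", "margin_pixels", "run_pipeline", "run_from_sequences", "DEFAULT_PIXEL_PITCH"]

log = logging.getLogger(__name__)

# 2048 px active area over 19.83 inches
DEFAULT_PIXEL_PITCH = 2048.0 / (19.83 * 2.54)  # ~40.7 px/cm


def margin_pixels(margin_deg: float, viewing_distance_cm: float, pixel_pitch_px_per_cm: float) -> float:
    """Convert a visual-angle margin to display pixels for the given geometry."""
    if margin_deg < 0 or viewing_distance_cm <= 0 or pixel_pitch_px_per_cm <= 0:
        raise ValueError("viewing geometry quantities must be positive (margin >= 0)")
    return math.tan(math.radians(margin_deg)) * viewing_distance_cm * pixel_pitch_px_per_cm


@dataclass
class RunConfig:
    fixations_path: str | None = None
    tracks_path: str | None = None
    out_dir: str = "dnetgaze_out"
    intervals: int = 4  # count of equal windows, or see `cuts`
    cuts: list[float] | None = None  # explicit interior boundaries (seconds), overrides `intervals`
    margin_deg: float = 0.75
    viewing_distance_cm: float = 60.0
    pixel_pitch_px_per_cm: float = DEFAULT_PIXEL_PITCH
    fixation_threshold_ms: float = 100.0
    color_bounds: str = "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixation_threshold_ms < 0:
            raise ValueError("fixation threshold must be >= 0")
        margin_pixels(self.margin_deg, self.viewing_distance_cm, self.pixel_pitch_px_per_cm)

    @property
    def margin_px(self) -> float:
        return margin_pixels(self.margin_deg, self.viewing_distance_cm, self.pixel_pitch_px_per_cm)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _networks_from_sequences(
    raw_sequences: list[AOISequence],
    fix_counts: list[dict] | None = None,
    dwell_totals: list[dict] | None = None,
) -> DynamicNetwork:
    networks = []
    for i, raw in enumerate(raw_sequences):
        collapsed = collapse(raw)
        matrix = build_transition_matrix(collapsed)
        counts = fix_counts[i] if fix_counts else {s: sum(1 for x in raw.states if x == s) for s in set(raw.states)}
        dwell = dwell_totals[i] if dwell_totals else {}
        networks.append(build_interval_network(matrix, counts, dwell, window=raw.window))
    return assemble_dnet(networks)


def _write_bundle(dnet: DynamicNetwork, raw_sequences: list[AOISequence], config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_sequence_file(out / "sequences_raw.tsv", raw_sequences)
    write_sequence_file(out / "sequences_collapsed.tsv", [collapse(s) for s in raw_sequences])
    for net in dnet:
        write_matrix(out / f"matrix_t{net.window.index}.csv", net.matrix)

    measures = measure_table(dnet)
    measures.to_csv(out / "measures.csv", index=False)
    normalized = normalize_measures(measures)
    normalized.to_csv(out / "measures_normalized.csv", index=False)

    layout = grid_positions(order_states(dnet.universe))
    enc = VisualEncoding(color_bounds=config.color_bounds)
    node_attrs, edge_attrs = render_dnet(dnet, layout, enc, out=out / "dnet.png")
    node_attrs.to_csv(out / "dnet_nodes.csv", index=False)
    edge_attrs.to_csv(out / "dnet_edges.csv", index=False)

    dot_attrs = render_dotplot(normalized, out=out / "dotplot.png")
    dot_attrs.to_csv(out / "dotplot_attrs.csv", index=False)

    first = normalized[normalized["interval"] == normalized["interval"].min()]
    bar_attrs = render_barplot(first, mode="by-measure", out=out / "barplot.png")
    bar_attrs.to_csv(out / "barplot_attrs.csv", index=False)

    import matplotlib
    import numpy

    manifest = {
        "dnetgaze": __version__,
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "matplotlib": matplotlib.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "intervals": dnet.T,
        "universe": [s.canonical for s in dnet.universe],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "dnet": dnet,
        "measures": measures,
        "normalized": normalized,
        "node_attrs": node_attrs,
        "edge_attrs": edge_attrs,
        "out_dir": out,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Full run: files -> sequences -> networks -> measures -> figures."""
    if not config.fixations_path or not config.tracks_path:
        raise ValueError("run_pipeline requires fixations_path and tracks_path")
    fixations = read_fixations(config.fixations_path, config.fixation_threshold_ms)
    tracks = read_target_tracks(config.tracks_path)
    t0, t1 = tracks.time_span
    boundaries = config.cuts if config.cuts else config.intervals
    windows = partition_time(t0, t1 + 1e-9, boundaries)

    raw_sequences, fix_counts, dwell_totals = [], [], []
    for window in windows:
        raw, counts, dwell = build_raw_sequence(fixations, tracks, window, config.margin_px)
        raw_sequences.append(raw)
        fix_counts.append(counts)
        dwell_totals.append(dwell)
    dnet = _networks_from_sequences(raw_sequences, fix_counts, dwell_totals)
    return _write_bundle(dnet, raw_sequences, config)


def run_from_sequences(path: str | Path, config: RunConfig) -> dict:
    """Start from a sequence file (one interval per line), skipping ingest."""
    raw_sequences = read_sequence_file(path)
    dnet = _networks_from_sequences(raw_sequences)
    return _write_bundle(dnet, raw_sequences, config)
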