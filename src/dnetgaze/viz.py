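"""Deterministic layout and the three renderers: network small multiples, dot plot, bar plot.

The small-multiples figure draws one node-link panel per time interval with
every AOI pinned to the same grid cell in every panel (mental-map
preservation): a reader can track one AOI's importance through time without
re-finding it.  Node area encodes the number of fixations received, node
color the total dwell duration (sequential yellow -> red), and edge width
the number of transitions, all by direct proportionality.

Grid cells fill from the bottom-left corner rightward, then upward, in the
canonical state order (single AOIs first, uppercase then lowercase; overlap
states after, by member count then lexicographically).  The column count is
the smallest integer whose square covers the state count, giving a roughly
square rectangle (six states -> 3 x 2).

Every renderer returns a plain attribute table (positions, sizes, colors,
widths) alongside the image so downstream checks never have to parse image
bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.patches import FancyArrowPatch

from .network import DynamicNetwork
from .sequence import parse_sequence
from .states import AOIState, state_sort_key

__all__ = [
    "GridLayout",
    "VisualEncoding",
    "order_states",
    "grid_positions",
    "render_dnet",
    "render_dotplot",
    "render_barplot",
]


def order_states(states: Iterable[AOIState]) -> list[AOIState]:
    """Canonical display order: singles (uppercase then lowercase, alphabetical),
    then overlap states by member count then lexicographic canonical form."""
    return sorted(set(states), key=state_sort_key)


@dataclass(frozen=True)
class GridLayout:
    """Fixed (row, column) cell per state; row 0 is the bottom row."""

    states: tuple[AOIState, ...]
    positions: dict[AOIState, tuple[int, int]]
    n_columns: int

    def xy(self, state: AOIState) -> tuple[float, float]:
        row, col = self.positions[state]
        return float(col), float(row)


def grid_positions(ordered: Sequence[AOIState]) -> GridLayout:
    """Row-major fill from the bottom-left corner rightward, then upward."""
    n = len(ordered)
    ncols = max(1, math.ceil(math.sqrt(n)))
    positions = {s: (i // ncols, i % ncols) for i, s in enumerate(ordered)}
    return GridLayout(tuple(ordered), positions, ncols)


@dataclass(frozen=True)
class VisualEncoding:
    """Proportional visual-encoding scales for the network panels."""

    node_area_per_fixation: float = 60.0  # pt^2 of node area per fixation
    min_node_area: float = 40.0  # pt^2 floor so rarely-fixated AOIs stay visible
    edge_width_per_transition: float = 0.8  # line points per transition
    colormap: str = "YlOrRd"  # sequential yellow -> red over dwell duration
    color_bounds: str = "global"  # "global": comparable across panels; "per-interval"

    def __post_init__(self) -> None:
        if self.node_area_per_fixation <= 0 or self.edge_width_per_transition <= 0 or self.min_node_area <= 0:
            raise ValueError("encoding scale factors must be positive")
        if self.color_bounds not in ("global", "per-interval"):
            raise ValueError("color_bounds must be 'global' or 'per-interval'")


def _state_from_label(label: str) -> AOIState:
    seq = parse_sequence(str(label))
    if len(seq) != 1:
        raise ValueError(f"label {label!r} is not a single AOI state")
    return seq.states[0]


def render_dnet(
    dnet: DynamicNetwork,
    layout: GridLayout | None = None,
    enc: VisualEncoding | None = None,
    out: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one panel per interval on a shared grid layout.

    Returns (node_attrs, edge_attrs) tables.  Node attributes carry the
    panel position, rendered area, and color value of every universe state
    in every interval, with ``present`` False (ghosted marker) where the
    state was not fixated in that interval.
    """
    universe = dnet.universe
    if layout is None:
        layout = grid_positions(order_states(universe))
    missing = [s for s in universe if s not in layout.positions]
    if missing:
        raise ValueError(f"layout does not cover states: {[str(s) for s in missing]}")
    enc = enc or VisualEncoding()

    dwell_values = [net.dwell_totals.get(s, 0.0) for net in dnet for s in net.states]
    global_max_dwell = max(dwell_values, default=0.0)
    cmap = colormaps[enc.colormap]

    node_rows, edge_rows = [], []
    fig, axes = plt.subplots(1, max(dnet.T, 1), figsize=(3.2 * max(dnet.T, 1), 3.2), squeeze=False)
    for ax, net in zip(axes[0], dnet):
        present = set(net.states)
        max_dwell = (
            global_max_dwell
            if enc.color_bounds == "global"
            else max((net.dwell_totals.get(s, 0.0) for s in net.states), default=0.0)
        )
        for state in universe:
            x, y = layout.xy(state)
            is_present = state in present
            fixations = int(net.fix_counts.get(state, 0))
            dwell = float(net.dwell_totals.get(state, 0.0))
            area = enc.min_node_area + enc.node_area_per_fixation * fixations if is_present else enc.min_node_area
            cval = dwell / max_dwell if max_dwell > 0 else 0.0
            color = cmap(cval) if is_present else (0.85, 0.85, 0.85, 1.0)
            ax.scatter(
                [x], [y], s=area, color=color,
                edgecolors="0.4", linewidths=0.8, alpha=1.0 if is_present else 0.35, zorder=3,
            )
            ax.annotate(state.canonical, (x, y), ha="center", va="center", fontsize=7, zorder=4)
            node_rows.append(
                {
                    "interval": net.window.index, "state": state.canonical, "x": x, "y": y,
                    "present": is_present, "area": area, "color_value": cval if is_present else float("nan"),
                    "fixations": fixations, "dwell_ms": dwell,
                }
            )
        mat = net.matrix
        for i, src in enumerate(mat.states):
            for j, dst in enumerate(mat.states):
                w = int(mat.counts[i, j])
                if w == 0:
                    continue
                width = enc.edge_width_per_transition * w
                x0, y0 = layout.xy(src)
                x1, y1 = layout.xy(dst)
                arrow = FancyArrowPatch(
                    (x0, y0), (x1, y1), arrowstyle="-|>", mutation_scale=8,
                    linewidth=width, color="0.3", alpha=0.7,
                    connectionstyle="arc3,rad=0.12", shrinkA=8, shrinkB=8, zorder=2,
                )
                ax.add_patch(arrow)
                edge_rows.append(
                    {"interval": net.window.index, "src": src.canonical, "dst": dst.canonical,
                     "weight": w, "width": width}
                )
        ax.set_title(f"interval {net.window.index}", fontsize=9)
        n_rows = (len(layout.states) - 1) // layout.n_columns + 1 if layout.states else 1
        ax.set_xlim(-0.7, layout.n_columns - 0.3)
        ax.set_ylim(-0.7, n_rows - 0.3)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    plt.close(fig)
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)


def render_dotplot(
    records: pd.DataFrame,
    out: str | Path | None = None,
    measure: str = "indegree",
    max_dot_area: float = 400.0,
) -> pd.DataFrame:
    """Dot plot of percent-normalized indegree: rows = states, columns = intervals.

    Dot area is proportional to the value; a zero value draws no dot.  Only
    the percent-normalized indegree is a share of attention, so any other
    measure is refused.
    """
    if measure != "indegree":
        raise ValueError("the dot plot renders percent-normalized indegree only")
    if "indegree_pctnorm" not in records.columns:
        raise ValueError("records lack an 'indegree_pctnorm' column; run normalize_measures first")
    states = order_states([_state_from_label(l) for l in records["aoi"].unique()])
    state_row = {s.canonical: i for i, s in enumerate(states)}
    intervals = sorted(records["interval"].unique())
    rows = []
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(intervals), 1.0 + 0.45 * len(states)))
    for rec in records.itertuples():
        value = float(rec.indegree_pctnorm)
        y = state_row[rec.aoi]
        area = max_dot_area * value
        if value > 0:
            ax.scatter([rec.interval], [y], s=area, color="tab:blue", alpha=0.8)
        rows.append({"interval": rec.interval, "state": rec.aoi, "row": y, "value": value, "area": area})
    ax.set_yticks(range(len(states)), [s.canonical for s in states])
    ax.set_xticks(intervals)
    ax.set_xlabel("time interval")
    ax.set_ylabel("AOI state")
    ax.invert_yaxis()
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    plt.close(fig)
    return pd.DataFrame(rows, columns=["interval", "state", "row", "value", "area"])


def render_barplot(
    records: pd.DataFrame,
    mode: str = "by-measure",
    measure: str = "indegree",
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Grouped bars of distance-normalized values for one interval.

    ``mode="by-participant"`` compares one measure across participants (the
    records need a ``participant`` column); ``mode="by-measure"`` compares
    the three measures for a single participant.  The y axis is fixed to
    [0, 1], the range of distance-normalized values.
    """
    if mode not in ("by-participant", "by-measure"):
        raise ValueError("mode must be 'by-participant' or 'by-measure'")
    if "interval" in records.columns and records["interval"].nunique() > 1:
        raise ValueError("bar plot compares within a single interval; filter the records first")
    states = order_states([_state_from_label(l) for l in records["aoi"].unique()])
    labels = [s.canonical for s in states]
    if mode == "by-participant":
        if "participant" not in records.columns:
            raise ValueError("mode 'by-participant' requires a 'participant' column")
        groups = sorted(records["participant"].unique())
        col = f"{measure}_distnorm"
        if col not in records.columns:
            raise ValueError(f"records lack {col!r}; run normalize_measures first")
        values = {
            g: records[records["participant"] == g].set_index("aoi")[col].reindex(labels).fillna(0.0)
            for g in groups
        }
        group_names = [str(g) for g in groups]
    else:
        cols = {m: f"{m}_distnorm" for m in ("indegree", "closeness", "betweenness")}
        missing = [c for c in cols.values() if c not in records.columns]
        if missing:
            raise ValueError(f"records lack {missing}; run normalize_measures first")
        values = {m: records.set_index("aoi")[c].reindex(labels).fillna(0.0) for m, c in cols.items()}
        group_names = list(cols)

    n_groups = len(values)
    width = 0.8 / max(n_groups, 1)
    x = np.arange(len(labels))
    rows = []
    fig, ax = plt.subplots(figsize=(1.5 + 0.5 * len(labels) * max(n_groups, 1), 3.0))
    for gi, (name, vals) in enumerate(values.items()):
        offs = x + (gi - (n_groups - 1) / 2) * width
        ax.bar(offs, vals.to_numpy(), width=width, label=str(name))
        for lab, v in zip(labels, vals.to_numpy()):
            rows.append({"state": lab, "group": str(name), "height": float(v)})
    ax.set_ylim(0.0, 1.05)
    ax.set_xticks(x, labels)
    ax.set_ylabel("distance-normalized value")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    plt.close(fig)
    return pd.DataFrame(rows, columns=["state", "group", "height"])
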