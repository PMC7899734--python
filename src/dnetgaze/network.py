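"""Per-interval transition networks and the dynamic network that strings them together.

A collapsed scanpath for one interval is turned into an m x m count matrix
w_ij: the number of adjacent ordered pairs (state_i, state_j) in the
sequence.  Collapsing guarantees a zero diagonal, and the grand total of the
matrix is len(sequence) - 1.  The matrix plus per-state fixation counts and
dwell totals make an interval network; the time-ordered list of interval
networks is the dynamic network, whose state universe is the union of the
per-interval vertex sets (never-fixated targets are absent by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import IntegrityError
from .sequence import AOISequence, TimeWindow
from .states import AOIState, state_sort_key

__all__ = [
    "TransitionMatrix",
    "IntervalNetwork",
    "DynamicNetwork",
    "build_transition_matrix",
    "build_interval_network",
    "assemble_dnet",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Square count matrix over the interval's unique states, canonical order."""

    states: tuple[AOIState, ...]
    counts: np.ndarray  # (m, m) int array, zero diagonal

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        m = len(self.states)
        if counts.shape != (m, m):
            raise ValueError(f"counts shape {counts.shape} does not match {m} states")
        if (counts < 0).any():
            raise ValueError("transition counts must be non-negative")
        if np.diagonal(counts).any():
            raise ValueError("collapsed sequences produce no self-transitions: diagonal must be 0")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def m(self) -> int:
        return len(self.states)

    def index_of(self, state: AOIState) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"state {state} not in matrix") from None

    def weight(self, src: AOIState, dst: AOIState) -> int:
        return int(self.counts[self.index_of(src), self.index_of(dst)])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [s.canonical for s in self.states]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


@dataclass(frozen=True)
class IntervalNetwork:
    """Weighted directed attention network of one time interval.

    Vertex payloads carry the raw (pre-collapse) per-state fixation counts
    and total dwell durations used by the visual encodings.
    """

    window: TimeWindow
    matrix: TransitionMatrix
    fix_counts: Mapping[AOIState, int] = field(default_factory=dict)
    dwell_totals: Mapping[AOIState, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vertex_set = set(self.matrix.states)
        for name, payload in (("fix_counts", self.fix_counts), ("dwell_totals", self.dwell_totals)):
            stray = set(payload) - vertex_set
            if stray:
                raise IntegrityError(f"{name} keys not in the vertex set: {sorted(map(str, stray))}")

    @property
    def states(self) -> tuple[AOIState, ...]:
        return self.matrix.states

    def to_networkx(self) -> nx.DiGraph:
        """Export as a networkx DiGraph with 'weight' edges and vertex payloads."""
        g = nx.DiGraph(interval=self.window.index)
        for s in self.states:
            g.add_node(s, fixations=int(self.fix_counts.get(s, 0)), dwell_ms=float(self.dwell_totals.get(s, 0.0)))
        m = self.matrix
        for i, src in enumerate(m.states):
            for j, dst in enumerate(m.states):
                w = int(m.counts[i, j])
                if w > 0:
                    g.add_edge(src, dst, weight=w)
        return g


@dataclass(frozen=True)
class DynamicNetwork:
    """Time-ordered sequence of interval networks over one shared state universe."""

    networks: tuple[IntervalNetwork, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "networks", tuple(self.networks))
        indices = [n.window.index for n in self.networks]
        if len(set(indices)) != len(indices):
            raise ValueError(f"duplicate window indices: {indices}")
        if indices != sorted(indices):
            object.__setattr__(self, "networks", tuple(sorted(self.networks, key=lambda n: n.window.index)))

    @property
    def T(self) -> int:
        return len(self.networks)

    @property
    def universe(self) -> list[AOIState]:
        """All states fixated in any interval, in canonical order."""
        seen: set[AOIState] = set()
        for net in self.networks:
            seen.update(net.states)
        return sorted(seen, key=state_sort_key)

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)


def build_transition_matrix(seq: AOISequence) -> TransitionMatrix:
    """Count adjacent ordered state pairs of a collapsed sequence.

    Raises on uncollapsed input: feeding a raw sequence would silently put
    repeat-fixation mass on the diagonal instead of modelling shifts.
    """
    if not seq.collapsed:
        raise ValueError("build_transition_matrix requires a collapsed sequence (see collapse())")
    states = sorted(seq.unique_states(), key=state_sort_key)
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=int)
    for a, b in zip(seq.states, seq.states[1:]):
        counts[index[a], index[b]] += 1
    return TransitionMatrix(tuple(states), counts)


def build_interval_network(
    matrix: TransitionMatrix,
    fix_counts: Mapping[AOIState, int] | None = None,
    dwell_totals: Mapping[AOIState, float] | None = None,
    window: TimeWindow | None = None,
) -> IntervalNetwork:
    """Wrap a transition matrix with its window and per-vertex payloads."""
    if window is None:
        window = TimeWindow(0.0, 1.0, index=1)
    return IntervalNetwork(
        window=window,
        matrix=matrix,
        fix_counts=dict(fix_counts or {}),
        dwell_totals=dict(dwell_totals or {}),
    )


def assemble_dnet(networks: Iterable[IntervalNetwork]) -> DynamicNetwork:
    """Assemble interval networks, sorted by window index, into a dynamic network."""
    return DynamicNetwork(tuple(networks))


def write_matrix(path: str | Path, matrix: TransitionMatrix) -> None:
    """Write the labelled count matrix as CSV (header row and column of state labels)."""
    matrix.to_frame().to_csv(path, index_label="from")


def read_matrix(path: str | Path) -> TransitionMatrix:
    df = pd.read_csv(path, index_col=0)
    from .sequence import parse_sequence  # local import to avoid cycle at module load

    def as_state(label: str) -> AOIState:
        seq = parse_sequence(str(label))
        if len(seq) != 1:
            raise IntegrityError(f"matrix label {label!r} is not a single state")
        return seq.states[0]

    row_states = [as_state(l) for l in df.index]
    col_states = [as_state(l) for l in df.columns]
    if row_states != col_states:
        raise IntegrityError("matrix row and column state labels differ")
    return TransitionMatrix(tuple(row_states), df.to_numpy(dtype=int))
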