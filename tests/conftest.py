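"""Shared fixtures: a worked four-interval scanpath and small network builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dnetgaze import (
    AOIState,
    IntervalNetwork,
    TimeWindow,
    TransitionMatrix,
    assemble_dnet,
    build_interval_network,
    build_transition_matrix,
    collapse,
    parse_sequence,
)

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")

# Hypothetical four-interval scanpath over seven targets (A-G) with one
# fixated overlap state (D;G); small enough to check every number by hand.
EXAMPLE_SEQUENCES = {
    1: "ABABABEBAEAEACACAEA",
    2: "EAEAEAEABABCBC(D;G)C(D;G)",
    3: "C(D;G)C(D;G)C(D;G)CEAEAEFEF",
    4: "EFEFEFCFC(D;G)C(D;G)FC(D;G)",
}


def network_from_text(text: str, index: int = 1) -> IntervalNetwork:
    """Collapsed sequence text -> interval network (no dwell payloads)."""
    raw = parse_sequence(text)
    collapsed = collapse(raw)
    counts = {s: sum(1 for x in raw.states if x == s) for s in set(raw.states)}
    return build_interval_network(
        build_transition_matrix(collapsed),
        fix_counts=counts,
        window=TimeWindow(float(index - 1), float(index), index=index),
    )


def network_from_weights(labels: str, weights: np.ndarray, index: int = 1) -> IntervalNetwork:
    """Arbitrary non-negative integer weight matrix -> interval network."""
    states = tuple(AOIState(ch) for ch in labels)
    weights = np.asarray(weights, dtype=int).copy()
    np.fill_diagonal(weights, 0)
    return build_interval_network(
        TransitionMatrix(states, weights), window=TimeWindow(float(index - 1), float(index), index=index)
    )


@pytest.fixture()
def example_networks() -> dict[int, IntervalNetwork]:
    return {t: network_from_text(seq, index=t) for t, seq in EXAMPLE_SEQUENCES.items()}


@pytest.fixture()
def example_dnet(example_networks):
    return assemble_dnet(example_networks.values())
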