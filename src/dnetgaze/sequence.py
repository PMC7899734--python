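"""Scanpath sequences, their text notation, and timeline partitioning.

A scanpath over AOIs is recorded as a time-ordered sequence of
:class:`~dnetgaze.states.AOIState`.  The *raw* sequence has one entry per
fixation that hit an AOI; the *collapsed* form merges maximal runs of the
same state into a single occurrence (``AABCC`` -> ``ABC``), so that adjacent
entries always differ and every adjacency is a genuine attention shift.

The text notation writes single AOIs as bare letters and overlap states in
parentheses with members separated by semicolons, e.g. ``C(D;G)C``.
Whitespace inside groups is tolerated on input and never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import SequenceParseError
from .states import AOIState

__all__ = [
    "TimeWindow",
    "AOISequence",
    "collapse",
    "parse_sequence",
    "format_sequence",
    "partition_time",
    "read_sequence_file",
    "write_sequence_file",
]


@dataclass(frozen=True)
class TimeWindow:
    """Half-open interval [start, end) in seconds, 1-based index in its run."""

    start: float
    end: float
    index: int = 1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TimeWindow requires start < end, got [{self.start}, {self.end})")
        if self.index < 1:
            raise ValueError("TimeWindow index is 1-based")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class AOISequence:
    """Time-ordered AOI states for one interval (raw or collapsed)."""

    states: tuple[AOIState, ...]
    window: TimeWindow | None = None
    collapsed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if self.collapsed:
            for a, b in zip(self.states, self.states[1:]):
                if a == b:
                    raise ValueError(f"sequence marked collapsed but repeats {a} adjacently")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def unique_states(self) -> set[AOIState]:
        return set(self.states)


def collapse(seq: AOISequence) -> AOISequence:
    """Merge maximal runs of identical adjacent states into one occurrence.

    Idempotent; preserves order; empty in, empty out.
    """
    out: list[AOIState] = []
    for s in seq.states:
        if not out or out[-1] != s:
            out.append(s)
    return AOISequence(tuple(out), window=seq.window, collapsed=True)


def parse_sequence(text: str, window: TimeWindow | None = None, *, line: int | None = None) -> AOISequence:
    """Parse sequence notation like ``EAEAB(D;G)C`` into an :class:`AOISequence`.

    Group members are canonicalized (``(G;D)`` -> ``(D;G)``).  Raises
    :class:`SequenceParseError` with the offending position on unbalanced
    parentheses, empty groups, or stray characters.
    """
    states: list[AOIState] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            close = text.find(")", i + 1)
            if close == -1:
                raise SequenceParseError("unbalanced '(' in sequence", position=i, line=line)
            body = text[i + 1 : close]
            members = [m.strip() for m in body.split(";")]
            if not body.strip() or any(not m for m in members):
                raise SequenceParseError("empty overlap group member", position=i, line=line)
            try:
                states.append(AOIState(members))
            except ValueError as exc:
                raise SequenceParseError(str(exc), position=i, line=line) from exc
            i = close + 1
        elif ch == ")":
            raise SequenceParseError("unbalanced ')' in sequence", position=i, line=line)
        elif ch.isalpha():
            states.append(AOIState(ch))
            i += 1
        else:
            raise SequenceParseError(f"unexpected character {ch!r}", position=i, line=line)
    return AOISequence(tuple(states), window=window, collapsed=False)


def format_sequence(seq: AOISequence) -> str:
    """Inverse of :func:`parse_sequence`: render states in canonical notation."""
    return "".join(s.canonical for s in seq.states)


def partition_time(
    total_start: float,
    total_end: float,
    boundaries: int | Sequence[float],
) -> list[TimeWindow]:
    """Split [total_start, total_end) into contiguous windows indexed 1..T.

    ``boundaries`` is either a count ``k`` of equal-width intervals or an
    explicit strictly increasing list of interior cut points.
    """
    if not total_start < total_end:
        raise ValueError("require total_start < total_end")
    if isinstance(boundaries, int):
        k = boundaries
        if k < 1:
            raise ValueError("interval count must be >= 1")
        width = (total_end - total_start) / k
        edges = [total_start + i * width for i in range(k)] + [total_end]
    else:
        cuts = list(boundaries)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must be strictly increasing")
        if cuts and (cuts[0] <= total_start or cuts[-1] >= total_end):
            raise ValueError("cut points must lie strictly inside (start, end)")
        edges = [total_start, *cuts, total_end]
    return [TimeWindow(a, b, index=i + 1) for i, (a, b) in enumerate(zip(edges, edges[1:]))]


def read_sequence_file(path: str | Path) -> list[AOISequence]:
    """Read a ``t<TAB>sequence`` file, one interval per line, sorted by t."""
    rows: list[tuple[int, AOISequence]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise SequenceParseError("expected 't<TAB>sequence'", line=lineno)
        try:
            t = int(parts[0].strip())
        except ValueError as exc:
            raise SequenceParseError(f"bad interval index {parts[0]!r}", line=lineno) from exc
        rows.append((t, parse_sequence(parts[1], line=lineno)))
    rows.sort(key=lambda r: r[0])
    out = []
    for t, seq in rows:
        # attach a nominal unit-length window carrying the interval index
        out.append(replace(seq, window=TimeWindow(float(t - 1), float(t), index=t)))
    return out


def write_sequence_file(path: str | Path, sequences: Iterable[AOISequence]) -> None:
    lines = []
    for i, seq in enumerate(sequences, start=1):
        t = seq.window.index if seq.window is not None else i
        lines.append(f"{t}\t{format_sequence(seq)}")
    Path(path).write_text("\n".join(lines) + "\n")
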