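"""AOI states: the alphabet of scanpath sequences.

An AOI (area of interest) is a labelled moving target on the display.  A
fixation that lands inside a single target's region yields a single-member
state such as ``A``; a fixation inside the intersection of several target
regions yields an *overlap state* written ``(A;B)``.  States are immutable
and hashable so they can serve as graph vertices and dictionary keys.
"""

from __future__ import annotations

import re
from typing import Iterable

__all__ = ["AOIState", "state_sort_key"]

_LABEL_RE = re.compile(r"^[A-Za-z]$")


def _member_key(label: str) -> tuple[int, str]:
    # uppercase block first, then lowercase; alphabetical within each block
    return (0 if label.isupper() else 1, label)


class AOIState:
    """A single target label or a canonical set of overlapping labels."""

    __slots__ = ("members",)

    members: tuple[str, ...]

    def __init__(self, members: str | Iterable[str]) -> None:
        if isinstance(members, str):
            members = (members,)
        labels = sorted(set(members), key=_member_key)
        if not labels:
            raise ValueError("AOIState requires at least one member label")
        for lab in labels:
            if not _LABEL_RE.match(lab):
                raise ValueError(f"invalid AOI label {lab!r}: expected a single letter")
        object.__setattr__(self, "members", tuple(labels))

    def __setattr__(self, name, value):  # immutable
        raise AttributeError("AOIState is immutable")

    @property
    def is_overlap(self) -> bool:
        return len(self.members) > 1

    @property
    def canonical(self) -> str:
        """Text form: the bare letter for a single AOI, ``(A;B)`` for overlaps."""
        if len(self.members) == 1:
            return self.members[0]
        return "(" + ";".join(self.members) + ")"

    def __str__(self) -> str:
        return self.canonical

    def __repr__(self) -> str:
        return f"AOIState({self.canonical!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, AOIState) and self.members == other.members

    def __hash__(self) -> int:
        return hash(self.members)

    def __lt__(self, other: "AOIState") -> bool:
        return state_sort_key(self) < state_sort_key(other)


def state_sort_key(state: AOIState) -> tuple:
    """Canonical ordering key used everywhere (sequences, matrices, layouts).

    Single AOIs precede overlap states; singles sort uppercase block first
    then lowercase, alphabetical within each block; overlap states sort by
    member count, then lexicographically by their (already canonical) member
    tuple.
    """
    members = state.members
    if len(members) == 1:
        return (0, _member_key(members[0]))
    return (1, len(members), tuple(_member_key(m) for m in members))
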