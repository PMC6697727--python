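"""Two-level zone partition hierarchies.

Commuter networks here live on a bipartite zone system with two sides
(origins = usual-residence zones, destinations = place-of-work zones) and two
levels per side: a *fine* partition (e.g. SA1 on the origin side, DZN on the
destination side) that nests exactly inside a *coarse* partition (SA2 on both
sides).  The exact nesting is what makes amalgamation of commuter counts from
fine to coarse zones unambiguous, and what makes the topological constraints
of the reconstruction well defined.

Zone codes are opaque strings; no arithmetic or structural parsing is ever
performed on them.  Coarse origin and coarse destination zones may share one
code space (both are SA2 in the Australian system) but are always addressed
through an explicit *side* argument so the two roles never get conflated by
accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping

ORIGIN = "origin"
DEST = "dest"
_SIDES = (ORIGIN, DEST)


class ZoneError(KeyError):
    """A zone code is missing from, or inconsistent with, a hierarchy."""


def _check_side(side: str) -> None:
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}, got {side!r}")


@dataclass
class ZoneHierarchy:
    """Exact-cover correspondence from fine zones to coarse zones, per side.

    Parameters
    ----------
    origin_parent
        Mapping fine-origin code -> coarse-origin code.
    dest_parent
        Mapping fine-destination code -> coarse-destination code.

    Because each side is a plain mapping, every fine zone has exactly one
    parent by construction; the inverse (children) maps are materialised once
    at construction time.
    """

    origin_parent: Mapping[str, str]
    dest_parent: Mapping[str, str]
    _children: Dict[str, Dict[str, FrozenSet[str]]] = field(
        init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.origin_parent = dict(self.origin_parent)
        self.dest_parent = dict(self.dest_parent)
        self._children = {}
        for side, parent_map in ((ORIGIN, self.origin_parent), (DEST, self.dest_parent)):
            inv: Dict[str, set] = {}
            for fine, coarse in parent_map.items():
                inv.setdefault(coarse, set()).add(fine)
            self._children[side] = {c: frozenset(f) for c, f in inv.items()}

    def _parent_map(self, side: str) -> Mapping[str, str]:
        _check_side(side)
        return self.origin_parent if side == ORIGIN else self.dest_parent

    def parent_of(self, zone: str, side: str) -> str:
        """Return the coarse zone containing fine ``zone`` on ``side``."""
        parents = self._parent_map(side)
        try:
            return parents[zone]
        except KeyError:
            raise ZoneError(
                f"fine {side} zone {zone!r} has no parent in the correspondence "
                "(incomplete correspondence table?)"
            ) from None

    def children_of(self, zone: str, side: str) -> FrozenSet[str]:
        """Return the fine zones whose parent is coarse ``zone`` on ``side``."""
        _check_side(side)
        try:
            return self._children[side][zone]
        except KeyError:
            raise ZoneError(
                f"unknown coarse {side} zone {zone!r} (no children recorded)"
            ) from None

    def coarse_zones(self, side: str) -> FrozenSet[str]:
        _check_side(side)
        return frozenset(self._children[side])

    def fine_zones(self, side: str) -> FrozenSet[str]:
        return frozenset(self._parent_map(side))
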