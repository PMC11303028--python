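"""Continental areas, geographic ranges and the DEC state space.

The study system is continent-scale historical biogeography on four areas —
South America (SA), North America (NA), Eurasia (EU) and Africa (AF) —
arranged on a chain: dispersal is only possible between SA-NA, NA-EU and
EU-AF.  A *range* is a non-empty subset of areas; the state space of the
range-evolution model enumerates all ranges up to a maximum size, plus one
internal "null" state representing a lineage whose range has contracted to
nothing along a branch.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Sequence, Tuple

#: Canonical area codes, in the fixed order used throughout the package.
AREAS: Tuple[str, ...] = ("SA", "NA", "EU", "AF")

Range = FrozenSet[str]


def chain_adjacency(areas: Sequence[str]) -> FrozenSet[Range]:
    """Adjacency pairs for areas arranged on a line, in the given order."""
    return frozenset(frozenset(p) for p in zip(areas[:-1], areas[1:]))


#: The fixed SA-NA-EU-AF chain.
ADJACENCY: FrozenSet[Range] = chain_adjacency(AREAS)


def as_range(areas: Iterable[str], valid: Sequence[str] = AREAS) -> Range:
    """Normalize an iterable of area codes into a frozenset, validating codes."""
    rng = frozenset(areas)
    unknown = rng - set(valid)
    if unknown:
        raise ValueError(f"unknown area codes: {sorted(unknown)}")
    if not rng:
        raise ValueError("a range must contain at least one area")
    return rng


class RangeStateSpace:
    """Ordered enumeration of permitted ranges plus an internal null state.

    States are ordered by range size, then lexicographically by area index
    in the order ``areas`` were given; the null state sits at the final
    index.  The null state is never assignable to a tip and carries no root
    prior mass — it only exists so that whole-range extinction along a
    branch is an absorbing anagenetic state.

    Parameters
    ----------
    areas : sequence of str
        2–8 unique area codes.
    max_range_size : int
        Largest permitted range (3 for reconstruction on four continents,
        2 for the simulator).
    adjacency : iterable of 2-sets, optional
        Pairs of areas between which dispersal is allowed.  Defaults to the
        chain over ``areas`` in the order given.  Must be symmetric and
        irreflexive (guaranteed by the 2-set representation).
    """

    def __init__(
        self,
        areas: Sequence[str] = AREAS,
        max_range_size: int = 3,
        adjacency: Iterable[Iterable[str]] | None = None,
    ) -> None:
        areas = tuple(areas)
        if not 2 <= len(areas) <= 8:
            raise ValueError("between 2 and 8 areas are supported")
        if len(set(areas)) != len(areas):
            raise ValueError("area codes must be unique")
        if max_range_size < 1:
            raise ValueError("max_range_size must be >= 1")
        if max_range_size > len(areas):
            raise ValueError("max_range_size cannot exceed the number of areas")
        self.areas = areas
        self.max_range_size = int(max_range_size)
        self._area_index: Dict[str, int] = {a: i for i, a in enumerate(areas)}

        if adjacency is None:
            pairs = chain_adjacency(areas)
        else:
            pairs = frozenset(frozenset(p) for p in adjacency)
        for p in pairs:
            if len(p) != 2:
                raise ValueError(f"adjacency entries must be pairs, got {set(p)}")
            if not p <= set(areas):
                raise ValueError(f"adjacency pair {set(p)} not within areas")
        self.adjacency_pairs = pairs
        self._neighbors: Dict[str, FrozenSet[str]] = {
            a: frozenset(b for b in areas if frozenset((a, b)) in pairs)
            for a in areas
        }

        states = []
        for size in range(1, self.max_range_size + 1):
            for combo in combinations(range(len(areas)), size):
                states.append(frozenset(areas[i] for i in combo))
        self.states: Tuple[Range, ...] = tuple(states)
        self.index: Dict[Range, int] = {s: i for i, s in enumerate(states)}
        self.n_observable = len(states)
        self.null_index = self.n_observable
        self.n_states = self.n_observable + 1

    # -- queries ---------------------------------------------------------
    def area_index(self, area: str) -> int:
        return self._area_index[area]

    def neighbors(self, area: str) -> FrozenSet[str]:
        """Areas adjacent to ``area``."""
        return self._neighbors[area]

    def is_adjacent(self, a: str, b: str) -> bool:
        return b in self._neighbors[a]

    def range_index(self, areas: Iterable[str]) -> int:
        """Index of a range in the state ordering; raises if not permitted."""
        rng = as_range(areas, self.areas)
        try:
            return self.index[rng]
        except KeyError:
            raise ValueError(
                f"range {sorted(rng)} exceeds max_range_size={self.max_range_size}"
            ) from None

    def sort_areas(self, areas: Iterable[str]) -> Tuple[str, ...]:
        return tuple(sorted(areas, key=self._area_index.get))

    def label(self, state_index: int) -> str:
        if state_index == self.null_index:
            return "null"
        return "+".join(self.sort_areas(self.states[state_index]))

    def __len__(self) -> int:
        return self.n_states

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RangeStateSpace(areas={self.areas}, max_range_size="
            f"{self.max_range_size}, n_observable={self.n_observable})"
        )
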