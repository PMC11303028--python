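"""Fossil preservation, biased detection, and tree subsampling.

Fossil preservation is a Poisson process: a species alive for a span of
time accumulates expected occurrences at a rate that may vary by time bin
and continent (a *stratified* preservation model).  A species is *known*
if it is detected at least once, so its detection probability is
``1 - exp(-f * I)`` where ``I`` integrates the stratum rates over the
species' lifespan (widespread spans split their intensity equally across
occupied continents) and ``f`` is a global multiplier.  Calibrating ``f``
against a target fraction of known fossil species, then Bernoulli-sampling
detections, yields biased known sets that over-represent well-preserved
strata; the random-sampling scheme is the homogeneous special case.

Reduced trees are produced by pruning: all extant tips are kept, a chosen
subset of extinct tips is kept, and unary nodes are suppressed with branch
lengths summed, so path lengths and divergence times among retained tips
are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import brentq

from .geography import AREAS, Range
from .trees import Node, PhyloTree, TreeValidationError

__all__ = [
    "PreservationModel",
    "SamplingScenario",
    "species_detection_prob",
    "calibrate_factor",
    "draw_known_set",
    "draw_included_set",
    "prune_to",
]

Segment = Tuple[float, float, Range]  # (age_old, age_young, range)


@dataclass
class PreservationModel:
    """Piecewise-constant preservation rates per (time bin x continent).

    ``bin_edges`` are age boundaries in Ma, ascending, implicitly starting
    at 0 and ending at +inf; ``rates`` has one row per bin (len(edges)+1
    bins) and one column per area, in /lineage/Ma.  ``factor`` is the
    global multiplier applied on top.
    """

    bin_edges: np.ndarray
    rates: np.ndarray
    areas: Tuple[str, ...] = AREAS
    factor: float = 1.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if np.any(self.rates < 0):
            raise ValueError("preservation rates must be >= 0")
        if self.factor < 0:
            raise ValueError("factor must be >= 0")
        if self.rates.shape != (len(self.bin_edges) + 1, len(self.areas)):
            raise ValueError(
                f"rates must be (n_bins={len(self.bin_edges) + 1}, "
                f"n_areas={len(self.areas)}), got {self.rates.shape}"
            )

    # -- constructors ----------------------------------------------------
    @classmethod
    def homogeneous(cls, rate: float, areas: Sequence[str] = AREAS) -> "PreservationModel":
        """A single stratum with the same rate everywhere and always."""
        return cls(np.array([]), np.full((1, len(areas)), float(rate)), tuple(areas))

    @classmethod
    def synthetic_biased(
        cls,
        root_age: float,
        base_rate: float = 0.1,
        area_multipliers: Sequence[float] = (0.5, 2.0, 1.0, 0.7),
        time_multipliers: Sequence[float] = (2.0, 1.0, 0.5),
        areas: Sequence[str] = AREAS,
    ) -> "PreservationModel":
        """A synthetic biased record: recent strata and North America richest.

        Emulates the qualitative structure of real mammal preservation
        (e.g. Pleistocene North America being far better known than the
        Paleogene tropics) without reference to any empirical rate table.
        Time bins are thirds of the root age.
        """
        edges = np.array([root_age / 3.0, 2.0 * root_age / 3.0])
        rates = base_rate * np.outer(time_multipliers, area_multipliers)
        return cls(edges, rates, tuple(areas))

    # -- evaluation ------------------------------------------------------
    def _bin_of(self, age: float) -> int:
        return int(np.searchsorted(self.bin_edges, age, side="right"))

    def iter_pieces(self, age_old: float, age_young: float, rng: Range):
        """Split a lifespan segment at bin edges.

        Yields ``(piece_old, piece_young, area, effective_rate)`` with the
        per-continent 1/|range| split and the global factor applied.
        """
        if age_old < age_young:
            raise ValueError("segment must run old -> young")
        cuts = [age_old]
        for e in reversed(self.bin_edges):
            if age_young < e < age_old:
                cuts.append(float(e))
        cuts.append(age_young)
        share = 1.0 / len(rng)
        members = sorted(rng, key=self.areas.index)  # fixed order per seed
        for old, young in zip(cuts[:-1], cuts[1:]):
            b = self._bin_of(0.5 * (old + young))
            for area in members:
                q = self.factor * self.rates[b, self.areas.index(area)] * share
                yield old, young, area, q

    def intensity_integral(self, segments: Iterable[Segment]) -> float:
        """Expected occurrences over a lifespan at factor 1."""
        return _base_integral(self, segments)

    def with_factor(self, f: float) -> "PreservationModel":
        return PreservationModel(self.bin_edges.copy(), self.rates.copy(), self.areas, f)


def _base_integral(model: PreservationModel, segments: Iterable[Segment]) -> float:
    """Expected occurrences at factor 1 (the calibration objective's kernel)."""
    total = 0.0
    for age_old, age_young, rng in segments:
        if age_old < age_young:
            raise ValueError("negative time span in trajectory segment")
        share = 1.0 / len(rng)
        cuts = [age_old]
        for e in reversed(model.bin_edges):
            if age_young < e < age_old:
                cuts.append(float(e))
        cuts.append(age_young)
        for old, young in zip(cuts[:-1], cuts[1:]):
            b = model._bin_of(0.5 * (old + young))
            for area in sorted(rng, key=model.areas.index):
                total += model.rates[b, model.areas.index(area)] * share * (old - young)
    return total


@dataclass(frozen=True)
class SamplingScenario:
    """One fossil-sampling condition of the study grid."""

    frac_known: float
    frac_included: float
    mode: str = "biased"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_included <= self.frac_known <= 1.0:
            raise ValueError(
                "need 0 <= frac_included <= frac_known <= 1, got "
                f"included={self.frac_included}, known={self.frac_known}"
            )
        if self.mode not in ("biased", "random"):
            raise ValueError("mode must be 'biased' or 'random'")

    @property
    def label(self) -> str:
        return (
            f"{self.mode}_known{round(self.frac_known * 100)}"
            f"_incl{round(self.frac_included * 100)}"
        )


def species_detection_prob(
    segments: Sequence[Segment], model: PreservationModel, factor: Optional[float] = None
) -> float:
    """P(at least one occurrence) for a species with the given lifespan."""
    f = model.factor if factor is None else factor
    if f < 0:
        raise ValueError("factor must be >= 0")
    return float(1.0 - np.exp(-f * _base_integral(model, segments)))


def calibrate_factor(
    model: PreservationModel,
    trajectories: Dict[str, Sequence[Segment]],
    target_frac_known: float,
    tol: float = 1e-6,
) -> float:
    """Multiplier ``f`` at which the mean detection probability hits the target.

    The map ``f -> mean_s (1 - exp(-f I_s))`` is monotone increasing, so
    the root is bracketed by doubling and solved with Brent's method to a
    ``tol`` on the achieved fraction.
    """
    if not 0.0 < target_frac_known < 1.0:
        raise ValueError("target fraction must lie strictly between 0 and 1")
    if not trajectories:
        raise ValueError("no extinct species to calibrate against")
    integrals = np.array([_base_integral(model, s) for s in trajectories.values()])
    if not np.any(integrals > 0):
        raise ValueError("all base preservation intensities are zero; target unreachable")

    def gap(f: float) -> float:
        return float(np.mean(1.0 - np.exp(-f * integrals)) - target_frac_known)

    hi = 1.0
    while gap(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise ValueError(
                f"target fraction {target_frac_known} unreachable: even f={hi:g} "
                "leaves too many species undetectable"
            )
    f = brentq(gap, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(gap(f)) < tol
    return float(f)


def draw_known_set(
    trajectories: Dict[str, Sequence[Segment]],
    model: PreservationModel,
    seed,
    factor: Optional[float] = None,
) -> Set[str]:
    """Bernoulli detection draw per extinct species under the (calibrated) model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    known = set()
    for name in sorted(trajectories):
        p = species_detection_prob(trajectories[name], model, factor)
        if rng.uniform() < p:
            known.add(name)
    return known


def draw_included_set(
    known_set: Set[str],
    n_extinct_total: int,
    frac_included: float,
    seed,
    frac_known: Optional[float] = None,
) -> Set[str]:
    """Uniform subset of the known species, sized as a fraction of *all* extinct.

    Both ``frac_included`` and ``frac_known`` refer to fractions of all
    extinct species; when they are equal, every known species is included.
    """
    if frac_known is not None and np.isclose(frac_included, frac_known):
        return set(known_set)
    size = int(round(frac_included * n_extinct_total))
    if size > len(known_set):
        raise ValueError(
            f"cannot include {size} species (= {frac_included:.0%} of "
            f"{n_extinct_total} extinct) from a known set of {len(known_set)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(sorted(known_set), size=size, replace=False)
    return set(chosen.tolist())


def tip_lifespan_segments(tree: PhyloTree) -> Dict[str, List[Segment]]:
    """Single-segment lifespans from terminal branches (for trees without
    a simulation event log): each species spans its terminal branch with
    its observed range throughout."""
    out: Dict[str, List[Segment]] = {}
    for t in tree.tips():
        if t.range_ is None:
            raise TreeValidationError(f"tip {t.name} has no range bound")
        out[t.name] = [(t.age + t.length, t.age, t.range_)]
    return out


def prune_to(tree: PhyloTree, keep_extinct: Iterable[str]) -> PhyloTree:
    """Reduced tree retaining all extant tips plus the listed extinct tips.

    Unary internal nodes are suppressed with their branch lengths summed;
    node ages, tip ranges and simulation-truth ranges are preserved on the
    retained nodes.
    """
    keep_extinct = set(keep_extinct)
    extinct_names = {t.name for t in tree.tips() if t.extinct}
    unknown = keep_extinct - extinct_names
    if unknown:
        raise TreeValidationError(
            f"keep set contains non-extinct or unknown species: {sorted(unknown)}"
        )
    keep = {t.name for t in tree.tips() if not t.extinct} | keep_extinct

    def clone(node: Node) -> Node:
        new = Node(node.name, node.length)
        new.age = node.age
        new.range_ = node.range_
        new.extinct = node.extinct
        new.last_continent = node.last_continent
        return new

    built: Dict[int, Optional[Node]] = {}
    for node in tree.postorder():  # iterative: simulated trees can be deep
        if node.is_tip:
            built[id(node)] = clone(node) if node.name in keep else None
            continue
        kids = [built[id(c)] for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            built[id(node)] = None
        elif len(kids) == 1:
            # suppress this node: the surviving child absorbs the branch
            kids[0].length += node.length
            built[id(node)] = kids[0]
        else:
            new = clone(node)
            for k in kids:
                new.add_child(k)
            built[id(node)] = new

    new_root = built[id(tree.root)]
    if new_root is None or new_root.is_tip:
        raise TreeValidationError("pruning left fewer than two tips")
    new_root.length = 0.0
    return PhyloTree(new_root)
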