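"""Forward simulation of range evolution on four continents.

The generator is a four-area geographic state-dependent speciation–
extinction (GeoSSE-equivalent ClaSSE) process run with the Gillespie
algorithm from a single endemic ancestor on a uniformly drawn continent.
Five rates, identical across continents, drive the process:

* ``mu``      per-continent extinction (/Ma): an endemic lineage dies, a
  widespread lineage contracts;
* ``delta``   range expansion into each adjacent continent (/Ma);
* ``lambda1`` sympatric speciation, per occupied continent (/Ma);
* ``lambda2`` jump-dispersal speciation, per adjacent unoccupied
  continent (/Ma): one daughter colonizes the new continent;
* ``lambda3`` allopatric speciation of a widespread lineage into two
  endemic daughters (/Ma).

Simulated ranges span at most two adjacent continents.  The run stops the
instant the number of living lineages first reaches the target; runs that
go globally extinct first are rejected and retried.  Extinct lineages are
retained as dated fossil tips with the range and continent at extinction;
the true range at every internal node is recorded as simulation truth.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geography import AREAS, Range, RangeStateSpace
from .trees import Node, PhyloTree

__all__ = [
    "SimParams",
    "Event",
    "SimulationResult",
    "SimulationError",
    "draw_params_from_priors",
    "simulate_tree",
    "simulate_occurrences",
    "oldest_record_area",
    "PRIOR_SUPPORTS",
]

#: Uniform prior supports for the five diversification parameters.
PRIOR_SUPPORTS: Dict[str, Tuple[float, float]] = {
    "mu": (0.0, 1.0),
    "delta": (0.0, 1.0),
    "lambda1": (0.0, 1.0),
    "lambda2": (0.0, 0.25),
    "lambda3": (0.0, 3.0),
}


class SimulationError(RuntimeError):
    """Raised when the simulator cannot produce a tree within its budgets."""


@dataclass(frozen=True)
class SimParams:
    """The five diversification rates (all /Ma, identical across continents)."""

    mu: float
    delta: float
    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        for f in ("mu", "delta", "lambda1", "lambda2", "lambda3"):
            v = getattr(self, f)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f} must be finite and >= 0, got {v}")

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in PRIOR_SUPPORTS}


def draw_params_from_priors(seed) -> SimParams:
    """One draw from the uniform priors; reproducible per seed (or Generator)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return SimParams(
        **{k: rng.uniform(lo, hi) for k, (lo, hi) in PRIOR_SUPPORTS.items()}
    )


@dataclass(frozen=True)
class Event:
    """One entry of the simulation event log (times increase forward)."""

    time: float
    lineage: int
    etype: str  # expansion | contraction | global-extinction | sympatric | jump | allopatric
    source: Range
    outcome: Tuple[Range, ...]


@dataclass
class SimulationResult:
    tree: PhyloTree
    params: SimParams
    seed: Optional[int]
    n_attempts: int
    t_stop: float
    stem_time: float
    total_lineage_time: float
    events: List[Event]
    exposures: Dict[str, float]
    counts: Dict[str, int]
    #: per-tip piecewise range history in age coordinates (old -> young)
    trajectories: Dict[str, List[Tuple[float, float, Range]]]

    def extinct_tips(self) -> List[str]:
        return [t.name for t in self.tree.tips() if t.extinct]

    def extant_tips(self) -> List[str]:
        return [t.name for t in self.tree.tips() if not t.extinct]


class _Lineage:
    __slots__ = ("lid", "range_", "t_birth", "parent", "segs")

    def __init__(self, lid: int, range_: Range, t_birth: float, parent: Optional[int]):
        self.lid = lid
        self.range_ = range_
        self.t_birth = t_birth
        self.parent = parent  # index of the internal-node record that created it
        self.segs: List[Tuple[float, float, Range]] = []  # closed (t0, t1, range)
        self._open(t_birth)

    def _open(self, t: float) -> None:
        self.segs.append((t, np.nan, self.range_))

    def set_range(self, t: float, new: Range) -> None:
        t0, _, rng = self.segs[-1]
        self.segs[-1] = (t0, t, rng)
        self.range_ = new
        self._open(t)

    def close(self, t: float) -> None:
        t0, _, rng = self.segs[-1]
        self.segs[-1] = (t0, t, rng)


def _neighbor_map(space: RangeStateSpace) -> Dict[str, FrozenSet[str]]:
    return {a: space.neighbors(a) for a in space.areas}


def _attempt(
    params: SimParams,
    n_extant_target: int,
    rng: np.random.Generator,
    neighbors: Dict[str, FrozenSet[str]],
    max_events: int,
    root_area: Optional[str],
    jumps_from_widespread: bool,
):
    """One Gillespie run.

    Always returns a run dict whose ``status`` is ``"ok"`` (target reached),
    ``"extinct"`` (total extinction first), ``"frozen"`` (all rates zero) or
    ``"overflow"`` (event cap hit); counts and exposures are kept for every
    outcome so that realized event rates can be checked unconditionally.
    """
    areas = list(neighbors)
    start = root_area or areas[rng.integers(len(areas))]
    lineages: Dict[int, _Lineage] = {0: _Lineage(0, frozenset((start,)), 0.0, None)}
    alive = {0}
    nodes: List[dict] = []  # speciation records
    fate: Dict[int, Tuple[str, object]] = {}  # lid -> ("node", idx) | ("dead", t)
    events: List[Event] = []
    exposures = defaultdict(float)
    counts: Counter = Counter()
    t = 0.0
    total_lt = 0.0
    stem_time = None

    def _finish(status):
        return dict(
            status=status,
            lineages=lineages,
            nodes=nodes,
            fate=fate,
            events=events,
            exposures=dict(exposures),
            counts=dict(counts),
            t_stop=t,
            stem_time=stem_time,
            total_lineage_time=total_lt,
        )

    # fixed area order: set/frozenset iteration order varies with string
    # hash randomization, and the event menu must be reproducible per seed
    area_rank = {a: i for i, a in enumerate(areas)}

    while True:
        menu: List[Tuple[float, int, str, Optional[str]]] = []
        risk = dict(sympatric=0.0, extinction=0.0, jump=0.0, expansion=0.0, allopatric=0.0)
        for lid in sorted(alive):
            R = lineages[lid].range_
            if len(R) == 1:
                (c,) = R
                adj = sorted(neighbors[c], key=area_rank.get)
                menu.append((params.lambda1, lid, "sympatric", c))
                menu.append((params.mu, lid, "global-extinction", c))
                for a in adj:
                    menu.append((params.lambda2, lid, "jump", a))
                    menu.append((params.delta, lid, "expansion", a))
                risk["sympatric"] += 1
                risk["extinction"] += 1
                risk["jump"] += len(adj)
                risk["expansion"] += len(adj)
            else:
                unocc = sorted(
                    frozenset().union(*(neighbors[a] for a in R)) - R,
                    key=area_rank.get,
                )
                for c in sorted(R, key=area_rank.get):
                    menu.append((params.lambda1, lid, "sympatric", c))
                    menu.append((params.mu, lid, "contraction", c))
                menu.append((params.lambda3, lid, "allopatric", None))
                if jumps_from_widespread:
                    for a in unocc:
                        menu.append((params.lambda2, lid, "jump", a))
                    risk["jump"] += len(unocc)
                risk["sympatric"] += len(R)
                risk["extinction"] += len(R)
                risk["allopatric"] += 1
        rates = np.array([m[0] for m in menu])
        total = rates.sum()
        if total <= 0.0:
            return _finish("frozen")
        dt = rng.exponential(1.0 / total)
        t += dt
        total_lt += len(alive) * dt
        for k, v in risk.items():
            exposures[k] += v * dt
        pick = int(np.searchsorted(np.cumsum(rates), rng.uniform(0.0, total)))
        pick = min(pick, len(menu) - 1)
        _, lid, etype, payload = menu[pick]
        lin = lineages[lid]
        R = lin.range_
        counts[etype] += 1

        if etype == "expansion":
            new = R | {payload}
            events.append(Event(t, lid, etype, R, (new,)))
            lin.set_range(t, new)
        elif etype == "contraction":
            new = R - {payload}
            events.append(Event(t, lid, etype, R, (new,)))
            lin.set_range(t, new)
        elif etype == "global-extinction":
            events.append(Event(t, lid, etype, R, ()))
            lin.close(t)
            fate[lid] = ("dead", t)
            alive.remove(lid)
            if not alive:
                return _finish("extinct")
        else:  # speciation
            if etype == "sympatric":
                daughters = (
                    (frozenset((payload,)), R) if len(R) > 1 else (R, R)
                )
            elif etype == "jump":
                daughters = (R, frozenset((payload,)))
            else:  # allopatric
                a, b = sorted(R)
                daughters = (frozenset((a,)), frozenset((b,)))
            events.append(Event(t, lid, etype, R, daughters))
            lin.close(t)
            node_idx = len(nodes)
            if stem_time is None:
                stem_time = t
            nodes.append(
                dict(time=t, range=R, parent=lin.parent, lineage=lid, children=[])
            )
            fate[lid] = ("node", node_idx)
            alive.remove(lid)
            for drange in daughters:
                nid = len(lineages)
                lineages[nid] = _Lineage(nid, drange, t, node_idx)
                nodes[node_idx]["children"].append(nid)
                alive.add(nid)
            if len(alive) >= n_extant_target:
                for l2 in alive:
                    lineages[l2].close(t)
                    fate[l2] = ("alive", t)
                return _finish("ok")
        if len(events) >= max_events:
            return _finish("overflow")  # runaway draw; treated as a failed attempt


def _build_tree(run: dict) -> Tuple[PhyloTree, Dict[str, List[Tuple[float, float, Range]]]]:
    lineages, nodes, fate, t_stop = (
        run["lineages"],
        run["nodes"],
        run["fate"],
        run["t_stop"],
    )
    trajectories: Dict[str, List[Tuple[float, float, Range]]] = {}

    def make_node(lid: int) -> Node:
        lin = lineages[lid]
        kind, info = fate[lid]
        if kind == "node":
            nrec = nodes[info]
            node = Node(length=nrec["time"] - lin.t_birth)
            node.age = t_stop - nrec["time"]
            node.range_ = nrec["range"]
            return node
        name = f"t{lid}"
        t_end = info if kind == "dead" else t_stop
        tip = Node(name=name, length=t_end - lin.t_birth)
        tip.age = t_stop - t_end
        tip.range_ = lin.range_
        tip.extinct = kind == "dead"
        if tip.extinct:
            (tip.last_continent,) = lin.range_  # extinction only strikes endemics
        trajectories[name] = [
            (t_stop - t0, t_stop - t1, rng) for t0, t1, rng in lin.segs
        ]
        return tip

    root_lid = nodes[0]["lineage"]
    root = make_node(root_lid)
    stack = [(root_lid, root)]
    while stack:  # iterative build: simulated trees can be very deep
        lid, node = stack.pop()
        kind, info = fate[lid]
        if kind != "node":
            continue
        for child_lid in nodes[info]["children"]:
            child = make_node(child_lid)
            node.add_child(child)
            stack.append((child_lid, child))
    root.length = 0.0
    return PhyloTree(root), trajectories


def simulate_tree(
    params: SimParams,
    n_extant_target: int,
    seed=None,
    max_attempts: int = 100,
    max_events: int = 1_000_000,
    root_area: Optional[str] = None,
    jumps_from_widespread: bool = True,
    state_space: Optional[RangeStateSpace] = None,
) -> SimulationResult:
    """Simulate one tree with exactly ``n_extant_target`` extant tips.

    Attempts that go globally extinct (or exceed ``max_events``) before the
    living-lineage count first reaches the target are rejected and retried,
    up to ``max_attempts``.
    """
    if n_extant_target < 2:
        raise ValueError("n_extant_target must be >= 2")
    space = state_space or RangeStateSpace(AREAS, max_range_size=2)
    neighbors = _neighbor_map(space)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        run = _attempt(
            params,
            n_extant_target,
            rng,
            neighbors,
            max_events,
            root_area,
            jumps_from_widespread,
        )
        if run["status"] == "ok":
            tree, trajectories = _build_tree(run)
            return SimulationResult(
                tree=tree,
                params=params,
                seed=seed if isinstance(seed, int) else None,
                n_attempts=attempt,
                t_stop=run["t_stop"],
                stem_time=run["stem_time"],
                total_lineage_time=run["total_lineage_time"],
                events=run["events"],
                exposures=run["exposures"],
                counts=run["counts"],
                trajectories=trajectories,
            )
    raise SimulationError(
        f"no surviving simulation reached {n_extant_target} extant lineages "
        f"in {max_attempts} attempts"
    )


#: nominal rate of each event class per unit of its own exposure
EVENT_CLASSES = {
    "sympatric": ("sympatric",),
    "extinction": ("global-extinction", "contraction"),
    "jump": ("jump",),
    "expansion": ("expansion",),
    "allopatric": ("allopatric",),
}


def nominal_event_rates(params: SimParams) -> Dict[str, float]:
    """Nominal per-exposure-unit rate of each event class.

    Exposure units: lineage-time weighted by range size (sympatric and
    extinction/contraction), by the number of adjacent unoccupied
    continents (jump, and expansion for endemics), and widespread
    lineage-time (allopatric).
    """
    return {
        "sympatric": params.lambda1,
        "extinction": params.mu,
        "jump": params.lambda2,
        "expansion": params.delta,
        "allopatric": params.lambda3,
    }


def pooled_event_rates(
    params: SimParams,
    seed,
    min_events: int = 10_000,
    n_extant_cap: int = 100,
    max_events_per_run: int = 20_000,
    max_runs: int = 10_000,
) -> pd.DataFrame:
    """Realized event rates pooled over runs until ``min_events`` accrue.

    Pools counts and exposures over *all* runs — including those ending in
    total extinction — so the realized rates estimate the unconditional
    process (conditioning on survival would bias extinction downward).
    Returns one row per event class with count, exposure, realized and
    nominal rates, and the nominal Poisson standard error.
    """
    space = RangeStateSpace(AREAS, max_range_size=2)
    neighbors = _neighbor_map(space)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts: Counter = Counter()
    exposures: Dict[str, float] = defaultdict(float)
    total = 0
    runs = 0
    while total < min_events and runs < max_runs:
        run = _attempt(
            params, n_extant_cap, rng, neighbors, max_events_per_run, None, True
        )
        runs += 1
        for k, v in run["counts"].items():
            counts[k] += v
        for k, v in run["exposures"].items():
            exposures[k] += v
        total += len(run["events"])
    nominal = nominal_event_rates(params)
    rows = []
    for cls, etypes in EVENT_CLASSES.items():
        count = sum(counts.get(e, 0) for e in etypes)
        exp_time = exposures.get(cls, 0.0)
        realized = count / exp_time if exp_time > 0 else np.nan
        se = np.sqrt(nominal[cls] / exp_time) if exp_time > 0 else np.nan
        rows.append(
            {
                "event_class": cls,
                "count": count,
                "exposure": exp_time,
                "realized_rate": realized,
                "nominal_rate": nominal[cls],
                "nominal_se": se,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fossil occurrences
# ---------------------------------------------------------------------------

def simulate_occurrences(
    result: SimulationResult,
    model,
    seed=None,
    species: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Poisson fossil occurrences along each species' lifespan.

    ``model`` is a :class:`~paleorange.sampling.PreservationModel`.  Each
    occupied continent contributes an independent Poisson stream with
    intensity ``factor x q(time bin, continent) / range size``, so a
    widespread species splits its preservation potential across its
    continents; occurrences are tagged with the continent of the stream
    that produced them.  Returns a DataFrame (species, age, continent).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: List[Tuple[str, float, str]] = []
    names = species if species is not None else list(result.trajectories)
    for name in names:
        for age_old, age_young, rng_range in result.trajectories[name]:
            for piece_old, piece_young, area, q in model.iter_pieces(
                age_old, age_young, rng_range
            ):
                lam = q * (piece_old - piece_young)
                if lam <= 0:
                    continue
                k = rng.poisson(lam)
                if k:
                    ages = rng.uniform(piece_young, piece_old, size=k)
                    rows.extend((name, float(a), area) for a in ages)
    return pd.DataFrame(rows, columns=["species", "age", "continent"]).sort_values(
        ["species", "age"], ascending=[True, False], ignore_index=True
    )


def oldest_record_area(
    occurrences: pd.DataFrame, group: Optional[Sequence[str]] = None
) -> Tuple[str, ...]:
    """Continent(s) of the oldest occurrence in a group (ties all reported)."""
    df = occurrences
    if group is not None:
        df = df[df["species"].isin(set(group))]
    if df.empty:
        raise ValueError("no occurrences for the requested group")
    top = df["age"].max()
    areas = sorted(set(df.loc[df["age"] == top, "continent"]), key=AREAS.index)
    return tuple(areas)
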