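"""Time-calibrated binary trees with fossil tips, and file I/O.

Trees are strictly binary and rooted; branch lengths are in millions of
years (Ma).  Tips may be extant (age 0) or extinct (age > 0, "fossil
tips").  Unless an explicit tip-age table is supplied, tip ages are derived
from root-to-tip path lengths with the deepest tip defining the present;
tips older than a small tolerance are flagged extinct.

Newick parsing and writing are delegated to dendropy; the geography file is
the Lagrange/PHYLIP-style binary presence table
(``n_species n_areas (A B C D)`` header, then ``name 0110`` rows).
"""

from __future__ import annotations

import io
import os
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import dendropy

from .geography import AREAS, Range, as_range

__all__ = [
    "Node",
    "PhyloTree",
    "GeographyTable",
    "read_newick",
    "write_newick",
    "read_geography",
    "write_geography",
    "bind_ranges",
    "TreeFormatError",
    "TreeValidationError",
]


class TreeFormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the package's contracts."""


class Node:
    """A node of a rooted binary tree.

    Attributes
    ----------
    name : str or None
        Tip label (mandatory for tips, optional for internal nodes).
    length : float
        Length of the branch subtending this node (0.0 for the root).
    age : float
        Time before present, in Ma.
    range_ : frozenset of str or None
        Observed range for tips; simulation-truth range for internal nodes
        when known.
    extinct : bool
        Tips only: whether the tip predates the present.
    last_continent : str or None
        Extinct tips only: the single continent occupied at extinction.
    """

    __slots__ = (
        "name",
        "length",
        "children",
        "parent",
        "age",
        "range_",
        "extinct",
        "last_continent",
    )

    def __init__(self, name: Optional[str] = None, length: float = 0.0) -> None:
        self.name = name
        self.length = float(length)
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None
        self.age: float = 0.0
        self.range_: Optional[Range] = None
        self.extinct: bool = False
        self.last_continent: Optional[str] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        kind = "tip" if self.is_tip else "node"
        return f"<{kind} {self.name or '?'} age={self.age:.3g}>"


class PhyloTree:
    """A rooted, strictly binary, time-calibrated phylogeny."""

    def __init__(self, root: Node, validate: bool = True) -> None:
        self.root = root
        self.root.length = 0.0
        self.root.parent = None
        if validate:
            self._validate()

    # -- traversal -------------------------------------------------------
    def postorder(self) -> List[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def preorder(self) -> List[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def tips(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def internal_nodes(self) -> List[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def root_age(self) -> float:
        return self.root.age

    def tip(self, name: str) -> Node:
        for t in self.tips():
            if t.name == name:
                return t
        raise KeyError(name)

    def tip_names(self) -> List[str]:
        return [t.name for t in self.tips()]

    def clade_tips(self, node: Node) -> FrozenSet[str]:
        """Names of the tips descending from ``node`` (the clade key)."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    # -- validation and ages --------------------------------------------
    def _validate(self) -> None:
        names = []
        for node in self.postorder():
            if node.is_tip:
                if not node.name:
                    raise TreeValidationError("every tip must be labelled")
                names.append(node.name)
            elif len(node.children) != 2:
                raise TreeValidationError(
                    "trees must be strictly binary; found a node with "
                    f"{len(node.children)} children (polytomies are rejected)"
                )
            if node is not self.root and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} above {node.name or 'an internal node'}"
                )
        if len(names) != len(set(names)):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dups}")
        if len(names) < 2:
            raise TreeValidationError("a tree needs at least two tips")

    def assign_ages(
        self,
        tip_ages: Optional[Dict[str, float]] = None,
        tip_age_tolerance: float = 1e-6,
    ) -> None:
        """Set node ages and extinct flags.

        Without a tip-age table the deepest tip defines the present (age 0)
        and every other tip's age follows from path lengths.  With a table,
        the listed ages override the path-length-derived ones and internal
        ages are propagated from them.
        """
        if tip_ages is None:
            depth: Dict[int, float] = {id(self.root): 0.0}
            for node in self.preorder():
                if node is not self.root:
                    depth[id(node)] = depth[id(node.parent)] + node.length
            plane = max(depth[id(t)] for t in self.tips())
            ages = {t.name: plane - depth[id(t)] for t in self.tips()}
        else:
            missing = set(self.tip_names()) - set(tip_ages)
            if missing:
                raise TreeValidationError(
                    f"tip-age table missing species: {sorted(missing)}"
                )
            ages = {n: float(tip_ages[n]) for n in self.tip_names()}
        for node in self.postorder():
            if node.is_tip:
                node.age = ages[node.name]
                node.extinct = node.age > tip_age_tolerance
                if not node.extinct:
                    node.age = max(node.age, 0.0)
            else:
                node.age = max(c.age + c.length for c in node.children)

    # -- utilities -------------------------------------------------------
    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def tip_distances(self) -> Dict[frozenset, float]:
        """Patristic distance for every unordered tip pair."""
        below: Dict[int, Dict[str, float]] = {}
        dists: Dict[frozenset, float] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = {node.name: 0.0}
            else:
                left, right = node.children
                dl = {k: v + left.length for k, v in below[id(left)].items()}
                dr = {k: v + right.length for k, v in below[id(right)].items()}
                for a, da in dl.items():
                    for b, db in dr.items():
                        dists[frozenset((a, b))] = da + db
                dl.update(dr)
                below[id(node)] = dl
        return dists

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        target = frozenset(names)
        if not target:
            raise ValueError("mrca of an empty set is undefined")
        missing = target - self.clade_tips(self.root)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        node = self.root
        while not node.is_tip:
            next_node = None
            for child in node.children:
                ct = self.clade_tips(child)
                if target <= ct:
                    next_node = child
                    break
            if next_node is None:
                return node
            node = next_node
        return node

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.age = node.age
            new.range_ = node.range_
            new.extinct = node.extinct
            new.last_continent = node.last_continent
            return new

        new_root = clone(self.root)
        stack = [(self.root, new_root)]
        while stack:
            old, new = stack.pop()
            for c in old.children:
                nc = clone(c)
                new.add_child(nc)
                stack.append((c, nc))
        return PhyloTree(new_root, validate=False)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is None:
                length = 0.0
            else:
                raise TreeFormatError(
                    f"missing branch length above {label or 'an internal node'}"
                )
        return Node(label, length)

    root = convert(dtree.seed_node)
    stack = [(dtree.seed_node, root)]
    while stack:
        dnode, node = stack.pop()
        for dchild in dnode.child_nodes():
            child = node.add_child(convert(dchild))
            stack.append((dchild, child))
    return PhyloTree(root)


def read_newick(
    path_or_string: str | os.PathLike,
    tip_ages: Optional[Dict[str, float]] = None,
    tip_age_tolerance: float = 1e-6,
) -> PhyloTree:
    """Read a Newick tree (branch lengths mandatory) into a :class:`PhyloTree`.

    ``path_or_string`` may be a file path or a Newick string.  Tip ages are
    derived from path lengths (deepest tip = present) unless ``tip_ages``
    overrides them; tips older than ``tip_age_tolerance`` Ma are flagged
    extinct.
    """
    text: str
    if isinstance(path_or_string, str) and (
        path_or_string.lstrip().startswith("(")
        or path_or_string.rstrip().endswith(";")
    ):
        text = path_or_string
    else:
        with open(path_or_string) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeFormatError(f"could not parse Newick input: {exc}") from exc
    tree = _from_dendropy(dtree)
    tree.assign_ages(tip_ages, tip_age_tolerance)
    return tree


def _to_dendropy(tree: PhyloTree) -> "dendropy.Tree":
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    if tree.root.name:
        dtree.seed_node.label = tree.root.name
    stack = [(tree.root, dtree.seed_node)]
    while stack:
        node, dnode = stack.pop()
        for child in node.children:
            dchild = dnode.new_child(edge_length=child.length)
            if child.is_tip:
                dchild.taxon = taxa.new_taxon(child.name)
            elif child.name:
                dchild.label = child.name
            stack.append((child, dchild))
    return dtree


def write_newick(tree: PhyloTree, path: str | os.PathLike) -> None:
    """Write a tree as Newick with full float precision branch lengths."""
    dtree = _to_dendropy(tree)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
        unquoted_underscores=True,
    )
    with open(path, "w") as fh:
        fh.write(text)


def read_tip_ages(path: str | os.PathLike) -> Dict[str, float]:
    """Read a TSV tip-age table with columns ``species`` and ``age_Ma``."""
    ages: Dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["species", "age_Ma"]:
            raise TreeFormatError("tip-age table must have columns species, age_Ma")
        for line in fh:
            if not line.strip():
                continue
            name, age = line.split()[:2]
            ages[name] = float(age)
    return ages


# ---------------------------------------------------------------------------
# Lagrange-style geography table
# ---------------------------------------------------------------------------

class GeographyTable:
    """Species -> binary presence vector over areas (Lagrange dialect)."""

    def __init__(self, ranges: Dict[str, Range], areas: Sequence[str] = AREAS) -> None:
        self.areas = tuple(areas)
        self.ranges: Dict[str, Range] = {}
        for name, rng in ranges.items():
            self.ranges[name] = as_range(rng, self.areas)

    def __getitem__(self, name: str) -> Range:
        return self.ranges[name]

    def __contains__(self, name: str) -> bool:
        return name in self.ranges

    def __len__(self) -> int:
        return len(self.ranges)

    def species(self) -> List[str]:
        return list(self.ranges)


def read_geography(path: str | os.PathLike | io.StringIO) -> GeographyTable:
    """Read a Lagrange/PHYLIP-style geography file."""
    if isinstance(path, io.StringIO):
        lines = path.getvalue().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise TreeFormatError("empty geography file")
    header = lines[0].replace("(", " ").replace(")", " ").split()
    try:
        n_species, n_areas = int(header[0]), int(header[1])
    except (IndexError, ValueError) as exc:
        raise TreeFormatError(
            "geography header must be 'n_species n_areas (codes)'"
        ) from exc
    codes = header[2:]
    if len(codes) != n_areas:
        raise TreeFormatError(
            f"header declares {n_areas} areas but lists {len(codes)} codes"
        )
    ranges: Dict[str, Range] = {}
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise TreeFormatError(f"malformed geography row: {ln!r}")
        name, bits = parts
        if len(bits) != n_areas or set(bits) - {"0", "1"}:
            raise TreeFormatError(
                f"row for {name} must have exactly {n_areas} binary digits"
            )
        rng = frozenset(c for c, b in zip(codes, bits) if b == "1")
        if not rng:
            raise TreeValidationError(
                f"species {name} has an all-zero range (null ranges are not observable)"
            )
        ranges[name] = rng
    if len(ranges) != n_species:
        raise TreeFormatError(
            f"header declares {n_species} species but {len(ranges)} rows found"
        )
    return GeographyTable(ranges, codes)


def write_geography(table: GeographyTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(table)} {len(table.areas)} ({' '.join(table.areas)})\n")
        for name, rng in table.ranges.items():
            bits = "".join("1" if a in rng else "0" for a in table.areas)
            fh.write(f"{name} {bits}\n")


def bind_ranges(tree: PhyloTree, table: GeographyTable) -> PhyloTree:
    """Attach tip ranges from a geography table; tip label sets must match."""
    tip_set = set(tree.tip_names())
    table_set = set(table.species())
    missing = sorted(tip_set - table_set)
    extra = sorted(table_set - tip_set)
    if missing:
        raise TreeValidationError(f"geography table missing species: {missing}")
    if extra:
        raise TreeValidationError(f"geography table has extra species: {extra}")
    for t in tree.tips():
        t.range_ = table[t.name]
    return tree
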