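"""Dated phylogeny data model and Newick/Nexus input/output.

Trees are rooted and carry branch lengths in millions of years (my).
Internally a tree is stored as flat parent/length arrays with tips
occupying indices ``0..n_tips-1``; this layout keeps the pruning
likelihood and pairwise-distance computations used elsewhere fast and
allocation-free.  Parsing and Nexus handling are delegated to dendropy;
writing uses a 9-significant-digit Newick serializer so that
read/write round-trips preserve branch lengths to better than 1e-9
relative error.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "read_tree",
    "write_tree",
    "node_ages",
    "patristic_distance",
    "distance_matrix",
    "prune_to",
]

#: Ultrametricity tolerance (my).  Grafted trees accumulate floating point
#: drift, so tip depths are only required to agree to this level.
ULTRAMETRIC_TOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or invalid tree input."""


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in my.

    Attributes
    ----------
    parent : np.ndarray of int
        ``parent[i]`` is the parent node id of node ``i``; the root has -1.
    length : np.ndarray of float
        Branch length (my) above each node; 0 for the root.
    tip_labels : list of str
        Labels of tips ``0..n_tips-1`` in index order.
    """

    parent: np.ndarray
    length: np.ndarray
    tip_labels: list[str]
    children: list[list[int]] = field(init=False, repr=False)
    root: int = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.parent)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=float)
        if np.any(self.length < 0):
            raise TreeError("negative branch length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children = [[] for _ in range(n)]
        for i in range(n):
            p = int(self.parent[i])
            if p >= 0:
                self.children[p].append(i)
        labels = self.tip_labels
        if len(labels) != self.n_tips:
            raise TreeError("tip_labels length does not match number of tips")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if any((not lab) for lab in labels):
            raise TreeError("empty tip label")
        self._tip_index = {lab: i for i, lab in enumerate(labels)}
        # sanity: indices 0..n_tips-1 are exactly the leaves
        for i in range(self.n_tips):
            if self.children[i]:
                raise TreeError("tip indices must be leaves")
        self._postorder: np.ndarray | None = None
        self._depth: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    @property
    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path length (my) per node."""
        if self._depth is None:
            d = np.zeros(self.n_nodes)
            for v in self.postorder[::-1]:  # preorder
                p = self.parent[v]
                if p >= 0:
                    d[v] = d[p] + self.length[v]
            self._depth = d
        return self._depth

    def is_bifurcating(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def max_ultrametric_deviation(self) -> float:
        tip_depths = self.depths[: self.n_tips]
        return float(tip_depths.max() - tip_depths.min())

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        return self.max_ultrametric_deviation() <= tol

    def root_age(self) -> float:
        return float(self.depths[: self.n_tips].max())

    # ------------------------------------------------------------------
    def mrca(self, a: int, b: int) -> int:
        """Most recent common ancestor of two node ids."""
        seen = set()
        x = a
        while x >= 0:
            seen.add(x)
            x = int(self.parent[x])
        x = b
        while x not in seen:
            x = int(self.parent[x])
        return x

    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for v in self.postorder:
            if not self.children[v]:
                lab = _quote_label(self.tip_labels[v])
            else:
                lab = "(" + ",".join(parts.pop(c) for c in self.children[v]) + ")"
            if v == self.root:
                parts[v] = f"{lab}:{_fmt(self.length[v])}"
            else:
                parts[v] = f"{lab}:{_fmt(self.length[v])}"
        return parts[self.root] + ";"

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.length.copy(), list(self.tip_labels))


def _fmt(x: float) -> str:
    # 12 significant digits: 9 would allow up to 5e-9 relative rounding,
    # breaking the 1e-9 round-trip contract on branch lengths
    return format(float(x), ".12g")


_SAFE_LABEL = re.compile(r"^[\w\.\-\|/]+$")


def _quote_label(lab: str) -> str:
    if _SAFE_LABEL.match(lab):
        return lab
    return "'" + lab.replace("'", "''") + "'"


# ----------------------------------------------------------------------
# construction from nested node structures (used by simulators/grafting)


class MutableNode:
    """Lightweight mutable node used to build or edit trees."""

    __slots__ = ("children", "length", "label")

    def __init__(self, length: float = 0.0, label: str | None = None):
        self.children: list[MutableNode] = []
        self.length = float(length)
        self.label = label

    def add(self, child: "MutableNode") -> "MutableNode":
        self.children.append(child)
        return child


def from_nodes(root: MutableNode) -> Phylogeny:
    """Build a :class:`Phylogeny` from a :class:`MutableNode` tree."""
    tips: list[MutableNode] = []
    internals: list[MutableNode] = []
    stack = [root]
    order: list[MutableNode] = []
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(v.children)
    for v in order:
        (internals if v.children else tips).append(v)
    # preserve left-to-right tip order for readability
    tips = [v for v in _tips_in_order(root)]
    index: dict[int, int] = {}
    for i, v in enumerate(tips):
        index[id(v)] = i
    for j, v in enumerate(internals):
        index[id(v)] = len(tips) + j
    n = len(tips) + len(internals)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.zeros(n)
    labels = []
    for v in order:
        i = index[id(v)]
        length[i] = v.length
        for c in v.children:
            parent[index[id(c)]] = i
    for v in tips:
        labels.append(v.label if v.label is not None else f"t{index[id(v)]}")
    return Phylogeny(parent, length, labels)


def _tips_in_order(root: MutableNode):
    stack = [root]
    while stack:
        v = stack.pop()
        if not v.children:
            yield v
        else:
            stack.extend(reversed(v.children))


def to_nodes(tree: Phylogeny) -> MutableNode:
    """Convert a :class:`Phylogeny` to an editable :class:`MutableNode` tree."""
    nodes = [MutableNode(length=float(tree.length[i])) for i in range(tree.n_nodes)]
    for i, lab in enumerate(tree.tip_labels):
        nodes[i].label = lab
    for i in range(tree.n_nodes):
        p = int(tree.parent[i])
        if p >= 0:
            nodes[p].children.append(nodes[i])
    return nodes[tree.root]


# ----------------------------------------------------------------------
# parsing / writing


def read_tree(text: str) -> Phylogeny:
    """Parse a Newick or Nexus tree string into a :class:`Phylogeny`.

    The dialect is auto-detected: input starting with ``#NEXUS`` is read
    as a Nexus TREES block, anything else as Newick.  Polytomies are
    preserved.  Malformed input raises :class:`TreeError` carrying the
    parser's position diagnostics; duplicate tip labels raise a
    validation error.
    """
    stripped = text.lstrip()
    schema = "nexus" if stripped.upper().startswith("#NEXUS") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"could not parse {schema} tree: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree_file(path: str) -> Phylogeny:
    with open(path) as fh:
        return read_tree(fh.read())


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    root = MutableNode(length=dtree.seed_node.edge.length or 0.0)
    stack = [(dtree.seed_node, root)]
    while stack:
        dnode, mnode = stack.pop()
        if dnode.is_leaf():
            lab = dnode.taxon.label if dnode.taxon is not None else None
            if lab is None:
                raise TreeError("tip without label")
            mnode.label = lab
        for ch in dnode.child_nodes():
            bl = ch.edge.length
            if bl is None:
                raise TreeError("branch length missing")
            stack.append((ch, mnode.add(MutableNode(length=bl))))
    return from_nodes(root)


def write_tree(tree: Phylogeny, schema: str = "newick") -> str:
    """Serialize a tree as Newick or a minimal Nexus TREES block."""
    nwk = tree.to_newick()
    if schema == "newick":
        return nwk + "\n"
    if schema == "nexus":
        buf = io.StringIO()
        buf.write("#NEXUS\nBEGIN TREES;\n")
        buf.write(f"    TREE tree1 = [&R] {nwk}\n")
        buf.write("END;\n")
        return buf.getvalue()
    raise ValueError(f"unknown schema: {schema}")


# ----------------------------------------------------------------------
# queries


def node_ages(tree: Phylogeny, tol: float = ULTRAMETRIC_TOL) -> np.ndarray:
    """Node ages (my before present) for an ultrametric tree.

    Ages are the maximum root-to-tip depth minus each node's depth; tip
    ages are clamped to exactly 0.  A tree whose tip depths disagree by
    more than ``tol`` raises :class:`TreeError` reporting the deviation.
    """
    dev = tree.max_ultrametric_deviation()
    if dev > tol:
        raise TreeError(
            f"tree is not ultrametric: max tip-depth deviation {dev:g} my > {tol:g}"
        )
    ages = tree.root_age() - tree.depths
    ages[: tree.n_tips] = 0.0
    return ages


def patristic_distance(tree: Phylogeny, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two tips (my)."""
    ia, ib = tree.tip_id(a), tree.tip_id(b)
    if ia == ib:
        return 0.0
    m = tree.mrca(ia, ib)
    d = tree.depths
    return float(d[ia] + d[ib] - 2.0 * d[m])


def distance_matrix(tree: Phylogeny) -> np.ndarray:
    """All-pairs patristic distance matrix over tips (my), tip-index order.

    Computed in one postorder sweep: tips under different children of a
    node are separated by ``depth(a) + depth(b) - 2 depth(node)``.
    """
    n = tree.n_tips
    d = tree.depths
    out = np.zeros((n, n))
    tipsets: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if not tree.children[v]:
            tipsets[v] = np.array([v], dtype=np.int64)
            continue
        groups = [tipsets.pop(c) for c in tree.children[v]]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                dist = d[a][:, None] + d[b][None, :] - 2.0 * d[v]
                out[np.ix_(a, b)] = dist
                out[np.ix_(b, a)] = dist.T
        tipsets[v] = np.concatenate(groups)
    return out


def prune_to(tree: Phylogeny, labels: list[str], keep_root: bool = True) -> Phylogeny:
    """Restrict a tree to a subset of tips, suppressing unifurcations.

    With ``keep_root=True`` the original root depth is preserved (the
    root's stem towards the retained subtree is kept), so node depths of
    retained lineages are unchanged — the behaviour wanted when building
    clade-level trees for comparative regressions.
    """
    keep = set(labels)
    missing = keep - set(tree.tip_labels)
    if missing:
        raise KeyError(f"labels not on tree: {sorted(missing)}")
    root = to_nodes(tree)

    def rec(node: MutableNode) -> MutableNode | None:
        if not node.children:
            return node if node.label in keep else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length += node.length
            return child
        node.children = kept
        return node

    new_root = rec(root)
    if new_root is None:
        raise ValueError("no tips retained")
    if keep_root:
        new_root.length = 0.0 if new_root is root else new_root.length
    else:
        new_root.length = 0.0
    return from_nodes(new_root)
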