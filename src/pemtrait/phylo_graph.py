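"""Rooted, edge-weighted phylogenies and their influence matrices.

The influence matrix of a rooted tree is the binary tips x edges matrix whose
(t, e) entry is 1 iff edge e lies on the path from the root to tip t.  It is
the combinatorial core of the eigenvector-map construction: together with the
edge lengths it encodes both topology and divergence times, and its weighted
Gram matrix recovers the Brownian-motion covariance between tips.

This module also handles the geometry of held-out tips: a tip that is pruned
from the training tree is summarised by a :class:`TipLocation` (which training
edge it hangs off, and how far along that edge), which is all the information
needed to score it against a basis built on the training tips alone.

A brute-force shared-path-length oracle (:func:`path_length_matrix`) is kept
deliberately independent of the influence-matrix code path so the two can be
checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Node",
    "PhyloTree",
    "InfluenceMatrix",
    "TipLocation",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "prune_to",
    "influence_matrix",
    "locate_targets",
    "training_tip_location",
    "path_length_matrix",
]


class NewickParseError(ValueError):
    """Malformed Newick input; the message carries the offending position."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate labels, missing lengths, ...)."""


class Node:
    """A vertex of a rooted tree.

    ``length`` is the length of the edge to the parent (0.0 for the root).
    Children are kept in input (Newick) order; tip enumeration follows it.
    """

    __slots__ = ("label", "length", "parent", "children", "_min_tip")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []
        self._min_tip: str | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "internal"
        return f"<Node {kind} label={self.label!r} length={self.length}>"


class PhyloTree:
    """A rooted tree with branch lengths and uniquely labelled tips."""

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    # -- traversals ------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        """Tips in input (Newick left-to-right) order."""
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    # -- derived quantities ---------------------------------------------

    def depths(self) -> dict[int, float]:
        """Root-to-node path length, keyed by ``id(node)``."""
        d: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is not None:
                d[id(node)] = d[id(node.parent)] + node.length
        return d

    def edges(self) -> list[Node]:
        """Deterministic edge enumeration, one entry per non-root node.

        Preorder from the root; among siblings, the subtree containing the
        lexicographically smallest tip label comes first.  This fixes the
        column order of the influence matrix and hence the sign/order of the
        eigenbasis.
        """
        self._annotate_min_tips()
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.parent is not None:
                out.append(node)
            ordered = sorted(node.children, key=lambda c: c._min_tip)
            stack.extend(reversed(ordered))
        return out

    def edge_lengths(self) -> np.ndarray:
        return np.array([e.length for e in self.edges()], dtype=float)

    def _annotate_min_tips(self) -> None:
        for node in self.postorder():
            if node.is_tip:
                node._min_tip = node.label
            else:
                node._min_tip = min(c._min_tip for c in node.children)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.preorder():
            if node.is_tip:
                if not node.label:
                    raise TreeValidationError("unlabelled tip")
                if node.label in seen:
                    raise TreeValidationError(
                        f"duplicate tip label {node.label!r}"
                    )
                seen.add(node.label)
            if node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} above "
                    f"{node.label or 'internal node'}"
                )
            for child in node.children:
                if child.parent is not node:
                    raise TreeValidationError("broken parent pointer")
        if self.root.parent is not None:
            raise TreeValidationError("root has a parent")

    def tip_map(self) -> dict[str, Node]:
        return {t.label: t for t in self.tips()}


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string with branch lengths.

    Raises :class:`NewickParseError` (naming the character position where
    available) for malformed input and :class:`TreeValidationError` for
    structural problems such as duplicate tip labels or missing lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon" in str(exc):
            raise TreeValidationError(f"duplicate tip label: {exc}") from exc
        pos = ""
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        if line is not None:
            pos = f" (line {line}, column {col})"
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        if dnode.parent_node is None:
            length = 0.0
        else:
            if dnode.edge.length is None:
                label = _dendropy_label(dnode) or "internal node"
                raise TreeValidationError(f"missing branch length above {label}")
            length = float(dnode.edge.length)
        node = Node(label=_dendropy_label(dnode), length=length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return PhyloTree(convert(dtree.seed_node))


def _dendropy_label(dnode: dendropy.Node) -> str | None:
    if dnode.taxon is not None:
        return dnode.taxon.label
    return dnode.label


def write_newick(tree: PhyloTree) -> str:
    """Serialise to Newick, round-tripping branch lengths at full precision."""

    def fmt(node: Node) -> str:
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner})" + (node.label or "")
        else:
            s = node.label or ""
        if node.parent is not None:
            s += f":{node.length!r}"
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Pruning and tip location
# ---------------------------------------------------------------------------


@dataclass
class PruneResult:
    """A pruned tree plus the bookkeeping to map full-tree points onto it.

    ``edge_path`` maps ``id(full_node)`` -> ``(pruned_child, traversed)`` for
    every full-tree node lying on a pruned edge (including its bottom end):
    the point sits on the pruned edge ending at ``pruned_child``, at distance
    ``traversed`` from that edge's top.
    """

    tree: PhyloTree
    node_map: dict[int, Node] = field(default_factory=dict)
    edge_path: dict[int, tuple[Node, float]] = field(default_factory=dict)
    keep_counts: dict[int, int] = field(default_factory=dict)


def prune_to(tree: PhyloTree, keep_labels) -> PruneResult:
    """Restrict ``tree`` to ``keep_labels``.

    Tips outside the set are removed and resulting degree-2 vertices are
    suppressed with their edge lengths summed; the original root is always
    retained (a chain edge hanging from it is harmless downstream, since its
    influence-matrix column is constant and vanishes under centering).
    """
    keep = set(keep_labels)
    if not keep:
        raise TreeValidationError("empty set of tips to keep")
    tip_labels = set(tree.tip_labels())
    unknown = keep - tip_labels
    if unknown:
        raise TreeValidationError(f"unknown tip labels: {sorted(unknown)}")

    counts: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_tip:
            counts[id(node)] = 1 if node.label in keep else 0
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)

    def is_kept(node: Node) -> bool:
        if node is tree.root:
            return True
        if node.is_tip:
            return node.label in keep
        live = sum(1 for c in node.children if counts[id(c)] > 0)
        return live >= 2

    depths = tree.depths()
    result = PruneResult(tree=None, keep_counts=counts)  # type: ignore[arg-type]
    new_root = Node(label=tree.root.label, length=0.0)
    result.node_map[id(tree.root)] = new_root

    # Preorder guarantees a kept ancestor is processed before its kept
    # descendants, so the parent lookup below always succeeds.
    for node in tree.preorder():
        if node is tree.root or counts[id(node)] == 0 or not is_kept(node):
            continue
        chain: list[Node] = []
        anc = node.parent
        while not (anc is tree.root or is_kept(anc)):
            chain.append(anc)
            anc = anc.parent
        pruned_parent = result.node_map[id(anc)]
        length = depths[id(node)] - depths[id(anc)]
        pruned = Node(label=node.label, length=length)
        pruned_parent.add_child(pruned)
        result.node_map[id(node)] = pruned
        result.edge_path[id(node)] = (pruned, length)
        for link in chain:
            result.edge_path[id(link)] = (
                pruned,
                depths[id(link)] - depths[id(anc)],
            )

    result.tree = PhyloTree(new_root)
    return result


@dataclass(frozen=True)
class TipLocation:
    """Where a held-out tip attaches to the training tree.

    ``edge_index`` refers to the training tree's deterministic edge
    enumeration; ``traversed`` is the distance from that edge's top end to the
    attachment point (0 <= traversed <= edge length).  ``pendant`` is the
    dangling path length from the attachment point down to the tip itself; it
    is recorded for path-length bookkeeping but contributes nothing to point
    scores.
    """

    label: str
    edge_index: int
    traversed: float
    pendant: float


@dataclass
class InfluenceMatrix:
    """Binary tips x edges root-path indicator matrix of a training tree."""

    matrix: np.ndarray
    tip_labels: list[str]
    edge_lengths: np.ndarray
    tree: PhyloTree

    @property
    def n_tips(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.matrix.shape[1]


def influence_matrix(tree: PhyloTree, training_tips=None) -> InfluenceMatrix:
    """Build the influence matrix of ``tree`` restricted to ``training_tips``.

    The tree is pruned to the training tips first; rows follow the pruned
    tree's tip order (which preserves input order), columns follow the
    deterministic edge enumeration.
    """
    if training_tips is None:
        training_tips = tree.tip_labels()
    pruned = prune_to(tree, training_tips).tree
    edges = pruned.edges()
    index = {id(e): j for j, e in enumerate(edges)}
    tips = pruned.tips()
    mat = np.zeros((len(tips), len(edges)), dtype=float)
    for i, tip in enumerate(tips):
        node = tip
        while node.parent is not None:
            mat[i, index[id(node)]] = 1.0
            node = node.parent
    return InfluenceMatrix(
        matrix=mat,
        tip_labels=[t.label for t in tips],
        edge_lengths=np.array([e.length for e in edges], dtype=float),
        tree=pruned,
    )


def locate_targets(full_tree: PhyloTree, training_tips) -> list[TipLocation]:
    """Locate every non-training tip of ``full_tree`` on the training tree.

    The returned locations satisfy path-length conservation: root-to-
    attachment length plus pendant length equals the tip's depth in the full
    tree.
    """
    training = set(training_tips)
    pr = prune_to(full_tree, training)
    edges = pr.tree.edges()
    edge_index = {id(e): j for j, e in enumerate(edges)}
    depths = full_tree.depths()

    locations: list[TipLocation] = []
    for tip in full_tree.tips():
        if tip.label in training:
            continue
        anc = tip.parent
        while pr.keep_counts[id(anc)] == 0:
            anc = anc.parent
        pendant = depths[id(tip)] - depths[id(anc)]
        if anc is full_tree.root:
            # Grafted directly at the root: zero traversal on any root edge.
            root_child = pr.tree.edges()[0]
            locations.append(TipLocation(tip.label, edge_index[id(root_child)], 0.0, pendant))
            continue
        pruned_child, traversed = pr.edge_path[id(anc)]
        locations.append(
            TipLocation(tip.label, edge_index[id(pruned_child)], traversed, pendant)
        )
    return locations


def training_tip_location(infl: InfluenceMatrix, label: str) -> TipLocation:
    """The location of a training tip on its own tree (for self-consistency
    checks): its terminal edge, fully traversed, zero pendant."""
    edges = infl.tree.edges()
    for j, node in enumerate(edges):
        if node.is_tip and node.label == label:
            return TipLocation(label, j, node.length, 0.0)
    raise KeyError(f"{label!r} is not a training tip")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def path_length_matrix(tree: PhyloTree, tip_labels=None) -> np.ndarray:
    """Shared root-path length between every pair of tips (brute force).

    Entry (i, j) sums the lengths of edges common to the root paths of tips i
    and j; the diagonal holds tip depths.  Under Brownian motion this is the
    trait covariance matrix, and it must equal
    ``infl @ diag(lengths) @ infl.T`` — the two are computed by unrelated
    code on purpose.
    """
    if tip_labels is None:
        tip_labels = tree.tip_labels()
    tip_nodes = tree.tip_map()
    missing = [t for t in tip_labels if t not in tip_nodes]
    if missing:
        raise TreeValidationError(f"unknown tip labels: {missing}")

    paths: list[dict[int, float]] = []
    for label in tip_labels:
        node = tip_nodes[label]
        edges: dict[int, float] = {}
        while node.parent is not None:
            edges[id(node)] = node.length
            node = node.parent
        paths.append(edges)

    n = len(tip_labels)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i, n):
            shared = paths[i].keys() & paths[j].keys()
            total = sum(paths[i][k] for k in shared)
            out[i, j] = out[j, i] = total
    return out
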