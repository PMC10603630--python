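"""Dated-tree input/output, validation and manipulation.

The in-memory container is :class:`TimeTree`, a lightweight rooted tree
whose branch lengths are carried verbatim in million years (Ma).  Parsing
of newick and NEXUS (including ``translate`` tables) is delegated to
dendropy; everything downstream of parsing operates on :class:`TimeTree`.

Internal nodes are matched *across* trees (e.g. the members of a posterior
tree sample) by :class:`CladeKey` — the frozen set of descendant tip
labels — which is stable under topology-preserving branch-length changes.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "TimeTree",
    "TreeSample",
    "CladeKey",
    "parse_newick",
    "read_tree_sample",
    "prune_to_taxa",
    "mrca_node",
]

CladeKey = FrozenSet[str]


class TreeError(ValueError):
    """Raised for malformed or invalid tree input."""


@dataclass
class Node:
    id: int
    label: Optional[str] = None
    length: float = 0.0  # Ma; stem branch length (0.0 at the root)
    parent: Optional["Node"] = None
    children: List["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id}, {self.label!r})"


class TimeTree:
    """A rooted, dated phylogeny with unique tip labels.

    Branch lengths are in Ma and are never rescaled.  The tree may contain
    polytomies; operations that require a strictly binary tree (the
    biogeographic likelihoods) check for it explicitly via
    :meth:`require_binary`.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()
        self.validate()

    # -- construction / indexing -------------------------------------------------

    def _index(self) -> None:
        self.nodes: List[Node] = list(self.preorder())
        self.tips: List[Node] = [n for n in self.nodes if n.is_tip]
        self.tip_labels: List[str] = [t.label or "" for t in self.tips]
        self._tip_by_label: Dict[str, Node] = {t.label: t for t in self.tips}

    def validate(self) -> None:
        seen: Set[str] = set()
        for tip in self.tips:
            if not tip.label:
                raise TreeError("tip without a label")
            if tip.label in seen:
                raise TreeError(f"duplicate tip label: {tip.label!r}")
            seen.add(tip.label)
        for node in self.nodes:
            bl = node.length
            if bl != bl or bl in (float("inf"), float("-inf")):
                raise TreeError(f"non-finite branch length at {node!r}")
            if bl < 0:
                raise TreeError(f"negative branch length {bl} at {node!r}")
            if node is not self.root and bl == 0.0:
                warnings.warn(
                    f"zero-length branch at node {node.id}", stacklevel=3
                )

    # -- traversal ----------------------------------------------------------------

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    # -- queries ------------------------------------------------------------------

    def tip(self, label: str) -> Node:
        try:
            return self._tip_by_label[label]
        except KeyError:
            raise TreeError(f"unknown tip label: {label!r}") from None

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n is not self.root)

    def depth(self, node: Node) -> float:
        """Root-to-node path length in Ma."""
        d = 0.0
        while node.parent is not None:
            d += node.length
            node = node.parent
        return d

    def clade_key(self, node: Node) -> CladeKey:
        if node.is_tip:
            return frozenset([node.label])
        labels: List[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                labels.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(labels)

    def tip_descendant_counts(self) -> Dict[int, int]:
        """node id -> number of descendant tips (tips count as 1)."""
        counts: Dict[int, int] = {}
        for node in self.postorder():
            if node.is_tip:
                counts[node.id] = 1
            else:
                counts[node.id] = sum(counts[c.id] for c in node.children)
        return counts

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.nodes if not n.is_tip)

    def require_binary(self) -> None:
        if not self.is_binary():
            raise TreeError("operation requires a strictly binary tree")

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = [self.depth(t) for t in self.tips]
        return max(depths) - min(depths) <= tol * max(max(depths), 1.0)

    # -- serialization ------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt_label(label: str) -> str:
            if any(c in label for c in " ()[]:;,'"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def rec(node: Node) -> str:
            if node.is_tip:
                s = fmt_label(node.label)
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.parent is not None:
                s += f":{node.length:.17g}"
            return s

        return rec(self.root) + ";"

    def copy(self) -> "TimeTree":
        def rec(node: Node, parent: Optional[Node]) -> Node:
            clone = Node(node.id, node.label, node.length, parent)
            clone.children = [rec(c, clone) for c in node.children]
            return clone

        return TimeTree(rec(self.root, None))

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree({len(self.tips)} tips, total {self.total_length():.3g} Ma)"


class TreeSample:
    """An ordered sample of trees over an identical tip set."""

    def __init__(self, trees: Sequence[TimeTree]):
        if not trees:
            raise TreeError("empty tree sample")
        ref = set(trees[0].tip_labels)
        for i, t in enumerate(trees[1:], start=2):
            other = set(t.tip_labels)
            if other != ref:
                diff = sorted(ref.symmetric_difference(other))
                raise TreeError(
                    f"tree {i} has a different tip set; symmetric difference: {diff}"
                )
        self.trees: List[TimeTree] = list(trees)
        self.tip_labels = sorted(ref)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> TimeTree:
        return self.trees[i]


# ---------------------------------------------------------------------------
# parsing


def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    any_length = any(
        e.length is not None for e in dtree.preorder_edge_iter() if e.head_node.parent_node
    )
    counter = [0]

    def rec(dnode, parent: Optional[Node]) -> Node:
        counter[0] += 1
        label = None
        if dnode.is_leaf():
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            if not label:
                raise TreeError("unlabeled tip in input tree")
        length = dnode.edge.length
        if length is None:
            if parent is not None and any_length:
                raise TreeError(
                    f"missing branch length on an internal edge near {label or counter[0]}"
                )
            length = 0.0
        node = Node(counter[0], label, float(length), parent)
        node.children = [rec(c, node) for c in dnode.child_nodes()]
        return node

    return TimeTree(rec(dtree.seed_node, None))


def parse_newick(text: str, preserve_underscores: bool = True) -> TimeTree:
    """Parse a single rooted newick statement into a :class:`TimeTree`.

    Quoted labels are honored and ``[...]`` comments are stripped.
    Unquoted underscores are kept verbatim by default; pass
    ``preserve_underscores=False`` for the strict underscores-as-spaces
    newick dialect.  Duplicate tip labels and negative branch lengths
    raise :class:`TreeError`.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=preserve_underscores,
        )
    except Exception as exc:
        raise TreeError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree_sample(text: str, preserve_underscores: bool = True) -> TreeSample:
    """Read a multi-tree input: NEXUS TREES block or newline-delimited newick.

    NEXUS ``translate`` tables are applied so tips carry their taxon names.
    All trees must share one tip set.
    """
    stripped = text.lstrip()
    schema = "nexus" if stripped.upper().startswith("#NEXUS") else "newick"
    try:
        dlist = dendropy.TreeList.get(
            file=io.StringIO(text),
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=preserve_underscores,
        )
    except Exception as exc:
        raise TreeError(f"malformed tree sample input: {exc}") from exc
    if len(dlist) == 0:
        raise TreeError("no trees found in input")
    return TreeSample([_from_dendropy(t) for t in dlist])


# ---------------------------------------------------------------------------
# manipulation


def prune_to_taxa(tree: TimeTree, keep: Iterable[str]) -> TimeTree:
    """Restrict *tree* to the tips in *keep*, preserving path lengths.

    Degree-2 nodes created by the pruning are suppressed with their branch
    lengths summed.  The original root (and therefore the root height) is
    retained, so root-to-tip distances are unchanged — pruning to a single
    taxon yields an unbranched lineage whose length is that taxon's
    root-to-tip distance.
    """
    keep_set = set(keep)
    if not keep_set:
        raise TreeError("must keep at least one taxon")
    for label in keep_set:
        tree.tip(label)  # raises on unknown label

    def rec(node: Node) -> Optional[Node]:
        if node.is_tip:
            if node.label in keep_set:
                return Node(node.id, node.label, node.length)
            return None
        kept = [c for c in (rec(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1 and node.parent is not None:
            # suppress degree-2 node: fold this stem into the child's stem
            child = kept[0]
            child.length += node.length
            return child
        clone = Node(node.id, node.label, node.length)
        clone.children = kept
        for c in kept:
            c.parent = clone
        return clone

    new_root = rec(tree.root)
    assert new_root is not None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # suppressed nodes may leave 0-length root edge
        return TimeTree(new_root)


def mrca_node(tree: TimeTree, clade: Iterable[str]) -> Node:
    """Most recent common ancestor of the named tips (a single tip is its own MRCA)."""
    labels = list(clade)
    if not labels:
        raise TreeError("empty clade")
    paths = []
    for label in labels:
        node = tree.tip(label)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        paths.append(list(reversed(path)))
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidate = paths[0][depth]
        if all(p[depth] is candidate for p in paths):
            mrca = candidate
        else:
            break
    return mrca
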