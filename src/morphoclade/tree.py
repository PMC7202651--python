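"""Unrooted leaf-labelled trees and newick serialization.

Trees are stored as a plain adjacency map over integer node ids with labels
on the leaves, which keeps branch-swapping cheap. Topologies are compared
through their non-trivial bipartition sets: two trees on the same leaves are
equal iff their bipartition sets are equal. Each bipartition is held in
canonical form — the side that does *not* contain the lexicographically
smallest leaf.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy

__all__ = [
    "PhyloTree",
    "TreeError",
    "parse_newick",
    "write_newick",
    "tree_from_bipartitions",
    "robinson_foulds",
]

Bipartition = frozenset  # frozenset[str]: canonical side of a split


class TreeError(ValueError):
    """Malformed tree or invalid tree operation."""


class PhyloTree:
    """Unrooted tree; binary for search, polytomous for consensus."""

    __slots__ = ("adj", "leaf_label", "lengths", "_next_id", "_bip_cache")

    def __init__(self) -> None:
        self.adj: dict[int, list[int]] = {}
        self.leaf_label: dict[int, str] = {}
        self.lengths: dict[frozenset, float] = {}
        self._next_id = 0
        self._bip_cache: frozenset | None = None

    # -- construction --------------------------------------------------
    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = []
        if label is not None:
            self.leaf_label[nid] = label
        self._bip_cache = None
        return nid

    def add_edge(self, u: int, v: int, length: float | None = None) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)
        if length is not None:
            self.lengths[frozenset((u, v))] = length
        self._bip_cache = None

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        self.lengths.pop(frozenset((u, v)), None)
        self._bip_cache = None

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            self.remove_edge(u, v)
        del self.adj[u]
        self.leaf_label.pop(u, None)
        self._bip_cache = None

    def suppress_degree_two(self, u: int) -> None:
        """Splice out a degree-2 internal node, merging its two edges."""
        if u in self.leaf_label or len(self.adj[u]) != 2:
            return
        a, b = self.adj[u]
        la = self.lengths.get(frozenset((u, a)))
        lb = self.lengths.get(frozenset((u, b)))
        self.remove_node(u)
        length = None
        if la is not None and lb is not None:
            length = la + lb
        self.add_edge(a, b, length)

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {u: list(vs) for u, vs in self.adj.items()}
        t.leaf_label = dict(self.leaf_label)
        t.lengths = dict(self.lengths)
        t._next_id = self._next_id
        return t

    # -- basic queries --------------------------------------------------
    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_label)

    def leaf_labels(self) -> frozenset:
        return frozenset(self.leaf_label.values())

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u in sorted(self.adj):
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def is_binary(self) -> bool:
        return all(
            len(vs) == 3 for u, vs in self.adj.items() if u not in self.leaf_label
        ) and all(len(self.adj[u]) == 1 for u in self.leaf_label)

    def leaf_by_label(self, label: str) -> int:
        for nid, lab in self.leaf_label.items():
            if lab == label:
                return nid
        raise TreeError(f"no leaf labelled {label!r}")

    # -- bipartitions ----------------------------------------------------
    def _side_labels(self, u: int, v: int) -> frozenset:
        """Labels of leaves on the v side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            x = stack.pop()
            if x in self.leaf_label:
                out.append(self.leaf_label[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self) -> frozenset:
        """Canonical non-trivial splits (side omitting the smallest leaf)."""
        if self._bip_cache is not None:
            return self._bip_cache
        labels = self.leaf_labels()
        if len(labels) < 4:
            self._bip_cache = frozenset()
            return self._bip_cache
        ref = min(labels)
        out = set()
        for u, v in self.edges():
            if u in self.leaf_label or v in self.leaf_label:
                continue
            side = self._side_labels(u, v)
            if ref in side:
                side = labels - side
            if 2 <= len(side) <= len(labels) - 2:
                out.add(side)
        self._bip_cache = frozenset(out)
        return self._bip_cache

    def topology_key(self) -> tuple:
        return (self.leaf_labels(), self.bipartitions())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.topology_key() == other.topology_key()

    def __hash__(self) -> int:
        return hash(self.topology_key())

    # -- newick ----------------------------------------------------------
    def to_newick(
        self,
        support: Mapping[frozenset, str] | None = None,
        outgroup: str | None = None,
        lengths: bool = True,
    ) -> str:
        """Serialize, optionally labelling clades from a bipartition map.

        ``support`` maps canonical bipartitions to label strings written on
        the matching internal node. With ``outgroup`` the tree is written
        rooted on that leaf's pendant edge.
        """
        if not self.adj:
            raise TreeError("empty tree")
        labels = self.leaf_labels()
        ref = min(labels)
        if outgroup is not None:
            og = self.leaf_by_label(outgroup)
            top, start = og, self.adj[og][0]
        else:
            first = min(self.leaf_label)
            top, start = first, self.adj[first][0]

        def label_for(node_side: frozenset) -> str:
            if support is None:
                return ""
            side = node_side
            if ref in side:
                side = labels - side
            return support.get(side, "")

        def fmt_len(u: int, v: int) -> str:
            if not lengths:
                return ""
            bl = self.lengths.get(frozenset((u, v)))
            return "" if bl is None else f":{bl:.10g}"

        def recurse(node: int, parent: int) -> tuple[str, frozenset]:
            if node in self.leaf_label:
                lab = self.leaf_label[node].replace(" ", "_")
                return lab, frozenset({self.leaf_label[node]})
            parts, below = [], set()
            for child in self.adj[node]:
                if child == parent:
                    continue
                txt, side = recurse(child, node)
                parts.append(txt + fmt_len(node, child))
                below |= side
            side = frozenset(below)
            return "(" + ",".join(parts) + ")" + label_for(side), side

        inner, _ = recurse(start, top)
        top_lab = self.leaf_label[top].replace(" ", "_")
        return f"({top_lab}{fmt_len(top, start)},{inner});"

    def __repr__(self) -> str:
        return f"<PhyloTree n_leaves={len(self.leaf_label)}>"


# ----------------------------------------------------------------------
def parse_newick(text: str) -> PhyloTree:
    """Parse newick into an unrooted :class:`PhyloTree` (dendropy backend)."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise TreeError(f"newick parse failed: {exc}") from exc
    t = PhyloTree()
    ids: dict = {}

    def visit(dnode, parent_id):
        label = dnode.taxon.label if dnode.taxon is not None else None
        nid = t.new_node(label)
        ids[dnode] = nid
        if parent_id is not None:
            t.add_edge(parent_id, nid, dnode.edge.length)
        for child in dnode.child_nodes():
            visit(child, nid)

    visit(dtree.seed_node, None)
    # unroot: splice out a degree-2 seed node left by rooted input
    seed = ids[dtree.seed_node]
    if len(t.adj[seed]) == 2 and seed not in t.leaf_label:
        t.suppress_degree_two(seed)
    if len(t.leaf_label) < 2:
        raise TreeError("tree must have at least 2 leaves")
    if len(set(t.leaf_label.values())) != len(t.leaf_label):
        raise TreeError("duplicate leaf labels")
    return t


def write_newick(
    tree: PhyloTree,
    support: Mapping[frozenset, str] | None = None,
    outgroup: str | None = None,
    lengths: bool = True,
) -> str:
    return tree.to_newick(support=support, outgroup=outgroup, lengths=lengths)


# ----------------------------------------------------------------------
def tree_from_bipartitions(labels: Iterable[str], biparts: Iterable[frozenset]) -> PhyloTree:
    """Build the (possibly polytomous) tree displaying exactly ``biparts``.

    The bipartitions must be pairwise compatible and in canonical form
    (side omitting the smallest label).
    """
    labels = sorted(set(labels))
    ref = labels[0]
    clades = sorted({frozenset(b) for b in biparts}, key=len)
    for c in clades:
        if ref in c or not c or not c.issubset(labels):
            raise TreeError(f"non-canonical or foreign bipartition: {sorted(c)}")
    t = PhyloTree()
    root = t.new_node()
    clade_node: dict[frozenset, int] = {}
    # smallest-first: each clade's node exists before any superset's
    for clade in clades:
        clade_node[clade] = t.new_node()
    # attach each clade to its minimal strict superset (or the root)
    for clade in clades:
        host = root
        best = None
        for other in clades:
            if other is not clade and clade < other:
                if best is None or len(other) < len(best):
                    best = other
        if best is not None:
            host = clade_node[best]
        t.add_edge(clade_node[clade], host)
    for label in labels:
        leaf = t.new_node(label)
        host = root
        best = None
        for clade in clades:
            if label in clade and (best is None or len(clade) < len(best)):
                best = clade
        if best is not None:
            host = clade_node[best]
        t.add_edge(leaf, host)
    # a fully resolved set leaves the root ternary; suppress artifacts
    for node in list(t.adj):
        if node in t.adj:
            t.suppress_degree_two(node)
    return t


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (Robinson–Foulds) distance over bipartitions."""
    if t1.leaf_labels() != t2.leaf_labels():
        raise TreeError("trees must share the same leaf set")
    return len(t1.bipartitions() ^ t2.bipartitions())
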