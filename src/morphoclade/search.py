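"""Heuristic maximum-parsimony tree search and clade support.

The protocol mirrors a traditional TNT-style analysis: random-addition
Wagner starting trees, tree-bisection-reconnection (TBR) branch swapping
that accepts strictly shorter trees and accumulates equal-length trees up
to a hold limit per replicate, a global most-parsimonious-tree (MPT) pool
capped at ``max_trees``, strict consensus, bootstrap resampling with
absolute frequencies, and Bremer decay indices found by accumulating
suboptimal trees within L + k steps of the optimum.

All tie-breaking is by deterministic branch/tree ordering, so a fixed seed
reproduces every output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .matrix import CharacterMatrix, MatrixError
from .parsimony import EncodedMatrix, TreeSet, encode_matrix, tree_length
from .tree import PhyloTree, TreeError, tree_from_bipartitions

__all__ = [
    "SearchConfig",
    "CladeSupport",
    "wagner_build",
    "tbr_rearrangements",
    "heuristic_search",
    "strict_consensus",
    "bootstrap_support",
    "bremer_support",
    "TreeSet",
]

_OP_SEARCH, _OP_BOOT = 101, 103
_EPS = 1e-9


@dataclass
class SearchConfig:
    """Search settings; the defaults are a full TNT-style analysis.

    Tests and bootstrap inner searches override them downward — the
    protocol is preserved as a setting, not a hard-coded cost.
    """

    n_replicates: int = 1000
    hold_per_replicate: int = 1000
    max_trees: int = 99999
    seed: int = 0
    outgroup: str | None = None
    bootstrap_replicates: int = 5000
    bootstrap_inner_replicates: int = 10
    bootstrap_inner_hold: int = 10
    bremer_max_decay: int = 10
    bremer_hold: int = 20000

    def __post_init__(self) -> None:
        for name in (
            "n_replicates",
            "hold_per_replicate",
            "max_trees",
            "bootstrap_replicates",
            "bootstrap_inner_replicates",
            "bootstrap_inner_hold",
            "bremer_max_decay",
            "bremer_hold",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class CladeSupport:
    """Per-bipartition support values (bootstrap percent or Bremer decay).

    ``censored`` marks bipartitions whose Bremer decay hit the search depth
    and is therefore a lower bound ("≥ max_decay").
    """

    values: dict[frozenset, float]
    kind: str  # "bootstrap" | "bremer"
    replicates: int | None = None
    censored: frozenset = frozenset()

    def get(self, bipartition: frozenset, default: float = 0.0) -> float:
        return self.values.get(bipartition, default)

    def labels(self) -> dict[frozenset, str]:
        """Formatted node labels for newick annotation ("3+" marks a decay
        censored at the search depth; '+' keeps the label newick-safe)."""
        out = {}
        for bip, v in self.values.items():
            if self.kind == "bremer":
                txt = f"{int(v)}" if bip not in self.censored else f"{int(v)}+"
            else:
                txt = f"{v:g}"
            out[bip] = txt
        return out

    def to_tsv(self) -> str:
        lines = [f"# kind: {self.kind}"
                 + (f"\treplicates: {self.replicates}" if self.replicates else "")]
        lines.append("clade\tsupport")
        for bip in sorted(self.values, key=lambda b: (len(b), sorted(b))):
            mark = ">=" if bip in self.censored else ""
            lines.append(";".join(sorted(bip)) + f"\t{mark}{self.values[bip]:g}")
        return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
def wagner_build(
    m: CharacterMatrix | EncodedMatrix, addition_order: Sequence[str]
) -> PhyloTree:
    """Greedy stepwise-addition (Wagner) tree for a fixed taxon order.

    Each successive taxon is inserted on the branch minimizing the
    resulting Fitch length; ties go to the earliest branch in a
    deterministic traversal.
    """
    enc = m if isinstance(m, EncodedMatrix) else encode_matrix(m)
    order = list(addition_order)
    if sorted(order) != sorted(enc.taxon_labels):
        raise MatrixError("addition order must be a permutation of the taxa")
    if len(order) < 3:
        raise TreeError("need at least 3 taxa")

    tree = PhyloTree()
    center = tree.new_node()
    for lab in order[:3]:
        tree.add_edge(tree.new_node(lab), center)

    for lab in order[3:]:
        sub = _sub_encoded(enc, set(_leafset(tree)) | {lab})
        best_tree = None
        best_len = float("inf")
        for u, v in tree.edges():
            cand = tree.copy()
            cand.remove_edge(u, v)
            mid = cand.new_node()
            cand.add_edge(u, mid)
            cand.add_edge(mid, v)
            cand.add_edge(cand.new_node(lab), mid)
            L = tree_length(cand, sub).L
            if L < best_len - _EPS:
                best_tree, best_len = cand, L
        tree = best_tree
    return tree


def _leafset(tree: PhyloTree) -> frozenset:
    return tree.leaf_labels()


def _sub_encoded(enc: EncodedMatrix, labels: set) -> EncodedMatrix:
    rows = [enc.label_row[t] for t in sorted(labels)]
    return EncodedMatrix(
        taxon_labels=sorted(labels),
        char_ids=enc.char_ids,
        masks=enc.masks[rows],
        weights=enc.weights,
    )


# ----------------------------------------------------------------------
def tbr_rearrangements(tree: PhyloTree):
    """Yield every distinct TBR neighbor of a binary tree.

    Each branch is bisected; the two fragments are reconnected across every
    pair of attachment branches. The original topology is excluded and
    duplicates arising within one bisection are suppressed.
    """
    original = tree.bipartitions()
    for u, v in tree.edges():
        base = tree.copy()
        base.remove_edge(u, v)
        comp_u = _component(base, u)
        comp_v = _component(base, v)
        for end in (u, v):
            if end not in base.leaf_label and len(base.adj[end]) == 2:
                base.suppress_degree_two(end)
        frag_u = {n for n in comp_u if n in base.adj}
        frag_v = {n for n in comp_v if n in base.adj}
        points_u = _attachment_points(base, frag_u)
        points_v = _attachment_points(base, frag_v)
        seen = set()
        for pa in points_u:
            for pb in points_v:
                cand = base.copy()
                na = _materialize(cand, pa)
                nb = _materialize(cand, pb)
                cand.add_edge(na, nb)
                key = cand.bipartitions()
                if key == original or key in seen:
                    continue
                seen.add(key)
                yield cand


def _component(tree: PhyloTree, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in tree.adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def _attachment_points(tree: PhyloTree, nodes: set[int]):
    """Edges of the fragment, or the node itself for a 1–2 node fragment."""
    edges = [
        (a, b) for a, b in tree.edges() if a in nodes and b in nodes
    ]
    if not edges:
        # single node (a leaf, or an unsuppressed stub): attach directly
        return [("node", n) for n in sorted(nodes)][:1]
    return [("edge", e) for e in edges]


def _materialize(tree: PhyloTree, point) -> int:
    kind, payload = point
    if kind == "node":
        return payload
    u, v = payload
    tree.remove_edge(u, v)
    mid = tree.new_node()
    tree.add_edge(u, mid)
    tree.add_edge(mid, v)
    return mid


# ----------------------------------------------------------------------
def heuristic_search(
    m: CharacterMatrix, cfg: SearchConfig
) -> TreeSet:
    """Random-addition Wagner starts + TBR swapping, merged over replicates.

    Per replicate the pool holds at most ``hold_per_replicate`` equal-length
    trees; the merged pool is trimmed to the best length, deduplicated and
    capped at ``max_trees`` (overflow flagged).
    """
    enc = encode_matrix(m)
    if len(enc.taxon_labels) < 4:
        raise MatrixError("heuristic search needs at least 4 taxa")
    rng = np.random.default_rng([cfg.seed, _OP_SEARCH])
    global_pool: dict = {}
    global_len = float("inf")
    overflow = False

    for _rep in range(cfg.n_replicates):
        order = [
            enc.taxon_labels[i] for i in rng.permutation(len(enc.taxon_labels))
        ]
        start = wagner_build(enc, order)
        pool = {start.topology_key(): start}
        pool_len = tree_length(start, enc).L
        queue = [start]
        while queue:
            current = queue.pop(0)
            restart = False
            for nb in tbr_rearrangements(current):
                L = tree_length(nb, enc).L
                if L < pool_len - _EPS:
                    pool = {nb.topology_key(): nb}
                    pool_len = L
                    queue = [nb]
                    restart = True
                    break
                if (
                    abs(L - pool_len) <= _EPS
                    and len(pool) < cfg.hold_per_replicate
                    and nb.topology_key() not in pool
                ):
                    pool[nb.topology_key()] = nb
                    queue.append(nb)
            if restart:
                continue
        if pool_len < global_len - _EPS:
            global_len = pool_len
            global_pool = {}
            for key, t in pool.items():
                if len(global_pool) >= cfg.max_trees:
                    overflow = True
                    break
                global_pool[key] = t
        elif abs(pool_len - global_len) <= _EPS:
            for key, t in pool.items():
                if key not in global_pool:
                    if len(global_pool) >= cfg.max_trees:
                        overflow = True
                        break
                    global_pool[key] = t
    return TreeSet(
        trees=list(global_pool.values()), length=global_len, overflow=overflow
    )


# ----------------------------------------------------------------------
def strict_consensus(trees: Iterable[PhyloTree] | TreeSet) -> PhyloTree:
    """Tree displaying exactly the bipartitions common to every input."""
    tree_list = list(trees.trees if isinstance(trees, TreeSet) else trees)
    if not tree_list:
        raise TreeError("strict consensus of an empty tree set")
    leafset = tree_list[0].leaf_labels()
    for t in tree_list[1:]:
        if t.leaf_labels() != leafset:
            raise TreeError("all trees must share the same leaf set")
    common = tree_list[0].bipartitions()
    for t in tree_list[1:]:
        common = common & t.bipartitions()
    return tree_from_bipartitions(leafset, common)


# ----------------------------------------------------------------------
def bootstrap_support(m: CharacterMatrix, cfg: SearchConfig) -> CladeSupport:
    """Character bootstrap with standard absolute frequencies.

    Characters are resampled with replacement to the original count; each
    replicate runs a scaled-down heuristic search
    (``bootstrap_inner_replicates`` / ``bootstrap_inner_hold``) and a
    bipartition scores when it appears in the replicate's strict consensus.
    """
    rng = np.random.default_rng([cfg.seed, _OP_BOOT])
    counts: dict[frozenset, int] = {}
    for _rep in range(cfg.bootstrap_replicates):
        cols = rng.integers(0, m.n_chars, size=m.n_chars)
        resampled = m.resample_characters([int(c) for c in cols])
        inner = replace(
            cfg,
            n_replicates=cfg.bootstrap_inner_replicates,
            hold_per_replicate=cfg.bootstrap_inner_hold,
            max_trees=max(cfg.bootstrap_inner_hold * 10, 100),
            seed=int(rng.integers(2**31)),
        )
        mpts = heuristic_search(resampled, inner)
        for bip in strict_consensus(mpts).bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    values = {
        bip: 100.0 * c / cfg.bootstrap_replicates for bip, c in counts.items()
    }
    return CladeSupport(
        values=values, kind="bootstrap", replicates=cfg.bootstrap_replicates
    )


# ----------------------------------------------------------------------
def bremer_support(
    m: CharacterMatrix, mpts: TreeSet, cfg: SearchConfig
) -> CladeSupport:
    """Bremer decay by suboptimal-tree accumulation.

    Starting from the MPTs, TBR swapping accumulates every encountered tree
    of length ≤ L + max_decay (up to ``bremer_hold`` trees). The decay of a
    consensus bipartition is the smallest extra length at which some
    accumulated tree lacks it; bipartitions that survive to the depth limit
    are reported censored at max_decay.
    """
    if not mpts.trees:
        raise TreeError("empty tree set")
    enc = encode_matrix(m)
    best = mpts.length
    limit = best + cfg.bremer_max_decay
    consensus_bips = strict_consensus(mpts).bipartitions()

    seen: dict = {}
    queue: list[PhyloTree] = []
    for t in mpts.trees:
        seen[t.topology_key()] = (best, t.bipartitions())
        queue.append(t)
    while queue and len(seen) < cfg.bremer_hold:
        current = queue.pop(0)
        for nb in tbr_rearrangements(current):
            key = nb.topology_key()
            if key in seen:
                continue
            L = tree_length(nb, enc).L
            if L <= limit + _EPS:
                seen[key] = (L, nb.bipartitions())
                queue.append(nb)
                if len(seen) >= cfg.bremer_hold:
                    break

    values: dict[frozenset, float] = {}
    censored = set()
    for bip in consensus_bips:
        decay = None
        for L, bips in seen.values():
            if bip not in bips:
                extra = L - best
                if decay is None or extra < decay:
                    decay = extra
        if decay is None:
            values[bip] = float(cfg.bremer_max_decay)
            censored.add(bip)
        else:
            values[bip] = float(decay)
    return CladeSupport(
        values=values, kind="bremer", censored=frozenset(censored)
    )
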