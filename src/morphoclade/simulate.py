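"""Synthetic trees and Mk-model character matrices.

The generator emulates the structure of an empirical morphological matrix:
unordered multistate characters evolved independently on a known tree under
the k-state symmetric Markov (Mk) model, then degraded with a stated
fraction of missing cells and a stated fraction of polymorphic cells (a
scored cell gains one extra distinct state, mimicking ontogenetically
variable characters scored as multi-states).

Everything is deterministic under ``SimConfig.seed``: each operation draws
from its own named generator derived from (seed, operation tag), so calling
the stages separately or through :func:`simulate_dataset` gives identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import CharacterMatrix, MatrixError, StateSet
from .tree import PhyloTree, TreeError

__all__ = [
    "SimConfig",
    "simulate_tree",
    "evolve_matrix",
    "degrade_matrix",
    "make_clean_signal_matrix",
    "simulate_dataset",
]

# operation tags: independent substreams of the one user-facing seed
_OP_TREE, _OP_EVOLVE, _OP_DEGRADE = 11, 13, 17


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_taxa: int = 16
    n_chars: int = 100
    states_per_char: int | list[int] = 2
    rate: float = 0.3  # expected changes per unit branch length
    tree_model: str = "yule"  # or "uniform"
    branch_mean: float = 0.1  # exponential branch-length mean (uniform model)
    missing_fraction: float = 0.0
    polymorphic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise MatrixError("n_taxa must be at least 3")
        if self.n_chars < 1:
            raise MatrixError("n_chars must be at least 1")
        ks = (
            [self.states_per_char] * self.n_chars
            if isinstance(self.states_per_char, int)
            else list(self.states_per_char)
        )
        if len(ks) != self.n_chars or any(k < 2 for k in ks):
            raise MatrixError("states_per_char must be ≥ 2 for every character")
        if self.rate < 0:
            raise MatrixError("rate must be non-negative")
        if self.tree_model not in ("yule", "uniform"):
            raise MatrixError("tree_model must be 'yule' or 'uniform'")
        if not (0 <= self.missing_fraction < 1) or not (
            0 <= self.polymorphic_fraction < 1
        ):
            raise MatrixError("fractions must lie in [0, 1)")
        if self.missing_fraction + self.polymorphic_fraction >= 1:
            raise MatrixError("missing + polymorphic fraction must be < 1")

    @property
    def k_per_char(self) -> list[int]:
        if isinstance(self.states_per_char, int):
            return [self.states_per_char] * self.n_chars
        return list(self.states_per_char)


# ----------------------------------------------------------------------
def simulate_tree(cfg: SimConfig) -> PhyloTree:
    """Random binary tree with leaves t1..tN and positive branch lengths.

    Yule trees are grown as a pure-birth process and rescaled to unit
    root-to-tip height (so ``rate`` is expected changes per tree depth);
    the uniform model draws the topology uniformly over all labelled
    unrooted topologies (sequential random edge insertion) with i.i.d.
    exponential branch lengths.
    """
    rng = np.random.default_rng([cfg.seed, _OP_TREE])
    labels = [f"t{i + 1}" for i in range(cfg.n_taxa)]
    if cfg.tree_model == "yule":
        return _yule_tree(labels, rng)
    return _uniform_tree(labels, rng, cfg.branch_mean)


def _yule_tree(labels: list[str], rng: np.random.Generator) -> PhyloTree:
    n = len(labels)
    t = PhyloTree()
    root = t.new_node()
    # active lineage: (attachment node, birth time)
    now = 0.0
    active: list[tuple[int, float]] = [(root, 0.0), (root, 0.0)]
    while len(active) < n:
        now += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent, birth = active.pop(i)
        node = t.new_node()
        t.add_edge(parent, node, now - birth)
        active.append((node, now))
        active.append((node, now))
    now += rng.exponential(1.0 / n)
    height = now
    order = rng.permutation(n)
    for (parent, birth), lab_i in zip(active, order):
        leaf = t.new_node(labels[lab_i])
        t.add_edge(parent, leaf, now - birth)
    # rescale to unit root-to-tip height, then unroot
    t.lengths = {e: bl / height for e, bl in t.lengths.items()}
    t.suppress_degree_two(root)
    return t


def _uniform_tree(
    labels: list[str], rng: np.random.Generator, branch_mean: float
) -> PhyloTree:
    t = PhyloTree()
    center = t.new_node()
    for lab in labels[:3]:
        t.add_edge(t.new_node(lab), center)
    for lab in labels[3:]:
        edges = t.edges()
        u, v = edges[int(rng.integers(len(edges)))]
        t.remove_edge(u, v)
        mid = t.new_node()
        t.add_edge(u, mid)
        t.add_edge(mid, v)
        t.add_edge(t.new_node(lab), mid)
    for u, v in t.edges():
        t.lengths[frozenset((u, v))] = float(rng.exponential(branch_mean))
    return t


# ----------------------------------------------------------------------
def _p_change(rate: float, t: float, k: int) -> float:
    """Probability a k-state symmetric chain ends in a different state."""
    return (k - 1) / k * (1.0 - math.exp(-rate * t * k / (k - 1)))


def evolve_matrix(tree: PhyloTree, cfg: SimConfig) -> CharacterMatrix:
    """Evolve independent Mk characters along the tree's branches.

    Root states are uniform over the k states of each character; every cell
    of the result is scored and monomorphic.
    """
    rng = np.random.default_rng([cfg.seed, _OP_EVOLVE])
    for u, v in tree.edges():
        if frozenset((u, v)) not in tree.lengths:
            raise TreeError("evolve_matrix requires branch lengths on every edge")
    ks = np.asarray(cfg.k_per_char)
    nchar = cfg.n_chars
    labels = sorted(tree.leaf_label.values())

    top = min(tree.leaf_label)
    start = tree.adj[top][0]
    states: dict[int, np.ndarray] = {}
    # uniform root state, placed at the top leaf (the chain is reversible)
    states[top] = rng.integers(0, ks, size=nchar)

    def transition(parent_states: np.ndarray, t: float) -> np.ndarray:
        p = np.array([_p_change(cfg.rate, t, int(k)) for k in ks])
        change = rng.random(nchar) < p
        # new state uniform over the k-1 others
        shift = 1 + np.floor(rng.random(nchar) * (ks - 1)).astype(int)
        out = np.where(change, (parent_states + shift) % ks, parent_states)
        return out

    stack = [(start, top)]
    while stack:
        node, parent = stack.pop()
        t = tree.lengths[frozenset((node, parent))]
        states[node] = transition(states[parent], t)
        for child in tree.adj[node]:
            if child != parent:
                stack.append((child, node))

    leaf_states = {tree.leaf_label[nid]: states[nid] for nid in tree.leaf_label}
    cells = [
        [StateSet.of(int(leaf_states[lab][j])) for j in range(nchar)]
        for lab in labels
    ]
    return CharacterMatrix(
        taxon_labels=labels,
        char_ids=list(range(1, nchar + 1)),
        cells=cells,
    )


# ----------------------------------------------------------------------
def degrade_matrix(
    m: CharacterMatrix,
    missing_fraction: float,
    polymorphic_fraction: float,
    seed: int,
) -> CharacterMatrix:
    """Knock out cells to missing and upgrade others to polymorphic.

    Exactly ⌊missing_fraction × n_cells⌋ uniformly chosen cells become
    missing; a disjoint ⌊polymorphic_fraction × n_cells⌋ scored cells each
    gain one extra, uniformly drawn, distinct state.
    """
    if not (0 <= missing_fraction < 1) or not (0 <= polymorphic_fraction < 1):
        raise MatrixError("fractions must lie in [0, 1)")
    if missing_fraction + polymorphic_fraction >= 1:
        raise MatrixError("missing + polymorphic fraction must be < 1")
    rng = np.random.default_rng([seed, _OP_DEGRADE])
    n_cells = m.n_taxa * m.n_chars
    n_missing = int(missing_fraction * n_cells)
    n_poly = int(polymorphic_fraction * n_cells)

    chosen = rng.choice(n_cells, size=n_missing + n_poly, replace=False)
    missing_cells = set(int(c) for c in chosen[:n_missing])
    poly_cells = [int(c) for c in chosen[n_missing:]]

    cells = [list(row) for row in m.cells]
    universes = [m.observed_states(cid) for cid in m.char_ids]
    for c in missing_cells:
        i, j = divmod(c, m.n_chars)
        cells[i][j] = StateSet(is_missing=True)
    for c in poly_cells:
        i, j = divmod(c, m.n_chars)
        cell = cells[i][j]
        if not cell.is_scored:
            continue  # cannot happen: disjoint draw
        candidates = sorted(universes[j] - cell.states)
        if not candidates:
            candidates = [max(universes[j] | cell.states) + 1]
        extra = candidates[int(rng.integers(len(candidates)))]
        cells[i][j] = StateSet(states=cell.states | {extra})
    return CharacterMatrix(
        taxon_labels=list(m.taxon_labels),
        char_ids=list(m.char_ids),
        cells=cells,
        weights=list(m.weights),
        ordering=list(m.ordering),
    )


# ----------------------------------------------------------------------
def make_clean_signal_matrix(tree: PhyloTree, chars_per_edge: int = 1) -> CharacterMatrix:
    """Homoplasy-free binary matrix: one block of identical characters per
    internal edge, state 1 on one side of that edge's bipartition.

    On the generating tree every character fits perfectly (CI = RI = 1) and
    the tree is the unique most parsimonious topology.
    """
    if chars_per_edge < 1:
        raise MatrixError("chars_per_edge must be positive")
    labels = sorted(tree.leaf_label.values())
    ref = labels[0]
    columns: list[frozenset] = []
    for u, v in tree.edges():
        if u in tree.leaf_label or v in tree.leaf_label:
            continue
        side = tree._side_labels(u, v)
        if ref in side:
            side = tree.leaf_labels() - side
        columns.extend([side] * chars_per_edge)
    if not columns:
        raise TreeError("tree has no internal edges")
    cells = [
        [StateSet.of(1 if lab in side else 0) for side in columns]
        for lab in labels
    ]
    return CharacterMatrix(
        taxon_labels=labels,
        char_ids=list(range(1, len(columns) + 1)),
        cells=cells,
    )


# ----------------------------------------------------------------------
def simulate_dataset(cfg: SimConfig) -> tuple[PhyloTree, CharacterMatrix]:
    """tree → Mk matrix → degradation, all driven by ``cfg.seed``."""
    tree = simulate_tree(cfg)
    m = evolve_matrix(tree, cfg)
    if cfg.missing_fraction or cfg.polymorphic_fraction:
        m = degrade_matrix(
            m, cfg.missing_fraction, cfg.polymorphic_fraction, cfg.seed
        )
    return tree, m
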