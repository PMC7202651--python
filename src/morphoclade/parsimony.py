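"""Per-tree parsimony scoring for unordered multistate characters.

Tree length is computed with Fitch optimization generalized to ambiguity
sets: a polymorphic cell may be explained by any of its member states at no
cost, and missing/inapplicable cells are full wildcards over the observed
state universe of their character. Columns are encoded as integer bitmasks
so that all characters are scored in one vectorized pass per tree.

Also here: the per-character step bounds m_i (minimum over all trees, via a
minimum hitting set of the cell state-sets) and g_i (maximum, via the star
tree after majority resolution of ambiguous cells), the ensemble consistency
and retention indices built from them, ACCTRAN/DELTRAN synapomorphy mapping,
and two deliberately independent brute-force oracles (`sankoff_steps`,
`exhaustive_search`) used to validate the fast paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix, MatrixError, StateSet
from .tree import PhyloTree, TreeError

__all__ = [
    "TreeScore",
    "TreeSet",
    "EncodedMatrix",
    "encode_matrix",
    "fitch_steps",
    "sankoff_steps",
    "tree_length",
    "char_min_steps",
    "char_max_steps",
    "consistency_index",
    "retention_index",
    "score_tree",
    "synapomorphies",
    "SynapomorphyRecord",
    "enumerate_topologies",
    "exhaustive_search",
    "n_unrooted_topologies",
]


# ----------------------------------------------------------------------
@dataclass
class TreeScore:
    """Length and per-character decomposition of one tree's score."""

    L: float
    per_char_steps: np.ndarray  # int steps per active character
    char_ids: list[int]
    CI: float | None = None
    RI: float | None = None


@dataclass
class TreeSet:
    """Deduplicated collection of equally optimal trees."""

    trees: list[PhyloTree]
    length: float
    overflow: bool = False

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ----------------------------------------------------------------------
@dataclass
class EncodedMatrix:
    """Bitmask view of a matrix: masks[t, c] has bit s set iff state s allowed."""

    taxon_labels: list[str]
    char_ids: list[int]
    masks: np.ndarray  # (n_taxa, n_chars) int64
    weights: np.ndarray  # (n_chars,) float
    label_row: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_row:
            self.label_row = {t: i for i, t in enumerate(self.taxon_labels)}


def _cell_mask(cell: StateSet, universe_mask: int) -> int:
    if cell.is_scored:
        m = 0
        for s in cell.states:
            m |= 1 << s
        return m
    return universe_mask


def encode_matrix(m: CharacterMatrix) -> EncodedMatrix:
    masks = np.zeros((m.n_taxa, m.n_chars), dtype=np.int64)
    for j, cid in enumerate(m.char_ids):
        universe = 0
        for row in m.cells:
            if row[j].is_scored:
                for s in row[j].states:
                    if s > 62:
                        raise MatrixError("state codes above 62 unsupported")
                    universe |= 1 << s
        if universe == 0:
            universe = 1  # all-missing column: any single dummy state, 0 steps
        for i, row in enumerate(m.cells):
            masks[i, j] = _cell_mask(row[j], universe)
    return EncodedMatrix(
        taxon_labels=list(m.taxon_labels),
        char_ids=list(m.char_ids),
        masks=masks,
        weights=np.asarray(m.weights, dtype=float),
    )


# ----------------------------------------------------------------------
def _rooted_order(tree: PhyloTree) -> tuple[int, int, list[tuple[int, int]]]:
    """Root on the pendant edge of the smallest leaf; return postorder.

    Returns (top_leaf, start, postorder list of (node, parent)) where the
    traversal covers the component hanging off ``start`` away from the leaf.
    """
    top = min(tree.leaf_label)
    if not tree.adj[top]:
        raise TreeError("disconnected leaf")
    start = tree.adj[top][0]
    order: list[tuple[int, int]] = []
    stack = [(start, top, False)]
    while stack:
        node, parent, done = stack.pop()
        if done or node in tree.leaf_label:
            order.append((node, parent))
            continue
        stack.append((node, parent, True))
        for child in tree.adj[node]:
            if child != parent:
                stack.append((child, node, False))
    return top, start, order


def _fitch_pass(tree: PhyloTree, enc: EncodedMatrix) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Fitch down-pass; returns per-char steps and preliminary state masks."""
    top, start, order = _rooted_order(tree)
    nchar = enc.masks.shape[1]
    steps = np.zeros(nchar, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node, parent in order:
        if node in tree.leaf_label:
            sets[node] = enc.masks[enc.label_row[tree.leaf_label[node]]]
            continue
        cur = None
        for child in tree.adj[node]:
            if child == parent:
                continue
            m = sets[child]
            if cur is None:
                cur = m
            else:
                inter = cur & m
                conflict = inter == 0
                steps += conflict
                cur = np.where(conflict, cur | m, inter)
        sets[node] = cur
    top_mask = enc.masks[enc.label_row[tree.leaf_label[top]]]
    final = sets[start] & top_mask
    conflict = final == 0
    steps += conflict
    sets[top] = np.where(conflict, sets[start] | top_mask, final)
    return steps, sets


def tree_length(tree: PhyloTree, m: CharacterMatrix | EncodedMatrix) -> TreeScore:
    """Weighted Fitch length of a binary tree on the matrix's taxa."""
    enc = m if isinstance(m, EncodedMatrix) else encode_matrix(m)
    if tree.leaf_labels() != frozenset(enc.taxon_labels):
        raise TreeError("tree leaves do not match the matrix's taxa")
    if not tree.is_binary():
        raise TreeError("length is defined on binary trees")
    steps, _ = _fitch_pass(tree, enc)
    return TreeScore(
        L=float(np.dot(steps, enc.weights)),
        per_char_steps=steps,
        char_ids=list(enc.char_ids),
    )


def fitch_steps(tree: PhyloTree, column: dict[str, StateSet]) -> int:
    """Minimum changes for one character column on one binary tree."""
    m = CharacterMatrix(
        taxon_labels=list(column),
        char_ids=[1],
        cells=[[column[t]] for t in column],
    )
    return int(tree_length(tree, m).per_char_steps[0])


# ----------------------------------------------------------------------
def sankoff_steps(tree: PhyloTree, column: dict[str, StateSet]) -> int:
    """Unit-cost Sankoff dynamic program; brute-force oracle for Fitch.

    Kept deliberately independent of the bitmask path: explicit per-state
    cost vectors with min-plus propagation.
    """
    universe = sorted(set().union(*(c.states for c in column.values())) or {0})
    k = len(universe)
    index = {s: i for i, s in enumerate(universe)}
    INF = float("inf")

    def leaf_cost(cell: StateSet) -> list[float]:
        if not cell.is_scored:
            return [0.0] * k
        return [0.0 if s in cell.states else INF for s in universe]

    top, start, order = _rooted_order(tree)
    costs: dict[int, list[float]] = {}
    for node, parent in order:
        if node in tree.leaf_label:
            costs[node] = leaf_cost(column[tree.leaf_label[node]])
            continue
        total = [0.0] * k
        for child in tree.adj[node]:
            if child == parent:
                continue
            c = costs[child]
            cheapest = min(c)
            for i in range(k):
                total[i] += min(c[i], cheapest + 1.0)
        costs[node] = total
    top_cost = leaf_cost(column[tree.leaf_label[top]])
    child = costs[start]
    cheapest = min(child)
    best = min(
        top_cost[i] + min(child[i], cheapest + 1.0) for i in range(k)
    )
    return int(best)


# ----------------------------------------------------------------------
def char_min_steps(column: dict[str, StateSet] | list[StateSet]) -> int:
    """m_i: fewest steps attainable on any tree.

    Equals (size of a minimum hitting set of the scored cells' state-sets)
    minus one: a tree can be arranged so that each extra required state
    arises exactly once.
    """
    cells = list(column.values()) if isinstance(column, dict) else list(column)
    sets = [c.states for c in cells if c.is_scored]
    if not sets:
        return 0
    universe = sorted(set().union(*sets))
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            hit = set(combo)
            if all(s & hit for s in sets):
                return size - 1
    raise AssertionError("unreachable: universe always hits")


def char_max_steps(column: dict[str, StateSet] | list[StateSet]) -> int:
    """g_i: steps on the worst (star) tree.

    Each ambiguous cell is first resolved to whichever of its member states
    is most frequent among monomorphic scored cells (ties to the lowest
    state code); g_i is then the number of scored cells minus the largest
    resolved state class.
    """
    cells = list(column.values()) if isinstance(column, dict) else list(column)
    scored = [c for c in cells if c.is_scored]
    if not scored:
        return 0
    freq: dict[int, int] = {}
    for c in scored:
        if len(c.states) == 1:
            (s,) = c.states
            freq[s] = freq.get(s, 0) + 1
    resolved: list[int] = []
    for c in scored:
        if len(c.states) == 1:
            (s,) = c.states
        else:
            s = min(
                c.states,
                key=lambda x: (-freq.get(x, 0), x),
            )
        resolved.append(s)
    counts: dict[int, int] = {}
    for s in resolved:
        counts[s] = counts.get(s, 0) + 1
    return len(resolved) - max(counts.values())


# ----------------------------------------------------------------------
def _bounds(m: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    mins = np.array(
        [char_min_steps([row[j] for row in m.cells]) for j in range(m.n_chars)]
    )
    maxs = np.array(
        [char_max_steps([row[j] for row in m.cells]) for j in range(m.n_chars)]
    )
    return mins, maxs


def consistency_index(
    m: CharacterMatrix, score: TreeScore, informative_only: bool = False
) -> float | None:
    """CI = Σ m_i / L; with ``informative_only`` characters whose steps are
    forced (m_i = g_i) are removed from both numerator and denominator."""
    mins, maxs = _bounds(m)
    steps = score.per_char_steps.astype(float)
    w = np.asarray(m.weights)
    keep = np.ones(m.n_chars, dtype=bool)
    if informative_only:
        keep = mins != maxs
    L = float(np.dot(steps[keep], w[keep]))
    if L == 0:
        return None
    return float(np.dot(mins[keep], w[keep])) / L


def retention_index(m: CharacterMatrix, score: TreeScore) -> float | None:
    """RI = (Σ g_i − L) / (Σ g_i − Σ m_i); None when max = min (no room)."""
    mins, maxs = _bounds(m)
    w = np.asarray(m.weights)
    gsum = float(np.dot(maxs, w))
    msum = float(np.dot(mins, w))
    if gsum == msum:
        return None
    return (gsum - float(np.dot(score.per_char_steps, w))) / (gsum - msum)


def score_tree(tree: PhyloTree, m: CharacterMatrix) -> TreeScore:
    """Length plus ensemble CI and RI in one call."""
    score = tree_length(tree, m)
    score.CI = consistency_index(m, score)
    score.RI = retention_index(m, score)
    return score


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SynapomorphyRecord:
    """One reconstructed state change: character ``char_id`` changes
    ``from_state`` → ``to_state`` on the branch subtending ``clade``."""

    clade: frozenset
    char_id: int
    from_state: int
    to_state: int

    def notation(self) -> str:
        """Field-standard "(char–derived state)" citation, 1-based ids."""
        return f"({self.char_id}–{self.to_state})"


def synapomorphies(
    tree: PhyloTree,
    m: CharacterMatrix,
    outgroup: str,
    mode: str = "acctran",
) -> list[SynapomorphyRecord]:
    """Map character changes onto branches of a tree rooted on the outgroup.

    One most-parsimonious reconstruction per character is chosen by a
    unit-cost Sankoff backtrace. Ties are broken toward change (ACCTRAN:
    transformations accelerated toward the root) or, with
    ``mode="deltran"``, away from change (delayed onto terminal branches).
    The number of reported changes per character always equals that
    character's Fitch step count.
    """
    if mode not in ("acctran", "deltran"):
        raise ValueError("mode must be 'acctran' or 'deltran'")
    if outgroup not in tree.leaf_labels():
        raise TreeError(f"outgroup {outgroup!r} not in tree")
    if not tree.is_binary():
        raise TreeError("synapomorphy mapping requires a binary tree")

    og = tree.leaf_by_label(outgroup)
    root_child = tree.adj[og][0]
    # postorder below root_child, with og as its parent
    order: list[tuple[int, int]] = []
    stack = [(root_child, og, False)]
    while stack:
        node, parent, done = stack.pop()
        if done or node in tree.leaf_label:
            order.append((node, parent))
            continue
        stack.append((node, parent, True))
        for child in tree.adj[node]:
            if child != parent:
                stack.append((child, node, False))
    parent_of = {node: parent for node, parent in order}
    below: dict[int, frozenset] = {}
    for node, _parent in order:
        if node in tree.leaf_label:
            below[node] = frozenset({tree.leaf_label[node]})
        else:
            below[node] = frozenset().union(
                *(below[c] for c in tree.adj[node] if c != parent_of[node])
            )

    records: list[SynapomorphyRecord] = []
    INF = float("inf")
    for j, cid in enumerate(m.char_ids):
        cells = {t: m.cells[i][j] for i, t in enumerate(m.taxon_labels)}
        universe = sorted(set().union(*(c.states for c in cells.values())) or {0})
        k = len(universe)

        def leaf_cost(cell: StateSet) -> list[float]:
            if not cell.is_scored:
                return [0.0] * k
            return [0.0 if s in cell.states else INF for s in universe]

        costs: dict[int, list[float]] = {}
        for node, parent in order:
            if node in tree.leaf_label:
                costs[node] = leaf_cost(cells[tree.leaf_label[node]])
                continue
            total = [0.0] * k
            for child in tree.adj[node]:
                if child == parent:
                    continue
                c = costs[child]
                cheapest = min(c)
                for i in range(k):
                    total[i] += min(c[i], cheapest + 1.0)
            costs[node] = total

        og_cost = leaf_cost(cells[outgroup])
        child = costs[root_child]
        cheapest = min(child)

        def root_total(i: int) -> float:
            return og_cost[i] + min(child[i], cheapest + 1.0)

        root_state_i = min(range(k), key=lambda i: (root_total(i), i))

        # preorder assignment from root_child downward
        prefer_change = 1 if mode == "acctran" else 0

        def pick(node: int, parent_state_i: int) -> int:
            c = costs[node]
            cheapest_here = min(
                c[i] + (1.0 if i != parent_state_i else 0.0) for i in range(k)
            )
            cand = [
                i
                for i in range(k)
                if c[i] + (1.0 if i != parent_state_i else 0.0) == cheapest_here
            ]
            cand.sort(
                key=lambda i: (
                    (i == parent_state_i) if prefer_change else (i != parent_state_i),
                    i,
                )
            )
            return cand[0]

        assign: dict[int, int] = {og: root_state_i}
        stack2 = [(root_child, og)]
        while stack2:
            node, parent = stack2.pop()
            s = pick(node, assign[parent])
            assign[node] = s
            if s != assign[parent]:
                records.append(
                    SynapomorphyRecord(
                        clade=below[node],
                        char_id=cid,
                        from_state=universe[assign[parent]],
                        to_state=universe[s],
                    )
                )
            for ch in tree.adj[node]:
                if ch != parent:  # leaves included: pick() reads their costs
                    stack2.append((ch, node))
    return records


# ----------------------------------------------------------------------
def n_unrooted_topologies(n: int) -> int:
    """(2n−5)!! labelled unrooted binary topologies on n ≥ 3 leaves."""
    out = 1
    for k in range(3, n + 1):
        out *= 2 * k - 5
    return out


def enumerate_topologies(labels: list[str]):
    """Yield every unrooted binary topology on the given leaf labels."""
    labels = list(labels)
    if len(labels) < 3:
        raise TreeError("need at least 3 leaves to enumerate topologies")

    base = PhyloTree()
    center = base.new_node()
    for lab in labels[:3]:
        base.add_edge(base.new_node(lab), center)

    def grow(tree: PhyloTree, remaining: list[str]):
        if not remaining:
            yield tree
            return
        lab, rest = remaining[0], remaining[1:]
        for u, v in tree.edges():
            t = tree.copy()
            t.remove_edge(u, v)
            mid = t.new_node()
            t.add_edge(u, mid)
            t.add_edge(mid, v)
            t.add_edge(t.new_node(lab), mid)
            yield from grow(t, rest)

    yield from grow(base, labels[3:])


def exhaustive_search(m: CharacterMatrix, max_taxa: int = 9) -> TreeSet:
    """Score every topology; the oracle against which heuristics are checked."""
    n = m.n_taxa
    if n > max_taxa:
        raise MatrixError(
            f"{n} taxa would need {n_unrooted_topologies(n)} topologies; "
            f"exhaustive search is limited to {max_taxa}"
        )
    if n < 3:
        raise MatrixError("need at least 3 taxa")
    enc = encode_matrix(m)
    best: list[PhyloTree] = []
    best_len = float("inf")
    for tree in enumerate_topologies(list(m.taxon_labels)):
        L = tree_length(tree, enc).L
        if L < best_len - 1e-9:
            best, best_len = [tree], L
        elif abs(L - best_len) <= 1e-9:
            best.append(tree)
    return TreeSet(trees=best, length=best_len)
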