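"""Wagner addition, TBR neighborhoods, heuristic search, consensus, support."""

import numpy as np
import pytest

from morphoclade.matrix import CharacterMatrix
from morphoclade.parsimony import enumerate_topologies, exhaustive_search, tree_length
from morphoclade.search import (
    SearchConfig,
    bootstrap_support,
    bremer_support,
    heuristic_search,
    strict_consensus,
    tbr_rearrangements,
    wagner_build,
)
from morphoclade.simulate import SimConfig, simulate_dataset, simulate_tree
from morphoclade.tree import parse_newick

from conftest import matrix_from_rows


class TestWagnerBuild:
    def test_three_taxa_unique(self):
        m = matrix_from_rows({"A": ["0"], "B": ["1"], "C": ["0"]})
        t = wagner_build(m, ["B", "C", "A"])
        assert t.leaf_labels() == frozenset("ABC")

    def test_clean_signal_any_order_finds_true_tree(self, clean_fixture):
        """Greedy addition is optimal when there is no homoplasy."""
        tree, m = clean_fixture
        rng = np.random.default_rng(1)
        labels = list(m.taxon_labels)
        for _ in range(5):
            order = [labels[i] for i in rng.permutation(len(labels))]
            built = wagner_build(m, order)
            assert built.bipartitions() == tree.bipartitions()

    def test_deterministic_for_fixed_order(self):
        _, m = simulate_dataset(SimConfig(n_taxa=7, n_chars=20, rate=2.0, seed=2))
        order = list(m.taxon_labels)
        assert wagner_build(m, order).bipartitions() == wagner_build(m, order).bipartitions()

    def test_rejects_bad_order(self):
        _, m = simulate_dataset(SimConfig(n_taxa=5, n_chars=5, seed=0))
        with pytest.raises(Exception):
            wagner_build(m, ["t1", "t2"])


class TestTBR:
    def test_quartet_neighborhood_is_both_alternatives(self):
        t = parse_newick("((A,B),(C,D));")
        keys = {n.bipartitions() for n in tbr_rearrangements(t)}
        assert len(keys) == 2 and t.bipartitions() not in keys

    def test_five_taxon_neighborhood_size(self):
        """Distinct TBR neighbors at n=5 equal the 2(n−3)(2n−7) bound: one
        move preserves the splits internal to each fragment, so topologies
        sharing no split with the start tree are out of reach."""
        t = parse_newick("((A,B),C,(D,E));")
        keys = {n.bipartitions() for n in tbr_rearrangements(t)}
        assert len(keys) == 12

    @pytest.mark.parametrize("n", [6, 7])
    def test_contains_all_nni_neighbors(self, n):
        """Every topology at RF distance 2 (an NNI move) is a TBR neighbor."""
        tree = simulate_tree(SimConfig(n_taxa=n, n_chars=1, seed=n, tree_model="uniform"))
        neighborhood = {t.bipartitions() for t in tbr_rearrangements(tree)}
        labels = sorted(tree.leaf_label.values())
        nni = {
            t.bipartitions()
            for t in enumerate_topologies(labels)
            if len(t.bipartitions() ^ tree.bipartitions()) == 2
        }
        assert nni <= neighborhood

    def test_all_neighbors_binary_and_same_leaves(self):
        tree = simulate_tree(SimConfig(n_taxa=7, n_chars=1, seed=9))
        for nb in tbr_rearrangements(tree):
            assert nb.is_binary() and nb.leaf_labels() == tree.leaf_labels()


class TestHeuristicSearch:
    def test_matches_exhaustive_on_fuzzed_instances(self):
        """Length and topology sets agree with full enumeration at n=8."""
        for seed in range(8):
            _, m = simulate_dataset(
                SimConfig(n_taxa=8, n_chars=15, rate=1.0, seed=seed,
                          missing_fraction=0.2)
            )
            exact = exhaustive_search(m)
            found = heuristic_search(
                m, SearchConfig(n_replicates=3, hold_per_replicate=200, seed=seed)
            )
            assert found.length == exact.length
            if not found.overflow:
                assert {t.bipartitions() for t in found.trees} == {
                    t.bipartitions() for t in exact.trees
                }

    def test_clean_fixture_single_mpt(self, clean_fixture):
        tree, m = clean_fixture
        found = heuristic_search(m, SearchConfig(n_replicates=2, hold_per_replicate=10, seed=1))
        assert len(found) == 1 and found.trees[0].bipartitions() == tree.bipartitions()
        assert found.length == tree_length(tree, m).L

    def test_never_longer_than_wagner_start(self):
        _, m = simulate_dataset(SimConfig(n_taxa=8, n_chars=20, rate=2.0, seed=77))
        start = wagner_build(m, list(m.taxon_labels))
        found = heuristic_search(m, SearchConfig(n_replicates=1, hold_per_replicate=5, seed=0))
        assert found.length <= tree_length(start, m).L

    def test_deterministic_under_seed(self):
        _, m = simulate_dataset(SimConfig(n_taxa=7, n_chars=15, rate=1.5, seed=10))
        cfg = SearchConfig(n_replicates=2, hold_per_replicate=20, seed=42)
        a = heuristic_search(m, cfg)
        b = heuristic_search(m, cfg)
        assert a.length == b.length
        assert [t.bipartitions() for t in a.trees] == [t.bipartitions() for t in b.trees]

    def test_hold_limit_flags_overflow(self):
        m = matrix_from_rows({t: ["?"] for t in "ABCDEFG"})  # everything ties
        found = heuristic_search(
            m, SearchConfig(n_replicates=1, hold_per_replicate=50, max_trees=10, seed=0)
        )
        assert found.overflow and len(found) <= 50


class TestStrictConsensus:
    def test_single_tree_is_itself(self):
        t = parse_newick("((A,B),(C,D),E);")
        assert strict_consensus([t]).bipartitions() == t.bipartitions()

    def test_conflicting_resolution_collapses(self):
        t1 = parse_newick("(((A,B),C),(D,E));")
        t2 = parse_newick("(((B,C),A),(D,E));")
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == frozenset({frozenset({"D", "E"})})

    def test_bipartition_intersection_property_fuzzed(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            trees = [
                simulate_tree(SimConfig(n_taxa=7, n_chars=1,
                                        seed=int(rng.integers(2**31)),
                                        tree_model="uniform"))
                for _ in range(3)
            ]
            expected = trees[0].bipartitions() & trees[1].bipartitions() & trees[2].bipartitions()
            assert strict_consensus(trees).bipartitions() == expected

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(Exception):
            strict_consensus([parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));")])


class TestBootstrap:
    CFG = SearchConfig(
        n_replicates=2, hold_per_replicate=10, seed=7,
        bootstrap_replicates=30, bootstrap_inner_replicates=2, bootstrap_inner_hold=5,
    )

    def test_clean_signal_clades_strongly_supported(self, clean_fixture):
        tree, m = clean_fixture
        support = bootstrap_support(m, self.CFG)
        for bip in tree.bipartitions():
            assert support.get(bip) >= 95.0

    def test_uninformative_matrix_unsupported(self):
        m = matrix_from_rows({t: ["0", "0"] for t in "ABCDEF"})
        support = bootstrap_support(m, self.CFG)
        assert all(v < 100.0 for v in support.values.values())

    def test_deterministic_under_seed(self, clean_fixture):
        _, m = clean_fixture
        a = bootstrap_support(m, self.CFG)
        b = bootstrap_support(m, self.CFG)
        assert a.values == b.values

    def test_percentages_in_range(self, clean_fixture):
        _, m = clean_fixture
        support = bootstrap_support(m, self.CFG)
        assert all(0.0 <= v <= 100.0 for v in support.values.values())


class TestBremer:
    def _three_char_clade_matrix(self, labels="ABCDEF", clade="AB", n_chars=3):
        rows = {
            lab: ["1" if lab in clade else "0"] * n_chars + ["0"] * 5
            for lab in labels
        }
        return matrix_from_rows(rows)

    def test_decay_equals_supporting_characters(self):
        """A clade backed by exactly 3 uncontradicted binary characters
        needs 3 extra steps to break (verified against full enumeration)."""
        m = self._three_char_clade_matrix()
        mpts = exhaustive_search(m)
        support = bremer_support(m, mpts, SearchConfig(bremer_max_decay=6, seed=0))
        clade_bip = frozenset("CDEF")  # canonical side omits A
        assert support.values[clade_bip] == 3.0
        assert clade_bip not in support.censored
        # independent check: best tree lacking the clade over all 105 topologies
        from morphoclade.parsimony import enumerate_topologies, tree_length
        best_without = min(
            tree_length(t, m).L
            for t in enumerate_topologies(list("ABCDEF"))
            if clade_bip not in t.bipartitions()
        )
        assert best_without - mpts.length == 3.0

    def test_absent_bipartition_reports_zero(self):
        m = self._three_char_clade_matrix()
        mpts = exhaustive_search(m)
        support = bremer_support(m, mpts, SearchConfig(bremer_max_decay=6, seed=0))
        assert support.get(frozenset({"B", "C"})) == 0.0

    def test_invariant_under_taxon_relabeling(self):
        m = self._three_char_clade_matrix()
        mapping = dict(zip("ABCDEF", "FEDCBA"))
        m2 = CharacterMatrix(
            taxon_labels=[mapping[t] for t in m.taxon_labels],
            char_ids=list(m.char_ids),
            cells=[list(r) for r in m.cells],
        )
        cfg = SearchConfig(bremer_max_decay=6, seed=0)
        s1 = bremer_support(m, exhaustive_search(m), cfg)
        s2 = bremer_support(m2, exhaustive_search(m2), cfg)
        relabeled = {
            frozenset(mapping[x] for x in bip) for bip in s1.values
        }
        canonical = set()
        labels2 = frozenset(m2.taxon_labels)
        ref = min(labels2)
        for bip in relabeled:
            canonical.add(bip if ref not in bip else labels2 - bip)
        assert canonical == set(s2.values)
        assert sorted(s1.values.values()) == sorted(s2.values.values())

    def test_consensus_clades_have_positive_decay(self, clean_fixture):
        tree, m = clean_fixture
        mpts = heuristic_search(m, SearchConfig(n_replicates=1, hold_per_replicate=5, seed=0))
        support = bremer_support(m, mpts, SearchConfig(bremer_max_decay=3, seed=0))
        assert set(support.values) == set(tree.bipartitions())
        assert all(v >= 1.0 for v in support.values.values())
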