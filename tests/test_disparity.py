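"""MORD distances, PCoA with corrections, Foote partial disparity."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from morphoclade.disparity import (
    DistanceMatrix,
    Ordination,
    _gower,
    cailliez_correction,
    foote_partial_disparity,
    lingoes_correction,
    mord_matrix,
    morphospace_table,
    normalize_partial_disparities,
    pcoa,
    read_morphospace_table,
)
from morphoclade.matrix import GroupMap, MatrixError
from morphoclade.simulate import SimConfig, degrade_matrix, evolve_matrix, simulate_tree

from conftest import matrix_from_rows


class TestMord:
    def test_identical_rows_zero(self):
        m = matrix_from_rows({"X": ["0", "1", "2"], "Y": ["0", "1", "2"]})
        assert mord_matrix(m).d[0, 1] == 0.0

    def test_all_different_is_one(self):
        m = matrix_from_rows({"X": ["0", "0", "0", "0"], "Y": ["1", "1", "1", "1"]})
        assert mord_matrix(m).d[0, 1] == 1.0

    def test_hand_enumerated_pair(self):
        """Comparable chars {1,2,4}; dissimilarities 0,1,0 → d = 1/3."""
        m = matrix_from_rows({"X": ["0", "1", "?", "01"], "Y": ["0", "0", "1", "1"]})
        dm = mord_matrix(m)
        assert dm.comparable_counts[0, 1] == 3
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_polymorphic_overlap_option(self):
        m = matrix_from_rows({"X": ["01"], "Y": ["1"]})
        assert mord_matrix(m).d[0, 1] == 0.0
        assert mord_matrix(m, partial_overlap_score=0.5).d[0, 1] == 0.5

    def test_incomparable_pair_flagged(self):
        m = matrix_from_rows({"X": ["0", "?"], "Y": ["?", "1"], "Z": ["0", "1"]})
        dm = mord_matrix(m)
        assert ("X", "Y") in dm.incomputable_pairs

    def test_all_incomparable_rejected(self):
        m = matrix_from_rows({"X": ["0", "?"], "Y": ["?", "1"]})
        with pytest.raises(MatrixError):
            mord_matrix(m)

    def test_subset_equivalence(self):
        """MORD on a character subset equals MORD of the subsetted matrix."""
        from morphoclade.matrix import CharacterMatrix

        cfg = SimConfig(n_taxa=8, n_chars=30, states_per_char=3, rate=1.0, seed=21)
        m = degrade_matrix(evolve_matrix(simulate_tree(cfg), cfg), 0.2, 0.1, seed=2)
        ids = [3, 7, 11, 20, 28]
        cols = [m.char_ids.index(i) for i in ids]
        rebuilt = CharacterMatrix(
            taxon_labels=list(m.taxon_labels),
            char_ids=[1, 2, 3, 4, 5],
            cells=[[row[j] for j in cols] for row in m.cells],
        )
        np.testing.assert_allclose(
            mord_matrix(m.select_characters(ids)).d, mord_matrix(rebuilt).d
        )
        # dropping taxa does not renumber characters
        sub = m.select_taxa(drop=["t1"]).select_characters(ids)
        assert sub.char_ids == ids


class TestCorrections:
    def _toy(self):
        d = np.ones((4, 4))
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 2.5  # violates the triangle inequality
        return DistanceMatrix(labels=list("abcd"), d=d)

    def test_euclidean_matrix_unchanged(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(labels=list("abcde"), d=d)
        np.testing.assert_allclose(cailliez_correction(dm).d, d, atol=1e-7)
        np.testing.assert_allclose(lingoes_correction(dm).d, d, atol=1e-7)

    @pytest.mark.parametrize("correct", [cailliez_correction, lingoes_correction])
    def test_toy_becomes_embeddable(self, correct):
        fixed = correct(self._toy())
        eigs = np.linalg.eigvalsh(_gower(fixed.d))
        assert eigs.min() >= -1e-8

    def test_cailliez_preserves_rank_order(self):
        dm = self._toy()
        fixed = cailliez_correction(dm)
        iu = np.triu_indices(4, 1)
        assert list(np.argsort(dm.d[iu])) == list(np.argsort(fixed.d[iu]))


class TestPcoa:
    def test_two_points_closed_form(self):
        dm = DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 3.0], [3.0, 0.0]]))
        o = pcoa(dm)
        assert o.n_positive_axes == 1
        np.testing.assert_allclose(sorted(o.scores.ravel()), [-1.5, 1.5])
        np.testing.assert_allclose(o.eigenvalues, [4.5])

    def test_recovers_known_configuration(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        d = squareform(pdist(pts))
        o = pcoa(DistanceMatrix(labels=list("abcde"), d=d))
        np.testing.assert_allclose(squareform(pdist(o.scores)), d, atol=1e-9)

    def test_spectral_identity(self):
        pts = np.random.default_rng(2).normal(size=(6, 4))
        d = squareform(pdist(pts))
        o = pcoa(DistanceMatrix(labels=list("abcdef"), d=d))
        assert o.eigenvalues.sum() == pytest.approx((o.scores**2).sum())

    def test_matches_independent_implementation(self):
        """Eigenvalues and score geometry agree with scikit-bio's PCoA."""
        skbio = pytest.importorskip("skbio")
        cfg = SimConfig(n_taxa=7, n_chars=40, rate=1.0, seed=5)
        m = evolve_matrix(simulate_tree(cfg), cfg)
        dm = mord_matrix(m)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.d, ids=dm.labels)
        )
        k = ours.n_positive_axes
        np.testing.assert_allclose(
            np.sort(np.asarray(theirs.eigvals)[:k]), np.sort(ours.eigenvalues),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            squareform(pdist(np.asarray(theirs.samples)[:, :k])),
            squareform(pdist(ours.scores)),
            atol=1e-8,
        )

    def test_sign_convention_deterministic(self):
        pts = np.random.default_rng(3).normal(size=(5, 2))
        d = squareform(pdist(pts))
        a = pcoa(DistanceMatrix(labels=list("abcde"), d=d))
        b = pcoa(DistanceMatrix(labels=list("abcde"), d=d))
        np.testing.assert_array_equal(a.scores, b.scores)


class TestPartialDisparity:
    def _groups(self, mapping):
        return GroupMap(genus=dict(mapping), tribe={k: "T" for k in mapping})

    def test_single_group_is_hundred_percent(self):
        o = Ordination(labels=["a", "b", "c"],
                       scores=np.array([[1.0], [0.0], [-1.0]]),
                       eigenvalues=np.array([2.0]))
        table = foote_partial_disparity(o, self._groups({"a": "G", "b": "G", "c": "G"}))
        assert table.table.loc["G", "pd_percent"] == pytest.approx(100.0)

    def test_two_points_hand_computed(self):
        o = Ordination(labels=["a", "b"], scores=np.array([[1.0], [-1.0]]),
                       eigenvalues=np.array([2.0]))
        table = foote_partial_disparity(o, self._groups({"a": "G1", "b": "G2"}))
        assert table.table.loc["G1", "pd"] == pytest.approx(1.0)
        assert table.total == pytest.approx(2.0)
        assert table.table.pd_percent.tolist() == pytest.approx([50.0, 50.0])

    def test_partition_is_exact_conservation(self):
        cfg = SimConfig(n_taxa=12, n_chars=60, states_per_char=3, rate=1.0, seed=31)
        m = evolve_matrix(simulate_tree(cfg), cfg)
        o = pcoa(mord_matrix(m), correction="cailliez")
        groups = self._groups({f"t{i+1}": f"G{i % 3}" for i in range(12)})
        table = foote_partial_disparity(o, groups)
        assert table.table.pd.sum() == pytest.approx(table.total, abs=1e-12)
        assert table.table.pd_percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_invariance_under_sign_flip_and_reorder(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(6, 3))
        labels = list("abcdef")
        groups = self._groups({l: ("G1" if l < "d" else "G2") for l in labels})
        ev = np.array([3.0, 2.0, 1.0])
        t1 = foote_partial_disparity(Ordination(labels, scores, ev), groups)
        flipped = scores * np.array([1, -1, 1])
        perm = [3, 1, 4, 0, 5, 2]
        t2 = foote_partial_disparity(
            Ordination([labels[i] for i in perm], flipped[perm], ev), groups
        )
        for g in ("G1", "G2"):
            assert t1.table.loc[g, "pd"] == pytest.approx(t2.table.loc[g, "pd"])

    def test_symmetric_groups_equal_disparity(self):
        scores = np.array([[2.0, 1.0], [1.0, -1.0], [-2.0, -1.0], [-1.0, 1.0]])
        groups = self._groups({"a": "G1", "b": "G1", "c": "G2", "d": "G2"})
        table = foote_partial_disparity(
            Ordination(list("abcd"), scores, np.array([5.0, 2.0])), groups
        )
        assert table.table.loc["G1", "pd"] == pytest.approx(table.table.loc["G2", "pd"])

    def test_axis_cap_applied(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(5, 4))
        o = Ordination(list("abcde"), scores, np.arange(4.0, 0.0, -1.0))
        groups = self._groups({l: "G" for l in "abcde"})
        t_capped = foote_partial_disparity(o, groups, axis_cap=2)
        assert t_capped.axis_cap == 2
        t_all = foote_partial_disparity(o, groups, axis_cap=10)
        assert t_all.axis_cap == 4  # only 4 positive axes available
        assert t_capped.total < t_all.total

    def test_unmapped_otu_rejected(self):
        o = Ordination(["a", "b"], np.array([[1.0], [-1.0]]), np.array([2.0]))
        with pytest.raises(MatrixError):
            foote_partial_disparity(o, self._groups({"a": "G"}))

    def test_normalization_arm_validates_coverage(self):
        with pytest.raises(MatrixError):
            normalize_partial_disparities({"G": 1.0}, {"H": 2})


class TestMorphospaceTable:
    def _ordination(self):
        cfg = SimConfig(n_taxa=6, n_chars=40, rate=1.0, seed=8)
        m = evolve_matrix(simulate_tree(cfg), cfg)
        return pcoa(mord_matrix(m), correction="cailliez")

    def test_row_count_and_variance_bound(self):
        o = self._ordination()
        text = morphospace_table(o)
        rows = [l for l in text.splitlines() if not l.startswith(("#", "otu"))]
        assert len(rows) == len(o.labels)
        ve_line = next(l for l in text.splitlines() if "variance" in l)
        assert sum(float(v) for v in ve_line.split("\t")[1:]) <= 100.0 + 1e-9

    def test_roundtrip_reproduces_partial_disparity(self):
        o = self._ordination()
        groups = GroupMap(
            genus={l: ("G1" if i < 3 else "G2") for i, l in enumerate(o.labels)},
            tribe={l: "T" for l in o.labels},
        )
        direct = foote_partial_disparity(o, groups, axis_cap=10)
        back, _ = read_morphospace_table(morphospace_table(o, groups, axis_cap=10))
        again = foote_partial_disparity(back, groups, axis_cap=10)
        for g in direct.table.index:
            assert again.table.loc[g, "pd"] == direct.table.loc[g, "pd"]
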