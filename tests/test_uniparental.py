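"""Y-site filters, Hamming distances, NJ exactness and haplogroup tables."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bubbscan.simulate import simulate_y_matrix
from bubbscan.uniparental import (CladeAssignment, YMatrix, assign_clades,
                                  filter_y_sites, hamming_matrix,
                                  haplogroup_frequencies, nj_tree)


class TestFilterYSites:
    def _inputs(self):
        # 4 males x 5 sites, haploid-coded
        calls = np.array([
            [0, 1, 0, 1, -1],
            [0, 1, 1, 1, -1],
            [1, 0, 0, 1, 0],
            [1, 0, 1, 1, 0],
        ], dtype=np.int8)
        female = np.array([False, True, False, False, False])
        het = np.array([False, False, True, False, False])
        return calls, female, het

    def test_female_shared_site_removed(self):
        calls, female, het = self._inputs()
        ym, report = filter_y_sites(calls, female, het, max_missing=0.6)
        assert report["removed_in_females"] == 1
        assert "site_1" not in ym.site_ids

    def test_heterozygous_site_removed(self):
        calls, female, het = self._inputs()
        ym, _ = filter_y_sites(calls, female, het, max_missing=0.6)
        assert "site_2" not in ym.site_ids

    def test_call_rate_below_95pct_removed(self):
        """A site called in 37/40 males (92.5%) fails the 95% call-rate rule."""
        calls = np.zeros((40, 2), dtype=np.int8)
        calls[:3, 0] = -1  # 92.5% call rate
        calls[:, 1] = 1
        ym, report = filter_y_sites(calls, np.array([False, False]))
        assert report["removed_low_call_rate"] == 1
        assert ym.calls.shape[1] == 1

    def test_empty_result_raises_with_attrition(self):
        calls, female, het = self._inputs()
        with pytest.raises(ValueError, match="removed_in_females"):
            filter_y_sites(calls, np.ones(5, dtype=bool), het)

    @given(order=st.permutations([0, 1, 2]))
    def test_filters_commute(self, order):
        """Applying the three site filters in any order keeps the same set."""
        calls, female, het = self._inputs()
        missing_ok = np.mean(calls == -1, axis=0) <= 0.05
        masks = [~female, ~het, missing_ok]
        kept = np.ones(5, dtype=bool)
        for k in order:
            kept &= masks[k]
        ym, _ = filter_y_sites(calls, female, het, max_missing=0.05)
        assert ym.calls.shape[1] == kept.sum()


class TestHammingMatrix:
    def test_identical_haplotypes_zero(self):
        ym = YMatrix(np.array([[0, 1, 1], [0, 1, 1]], dtype=np.int8), ["a", "b"])
        assert hamming_matrix(ym)[0, 1] == 0.0

    def test_two_clade_structure(self):
        calls, truth = simulate_y_matrix(10, (5, 5), 8, seed=1)
        d = hamming_matrix(YMatrix(calls, [f"m{i}" for i in range(10)]))
        within = d[0, 1]
        between = d[0, 7]
        assert between > within

    def test_missing_aware_normalisation_brute_force(self, rng):
        calls = rng.integers(0, 2, size=(6, 30)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.2] = -1
        ym = YMatrix(calls, [f"m{i}" for i in range(6)])
        d = hamming_matrix(ym)
        for i in range(6):
            for j in range(6):
                shared = diff = 0
                for s in range(30):
                    if calls[i, s] != -1 and calls[j, s] != -1:
                        shared += 1
                        diff += calls[i, s] != calls[j, s]
                expected = diff / shared if shared else np.nan
                if i == j:
                    expected = 0.0
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


def _patristic(newick: str) -> dict[frozenset, float]:
    """Tip-to-tip path lengths via scikit-bio's tree parser."""
    import skbio

    tree = skbio.TreeNode.read(io.StringIO(newick))
    tips = [t.name for t in tree.tips()]
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[frozenset((a, b))] = tree.find(a).distance(tree.find(b))
    return out


class TestNjTree:
    def test_three_taxon_closed_form(self):
        """d(A,B)=2, d(A,C)=4, d(B,C)=4 -> branches A:1, B:1, C:3."""
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(d, ["A", "B", "C"])
        pat = _patristic(tree.newick())
        assert pat[frozenset(("A", "B"))] == pytest.approx(2.0, abs=1e-9)
        assert pat[frozenset(("A", "C"))] == pytest.approx(4.0, abs=1e-9)
        assert pat[frozenset(("B", "C"))] == pytest.approx(4.0, abs=1e-9)

    def test_additive_four_taxon_exact(self):
        """An additive metric from ((A:2,B:3):1,(C:4,D:5)) is recovered with
        exact path lengths (additivity oracle)."""
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ], dtype=float)
        tree = nj_tree(d, labels)
        pat = _patristic(tree.newick())
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert pat[frozenset((a, b))] == pytest.approx(
                    d[labels.index(a), labels.index(b)], abs=1e-9)

    def test_agrees_with_skbio_on_additive_metric(self):
        import skbio

        labels = ["A", "B", "C", "D", "E"]
        # additive metric from a random tree with positive branch lengths
        ref = skbio.TreeNode.read(io.StringIO(
            "((A:1.5,B:2.5):0.7,(C:1.1,(D:0.9,E:2.2):0.4):0.3);"))
        d = np.zeros((5, 5))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d[i, j] = d[j, i] = ref.find(a).distance(ref.find(b))
        mine = _patristic(nj_tree(d, labels).newick())
        theirs = _patristic(str(skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))))
        for pair, val in mine.items():
            assert val == pytest.approx(theirs[pair], abs=1e-9)

    def test_two_taxa_single_edge(self):
        tree = nj_tree(np.array([[0.0, 3.0], [3.0, 0.0]]), ["A", "B"])
        pat = _patristic(tree.newick())
        assert pat[frozenset(("A", "B"))] == pytest.approx(3.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1.0], [2.0, 0]]), ["A", "B"])


class TestAssignClades:
    def test_simulated_two_clades_fully_recovered(self):
        calls, truth = simulate_y_matrix(24, (14, 10), 15, seed=2)
        males = [f"m{i}" for i in range(24)]
        ym = YMatrix(calls, males)
        tree = nj_tree(hamming_matrix(ym), males)
        assign = assign_clades(tree)
        # labels must match truth up to H1/H2 relabeling
        truth_sets = {frozenset(m for m, c in zip(males, truth.clades) if c == lab)
                      for lab in ("clade1", "clade2")}
        got_sets = {frozenset(m for m, h in assign.labels.items() if h == lab)
                    for lab in ("H1", "H2")}
        assert truth_sets == got_sets

    def test_outgroup_excluded_from_labels(self):
        calls, _ = simulate_y_matrix(10, (5, 5), 8, seed=3)
        males = [f"m{i}" for i in range(10)]
        tree = nj_tree(hamming_matrix(YMatrix(calls, males)), males)
        assign = assign_clades(tree, outgroup="m0")
        assert "m0" not in assign.labels
        assert len(assign.labels) == 9

    def test_star_tree_warns(self):
        d = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(d, list("ABCD"))
        with pytest.warns(UserWarning, match="star"):
            assign_clades(tree)


class TestHaplogroupFrequencies:
    def _assign(self, labels):
        return CladeAssignment(labels, tree=None, split_edge_length=1.0)

    def test_single_clade_hundred_percent(self):
        assign = self._assign({f"m{i}": "H1" for i in range(5)})
        out = haplogroup_frequencies(assign, {f"m{i}": "G" for i in range(5)})
        assert out.loc[0, "H1_pct"] == 100.0

    def test_truth_labelled_exact_proportions(self):
        labels = {"a": "H1", "b": "H1", "c": "H2", "d": "H1"}
        groups = {"a": "north", "b": "north", "c": "north", "d": "south"}
        out = haplogroup_frequencies(self._assign(labels), groups).set_index("group")
        assert out.loc["north", "H1_pct"] == pytest.approx(66.67)
        assert out.loc["north", "H2_pct"] == pytest.approx(33.33)
        assert out.loc["south", "H1_pct"] == 100.0

    @given(n1=st.integers(1, 30), n2=st.integers(0, 30))
    def test_percentages_sum_to_hundred(self, n1, n2):
        labels = {f"m{i}": ("H1" if i < n1 else "H2") for i in range(n1 + n2)}
        out = haplogroup_frequencies(self._assign(labels),
                                     {m: "G" for m in labels})
        pct_cols = [c for c in out.columns if c.endswith("_pct")]
        assert out[pct_cols].sum(axis=1).iloc[0] == pytest.approx(100, abs=0.011)

    def test_study_scale_panel_reproduces_printed_percentages(self):
        """A synthetic stand-in panel with the study's group compositions
        (46 Yangtze males 35/11, 39 SC+SEA males 6/33) reproduces the
        dominant-haplogroup percentages 76.09% and 84.62% through the full
        filter -> NJ -> assignment -> frequency workflow."""
        calls, truth = simulate_y_matrix(85, (41, 44), 40, missing_rate=0.02,
                                         seed=9)
        males = [f"m{i}" for i in range(85)]
        # clade1 (41): 35 Yangtze + 6 SC+SEA; clade2 (44): 11 Yangtze + 33 SC+SEA
        groups = {}
        for i in range(85):
            if i < 41:
                groups[males[i]] = "Yangtze" if i < 35 else "SC+SEA"
            else:
                groups[males[i]] = "Yangtze" if i < 52 else "SC+SEA"
        ym, _ = filter_y_sites(calls, np.zeros(calls.shape[1], dtype=bool),
                               max_missing=0.05, males=males)
        tree = nj_tree(hamming_matrix(ym), ym.males)
        assign = assign_clades(tree)
        out = haplogroup_frequencies(assign, groups).set_index("group")
        dominant = {g: out.loc[g, ["H1_pct", "H2_pct"]].max()
                    for g in ("Yangtze", "SC+SEA")}
        assert dominant["Yangtze"] == pytest.approx(76.09)
        assert dominant["SC+SEA"] == pytest.approx(84.62)
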