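"""Levenshtein metric, agglomerative trees, subgroup cutting, Newick output."""

import itertools
from functools import lru_cache

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligomine.cluster import (
    ClusteringError,
    LevenshteinClustering,
    agglomerate,
    build_matrix,
    cut_subgroups,
    levenshtein,
    select_candidates,
    to_newick,
    write_newick,
)

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=12)


def brute_force_edit_distance(a: str, b: str) -> int:
    """Independent oracle: naive recursive edit distance with memoization."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ESSES", "ESSES", 0),
            ("GPA", "GPPA", 1),
            ("ESSES", "AGLAS", 4),
            ("", "ACD", 3),
            ("ACD", "", 3),
            ("A", "G", 1),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected
        assert brute_force_edit_distance(a, b) == expected

    def test_exhaustive_three_mers_vs_oracle(self):
        # all pairs of 3-mers over a 3-letter alphabet against the oracle
        mers = ["".join(t) for t in itertools.product("AGS", repeat=3)]
        for a in mers:
            for b in mers:
                assert levenshtein(a, b) == brute_force_edit_distance(a, b)

    @given(a=peptides, b=peptides)
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_edlib(self, a, b):
        expected = edlib.align(a, b, task="distance")["editDistance"] if (a or b) else 0
        if not a or not b:
            expected = max(len(a), len(b))
        assert levenshtein(a, b) == expected

    @given(a=peptides, b=peptides, c=peptides)
    @settings(max_examples=200, deadline=None)
    def test_metric_properties(self, a, b, c):
        assert levenshtein(a, b) >= 0
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, b) == levenshtein(b, a)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestBuildMatrix:
    def test_pairwise_example(self):
        matrix = build_matrix(["AAA", "AAB", "BBB"])
        np.testing.assert_array_equal(
            matrix.values, [[0, 1, 3], [1, 0, 2], [3, 2, 0]]
        )

    def test_single_candidate_is_error(self):
        with pytest.raises(ClusteringError):
            build_matrix(["AAA"])

    def test_mixed_lengths_are_error(self):
        with pytest.raises(ClusteringError, match="length"):
            build_matrix(["AAA", "AAAA"])

    def test_symmetry_zero_diagonal(self):
        matrix = build_matrix(["ESSES", "SESSE", "GPAGA", "AGLAS"])
        np.testing.assert_array_equal(matrix.values, matrix.values.T)
        assert np.all(np.diag(matrix.values) == 0)


class TestAgglomerate:
    def test_complete_linkage_hand_run(self):
        tree = agglomerate(build_matrix(["AAA", "AAB", "BBB"]))
        heights = tree.heights()
        assert heights[0] == pytest.approx(1.0)  # {AAA, AAB} merge first
        assert heights[1] == pytest.approx(3.0)  # complete linkage: max(3, 2)

    def test_two_leaves_single_merge(self):
        tree = agglomerate(build_matrix(["AAA", "ABB"]))
        assert tree.heights() == pytest.approx([2.0])

    def test_duplicate_sequences_merge_at_zero(self):
        tree = agglomerate(build_matrix(["AAA", "AAA", "AAA"]))
        assert tree.heights() == pytest.approx([0.0, 0.0])

    def test_heights_nondecreasing(self):
        seqs = ["ESSES", "SESSE", "ESSSS", "GPAGA", "GGPAA", "AGLAS"]
        tree = agglomerate(build_matrix(seqs))
        heights = tree.heights()
        assert np.all(np.diff(heights) >= 0)

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ClusteringError):
            agglomerate(build_matrix(["AAA", "AAB"]), method="ward")


class TestCutSubgroups:
    def test_three_leaf_two_groups(self):
        tree = agglomerate(build_matrix(["AAA", "AAB", "BBB"]))
        assignment = cut_subgroups(tree, k=2)
        assert assignment["AAA"] == assignment["AAB"]
        assert assignment["AAA"] != assignment["BBB"]

    def test_k_one_everything_together(self):
        tree = agglomerate(build_matrix(["AAA", "AAB", "BBB"]))
        assert set(cut_subgroups(tree, k=1).values()) == {0}

    def test_k_equals_leaf_count_singletons(self):
        tree = agglomerate(build_matrix(["AAA", "AAB", "BBB"]))
        assignment = cut_subgroups(tree, k=3)
        assert sorted(assignment.values()) == [0, 1, 2]

    def test_k_exceeding_leaves_is_error(self):
        tree = agglomerate(build_matrix(["AAA", "AAB"]))
        with pytest.raises(ClusteringError):
            cut_subgroups(tree, k=3)

    def test_partition_covers_all_leaves(self):
        seqs = ["ESSES", "SESSE", "ESSSS", "GPAGA", "GGPAA", "AGLAS"]
        tree = agglomerate(build_matrix(seqs))
        assignment = cut_subgroups(tree, k=3)
        assert set(assignment) == set(seqs)

    def test_planted_families_exactly_separated(self):
        # ten serine/glutamate-rich vs ten glycine/proline/alanine-rich
        # pentapeptides: within-family distances are smaller than
        # between-family ones, so the k=2 cut recovers the families
        rng = np.random.default_rng(0)
        # a shared first residue keeps within-family distances <= 4 while the
        # disjoint alphabets pin between-family distances at 5
        se, gpa = set(), set()
        while len(se) < 10:
            se.add("S" + "".join(rng.choice(list("SE"), size=4)))
        while len(gpa) < 10:
            gpa.add("G" + "".join(rng.choice(list("GPA"), size=4)))
        se, gpa = sorted(se), sorted(gpa)
        seqs = se + gpa
        tree = agglomerate(build_matrix(seqs))
        assignment = cut_subgroups(tree, k=2)
        se_groups = {assignment[s] for s in se}
        gpa_groups = {assignment[s] for s in gpa}
        assert len(se_groups) == 1 and len(gpa_groups) == 1
        assert se_groups != gpa_groups


class TestSelectCandidates:
    def _tree(self):
        return agglomerate(build_matrix(["AAA", "AAB", "BBB", "BBA", "ABB"]))

    def test_top_per_group(self):
        tree = self._tree()
        scores = {"AAA": 0.9, "AAB": 0.8, "BBB": 0.7, "BBA": 0.6, "ABB": 0.5}
        picks = select_candidates(tree, scores, per_group=2, k=2)
        assignment = cut_subgroups(tree, k=2)
        for grp in set(assignment.values()):
            members = [s for s in assignment if assignment[s] == grp]
            expected = sorted(members, key=lambda s: -scores[s])[:2]
            assert [p for p in picks if assignment[p] == grp] == expected

    def test_small_group_returns_all(self):
        tree = agglomerate(build_matrix(["AAA", "AAB", "BBB"]))
        scores = {"AAA": 0.9, "AAB": 0.8, "BBB": 0.7}
        picks = select_candidates(tree, scores, per_group=3, k=2)
        assert sorted(picks) == ["AAA", "AAB", "BBB"]

    def test_missing_score_is_error(self):
        tree = agglomerate(build_matrix(["AAA", "AAB"]))
        with pytest.raises(ClusteringError):
            select_candidates(tree, {"AAA": 0.9}, per_group=1, k=1)

    def test_tie_broken_lexicographically(self):
        tree = agglomerate(build_matrix(["AAA", "AAB", "ABA"]))
        scores = {"AAA": 0.5, "AAB": 0.5, "ABA": 0.5}
        picks = select_candidates(tree, scores, per_group=1, k=1)
        assert picks == ["AAA"]


class TestNewick:
    def test_two_leaf_branch_lengths(self):
        tree = agglomerate(build_matrix(["AA", "GG"]))  # distance 2
        assert to_newick(tree) == "(AA:1,GG:1);"

    def test_topology_groups_close_pair(self, tmp_path):
        import dendropy

        tree = agglomerate(build_matrix(["AAA", "AAB", "BBB"]))
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == {"AAA", "AAB", "BBB"}
        # AAA and AAB must be siblings
        mrca = parsed.mrca(taxon_labels=["AAA", "AAB"])
        assert {l.taxon.label for l in mrca.leaf_iter()} == {"AAA", "AAB"}

    def test_roundtrip_preserves_leaf_partition(self, tmp_path):
        import dendropy

        seqs = ["ESSES", "SESSE", "GPAGA", "GGPAA"]
        tree = agglomerate(build_matrix(seqs))
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
        assignment = cut_subgroups(tree, k=2)
        groups = {}
        for s in seqs:
            groups.setdefault(assignment[s], set()).add(s)
        # the two subgroups appear as clades in the parsed tree
        for members in groups.values():
            if len(members) == 1:
                continue
            mrca = parsed.mrca(taxon_labels=sorted(members))
            assert {l.taxon.label for l in mrca.leaf_iter()} == members


class TestEstimator:
    def test_fit_predict_labels(self):
        seqs = ["SSSSS", "SESSS", "GGPAA", "GPAAA"]
        est = LevenshteinClustering(n_clusters=2)
        labels = est.fit_predict(seqs)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = LevenshteinClustering(n_clusters=3, linkage="average")
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
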