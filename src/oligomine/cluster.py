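"""Levenshtein-distance hierarchical clustering of equal-length oligopeptides.

Candidates are grouped by length (cross-length clustering would treat the
overhang of the longer sequence as arbitrary edits), a pairwise unit-cost
edit-distance matrix is built, and complete-linkage agglomeration produces
a dendrogram per length. Cutting the k-1 highest merges yields subgroups
(the default k=2 mirrors the serine/glutamate-rich versus
glycine/proline/alanine-rich split typical of disordered sequence), and the
top-scoring candidates per subgroup are selected for follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

LINKAGES = ("complete", "average", "single")


class ClusteringError(ValueError):
    """Raised on invalid clustering input."""


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertion, deletion, substitution).

    Standard two-row dynamic program, O(len(a)*len(b)).
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            curr[j] = min(
                prev[j] + 1,          # deletion
                curr[j - 1] + 1,      # insertion
                prev[j - 1] + (ca != cb),  # substitution / match
            )
        prev = curr
    return prev[-1]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise Levenshtein distances over equal-length sequences."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ClusteringError("distance matrix shape does not match labels")


def build_matrix(candidates: Sequence[str]) -> DistanceMatrix:
    """Full pairwise distance matrix for >= 2 equal-length sequences."""
    if len(candidates) < 2:
        raise ClusteringError("clustering needs at least two candidates")
    lengths = {len(c) for c in candidates}
    if len(lengths) != 1:
        raise ClusteringError(
            f"mixed candidate lengths {sorted(lengths)}: cluster per length only"
        )
    n = len(candidates)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein(candidates[i], candidates[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=tuple(candidates), values=values)


@dataclass
class ClusterTree:
    """Agglomerative merge tree over candidate sequences.

    ``linkage_matrix`` is in scipy's standard (n-1, 4) form: each row merges
    two cluster ids at a given height. Merge heights are non-decreasing for
    complete/average/single linkage on a metric.
    """

    leaves: tuple[str, ...]
    linkage_matrix: np.ndarray
    method: str = "complete"

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def agglomerate(matrix: DistanceMatrix, method: str = "complete") -> ClusterTree:
    """Agglomerative clustering of a distance matrix (default complete linkage)."""
    if method not in LINKAGES:
        raise ClusteringError(f"unsupported linkage {method!r}; use one of {LINKAGES}")
    condensed = squareform(matrix.values, checks=False)
    Z = linkage(condensed, method=method)
    return ClusterTree(leaves=matrix.labels, linkage_matrix=Z, method=method)


def cut_subgroups(tree: ClusterTree, k: int = 2) -> dict[str, int]:
    """Partition leaves into k subgroups by removing the k-1 highest merges.

    Subgroup ids are 0-based, renumbered in order of each subgroup's
    smallest leaf index so that assignments are stable across runs.
    """
    if k < 1:
        raise ClusteringError("k must be positive")
    if k > tree.n_leaves:
        raise ClusteringError(f"k={k} exceeds leaf count {tree.n_leaves}")
    if k == tree.n_leaves:
        raw = np.arange(tree.n_leaves)
    else:
        # cut_tree removes exactly the k-1 last merges, even when the top
        # merge heights tie
        raw = cut_tree(tree.linkage_matrix, n_clusters=k)[:, 0]
    order: dict[int, int] = {}
    for leaf_idx, grp in enumerate(raw):
        if grp not in order:
            order[int(grp)] = len(order)
    return {
        leaf: order[int(grp)] for leaf, grp in zip(tree.leaves, raw)
    }


def select_candidates(
    tree: ClusterTree,
    ranked_scores: Mapping[str, float],
    per_group: int = 3,
    k: int = 2,
) -> list[str]:
    """Top ``per_group`` scorers within each subgroup of the k-cut.

    Output is ordered by subgroup id then descending score; ties broken
    lexicographically. Smaller subgroups contribute all their members.
    """
    missing = [leaf for leaf in tree.leaves if leaf not in ranked_scores]
    if missing:
        raise ClusteringError(f"no score for leaves {missing[:3]}...")
    assignment = cut_subgroups(tree, k=k)
    selected: list[str] = []
    n_groups = max(assignment.values()) + 1
    for grp in range(n_groups):
        members = [leaf for leaf in tree.leaves if assignment[leaf] == grp]
        members.sort(key=lambda s: (-ranked_scores[s], s))
        selected.extend(members[:per_group])
    return selected


class LevenshteinClustering(BaseEstimator, ClusterMixin):
    """Scikit-learn style clusterer over equal-length peptide sequences.

    fit(X) with X a sequence of equal-length strings computes the pairwise
    Levenshtein matrix, agglomerates with the configured linkage, and cuts
    into ``n_clusters`` subgroups. Fitted attributes: ``labels_`` (subgroup
    id per input sequence), ``tree_`` (:class:`ClusterTree`),
    ``distance_matrix_``.
    """

    def __init__(self, n_clusters: int = 2, linkage: str = "complete"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, X: Sequence[str], y: None = None) -> "LevenshteinClustering":
        matrix = build_matrix(list(X))
        self.distance_matrix_ = matrix
        self.tree_ = agglomerate(matrix, method=self.linkage)
        assignment = cut_subgroups(self.tree_, k=self.n_clusters)
        self.labels_ = np.array([assignment[s] for s in X])
        return self

    def fit_predict(self, X: Sequence[str], y: None = None) -> np.ndarray:
        return self.fit(X).labels_


# -- Newick serialization -------------------------------------------------

def _newick_node(node, leaves: Sequence[str], parent_height: float) -> str:
    # leaf depth is height/2 under an ultrametric reading of the dendrogram,
    # so each branch spans half the height gap to the parent merge
    height = 0.0 if node.is_leaf() else node.dist
    branch = (parent_height - height) / 2.0
    if node.is_leaf():
        return f"{leaves[node.id]}:{branch:g}"
    left = _newick_node(node.left, leaves, height)
    right = _newick_node(node.right, leaves, height)
    return f"({left},{right}):{branch:g}"


def to_newick(tree: ClusterTree) -> str:
    """Newick string with branch lengths derived from merge heights."""
    from scipy.cluster.hierarchy import to_tree as _to_tree

    root = _to_tree(tree.linkage_matrix)
    height = root.dist
    left = _newick_node(root.left, tree.leaves, height)
    right = _newick_node(root.right, tree.leaves, height)
    return f"({left},{right});"


def write_newick(tree: ClusterTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def write_matrix_tsv(matrix: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(label + "\t" + "\t".join(f"{int(v)}" for v in row) + "\n")


def write_selection_report(
    rows: Iterable[tuple[str, int, int, float, int]], path: str | Path
) -> None:
    """TSV report: sequence, length, subgroup, score, rank."""
    with open(path, "w") as fh:
        fh.write("sequence\tlength\tsubgroup\tscore\trank\n")
        for seq, length, subgroup, sc, rank in rows:
            fh.write(f"{seq}\t{length}\t{subgroup}\t{sc:.6g}\t{rank}\n")
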