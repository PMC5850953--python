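"""Phylogenetic trees and patristic distances.

Features (OTUs) live on the leaves of a rooted phylogeny with branch
lengths.  The distance between two features is the patristic distance:
the sum of branch lengths along the unique path joining the two leaves.
The square root of the patristic distance is a Euclidean metric, which is
what licenses the embedding step downstream; ``euclidean_certificate``
checks that property numerically on any distance matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "LeafDistanceMatrix",
    "parse_newick",
    "write_newick",
    "patristic_matrix",
    "euclidean_certificate",
    "four_point_check",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


@dataclass
class PhyloTree:
    """A rooted phylogeny with branch lengths, leaves labelled by feature name.

    Wraps a dendropy tree; the leaf order exposed in ``leaf_labels`` is the
    tree's own (preorder) leaf traversal and is used consistently by every
    distance and embedding routine.
    """

    _tree: dendropy.Tree
    leaf_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.leaf_labels:
            self.leaf_labels = [lf.taxon.label for lf in self._tree.leaf_node_iter()]
        if len(set(self.leaf_labels)) != len(self.leaf_labels):
            dupes = sorted({l for l in self.leaf_labels if self.leaf_labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def parse_newick(text: str, default_branch_length: float | None = None) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Unrooted input is rooted at dendropy's first internal node; patristic
    distances are invariant under the choice of root, so this is safe.

    Parameters
    ----------
    text:
        Newick string (standard dialect, branch lengths after colons).
    default_branch_length:
        Substitute for missing branch lengths.  By default missing lengths
        are an error: silently defaulting them corrupts distances.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            if edge.length is None:
                edge.length = 0.0
            continue
        if edge.length is None:
            if default_branch_length is None:
                n_missing += 1
            else:
                edge.length = default_branch_length
    if n_missing:
        raise ValueError(
            f"{n_missing} branch(es) lack a length; pass default_branch_length "
            "to substitute one explicitly"
        )
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree back to Newick (branch lengths kept)."""
    return tree.dendropy_tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


@dataclass
class LeafDistanceMatrix:
    """Symmetric patristic-distance matrix over the leaves of a tree."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.labels):
            raise ValueError("labels and matrix size disagree")
        if not np.allclose(d, d.T, atol=1e-12, rtol=0):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "LeafDistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def patristic_matrix(tree: PhyloTree) -> LeafDistanceMatrix:
    """All-pairs patristic distances: path sums of branch lengths between leaves."""
    if tree.n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
    n = tree.n_leaves
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        dij = pdm.patristic_distance(taxa[tree.leaf_labels[i]], taxa[tree.leaf_labels[j]])
        d[i, j] = d[j, i] = dij
    return LeafDistanceMatrix(list(tree.leaf_labels), d)


def euclidean_certificate(
    dm: LeafDistanceMatrix | np.ndarray,
    apply_sqrt: bool = True,
    tol: float = 1e-8,
) -> tuple[bool, float]:
    """Check whether a distance matrix embeds isometrically in Euclidean space.

    Builds the double-centred Gram matrix ``B = -1/2 J D2 J`` where ``D2`` is
    the matrix of squared distances (elementwise-square-rooted patristic
    distances by default, so ``D2`` is the patristic matrix itself) and
    ``J = I - 11^T/n``.  The metric is Euclidean iff ``B`` is positive
    semidefinite; the returned ``min_eigenvalue`` is the smallest eigenvalue
    of ``B``, and the flag is true iff it is ``>= -tol * max_eigenvalue``.
    """
    d = dm.values if isinstance(dm, LeafDistanceMatrix) else np.asarray(dm, float)
    if not np.allclose(d, d.T, atol=1e-10, rtol=0):
        raise ValueError("distance matrix must be symmetric")
    d2 = d if apply_sqrt else d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    eig = np.linalg.eigvalsh(gram)
    min_eig, max_eig = eig[0], eig[-1]
    return bool(min_eig >= -tol * max(max_eig, np.finfo(float).tiny)), float(min_eig)


def four_point_check(dm: LeafDistanceMatrix, rel_tol: float = 1e-9,
                     max_quartets: int | None = 20000, seed: int = 0) -> bool:
    """Verify the four-point condition (additive tree metric) up to tolerance.

    For every quartet {i,j,k,l} the two largest of the three pairings
    d(i,j)+d(k,l), d(i,k)+d(j,l), d(i,l)+d(j,k) must be equal.  The check is
    exhaustive for small n and sampled for large n; tolerance is relative to
    the matrix maximum since path sums drift in floating point.
    """
    d = dm.values
    n = dm.n
    tol = rel_tol * max(d.max(), 1.0)
    quartets = list(combinations(range(n), 4))
    if max_quartets is not None and len(quartets) > max_quartets:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(quartets), size=max_quartets, replace=False)
        quartets = [quartets[i] for i in idx]
    for i, j, k, l in quartets:
        sums = sorted((d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]))
        if sums[2] - sums[1] > tol:
            return False
    return True
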