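"""Euclidean embedding of tree leaves by classical multidimensional scaling.

Because the square root of the patristic distance is a Euclidean metric,
classical (Torgerson) MDS on those square-rooted distances is exact at full
rank: the embedded pairwise distances reproduce sqrt(d) to machine
precision.  The closed-form eigendecomposition route is used rather than
iterative stress majorisation — it is deterministic and needs no seed.

Coordinates may optionally be sparsified with a SCAD (smoothly clipped
absolute deviation) threshold, the penalty tuned by cross-validated
reconstruction error on held-out distance entries.  Sparsification is off
by default; plain MDS is the baseline path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import LeafDistanceMatrix

__all__ = [
    "LeafCoordinates",
    "classical_mds",
    "embedding_stress",
    "scad_sparsify",
    "scad_threshold",
]


@dataclass
class LeafCoordinates:
    """Euclidean coordinates for the leaves, one row per leaf.

    ``eigenvalues`` are the retained (nonincreasing) eigenvalues of the
    double-centred Gram matrix; pairwise row distances approximate
    sqrt(patristic distance), exactly so at full rank.
    """

    labels: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.coords.shape[0] != len(self.labels):
            raise ValueError("labels and coordinate rows disagree")
        if self.coords.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("eigenvalues must match embedding dimension")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")

    @property
    def k_dim(self) -> int:
        return self.coords.shape[1]

    def reorder(self, labels) -> "LeafCoordinates":
        """Rows permuted to the given label order (e.g. table column order)."""
        labels = list(labels)
        if set(labels) != set(self.labels):
            raise ValueError("label sets disagree")
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = [pos[l] for l in labels]
        return LeafCoordinates(labels, self.coords[idx], self.eigenvalues.copy())

    def to_tsv(self, path) -> None:
        cols = [f"dim{i + 1}" for i in range(self.k_dim)]
        pd.DataFrame(self.coords, index=self.labels, columns=cols).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "LeafCoordinates":
        df = pd.read_csv(path, sep="\t", index_col=0)
        coords = df.to_numpy(dtype=float)
        # eigenvalues are not stored in the TSV; recover surrogate column norms
        ev = np.sort(np.sum(coords**2, axis=0))[::-1]
        return cls(list(df.index), coords, ev)


def classical_mds(dm: LeafDistanceMatrix, k_dim: int | None = None) -> LeafCoordinates:
    """Torgerson MDS of the square-rooted distances in ``dm``.

    The squared embedded distances should reproduce ``dm`` itself, so the
    matrix that is double-centred is ``dm.values`` directly.  Negative
    eigenvalues (numerical noise; the metric is provably Euclidean) are
    clipped to zero.  ``k_dim`` defaults to the effective rank: the number
    of eigenvalues exceeding ``1e-9`` times the largest.

    Each eigenvector's sign is fixed so its largest-magnitude entry is
    positive, making embeddings reproducible bit-for-bit.
    """
    d = dm.values
    n = dm.n
    if not d.any():
        raise ValueError("all-zero distance matrix: degenerate embedding")
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d @ j
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if k_dim is None:
        k_dim = int(np.sum(eigval > 1e-9 * max(eigval[0], np.finfo(float).tiny)))
        k_dim = max(k_dim, 1)
    if not 1 <= k_dim <= n - 1:
        raise ValueError(f"k_dim must be in [1, {n - 1}], got {k_dim}")
    lam = np.clip(eigval[:k_dim], 0.0, None)
    vec = eigvec[:, :k_dim]
    # deterministic sign: largest-|entry| of each eigenvector made positive
    for c in range(k_dim):
        pivot = np.argmax(np.abs(vec[:, c]))
        if vec[pivot, c] < 0:
            vec[:, c] = -vec[:, c]
    coords = vec * np.sqrt(lam)
    return LeafCoordinates(list(dm.labels), coords, lam)


def embedding_stress(dm: LeafDistanceMatrix, coords: LeafCoordinates) -> float:
    """Normalised residual stress of an embedding against sqrt(d).

    Returns sqrt( sum_{i<j} (||P_i - P_j|| - sqrt(d_ij))^2 / sum_{i<j} d_ij ).
    Zero for an exact embedding; one for all-zero coordinates.
    """
    if list(dm.labels) != list(coords.labels):
        raise ValueError("labels of distance matrix and coordinates disagree")
    iu = np.triu_indices(dm.n, k=1)
    target = np.sqrt(dm.values[iu])
    diff = coords.coords[:, None, :] - coords.coords[None, :, :]
    emb = np.sqrt(np.sum(diff**2, axis=-1))[iu]
    denom = np.sum(dm.values[iu])
    if denom == 0:
        raise ValueError("degenerate (all-zero) distance matrix")
    return float(np.sqrt(np.sum((emb - target) ** 2) / denom))


def scad_threshold(z: np.ndarray, penalty: float, a: float = 3.7) -> np.ndarray:
    """Elementwise SCAD thresholding operator.

    Kills entries below the penalty, shrinks moderate ones, and leaves large
    ones untouched (the usual a = 3.7 concavity convention).
    """
    z = np.asarray(z, dtype=float)
    if penalty == 0:
        return z.copy()
    absz = np.abs(z)
    out = np.zeros_like(z)
    soft = absz <= 2 * penalty
    out[soft] = np.sign(z[soft]) * np.maximum(absz[soft] - penalty, 0.0)
    mid = (absz > 2 * penalty) & (absz <= a * penalty)
    out[mid] = ((a - 1) * z[mid] - np.sign(z[mid]) * a * penalty) / (a - 2)
    big = absz > a * penalty
    out[big] = z[big]
    return out


def scad_sparsify(
    coords: LeafCoordinates,
    penalty_grid,
    cv_folds: int = 5,
    dm: LeafDistanceMatrix | None = None,
    a: float = 3.7,
    seed: int = 0,
    return_trace: bool = False,
):
    """Sparsify MDS coordinates by SCAD thresholding, penalty tuned by CV.

    The coordinate matrix is thresholded elementwise; the penalty is chosen
    from ``penalty_grid`` to minimise the cross-validated squared error of
    the reconstructed pairwise distances on held-out (i, j) entries.  The
    reference distances are sqrt(dm) when ``dm`` is given, else the input
    coordinates' own pairwise distances (exact for full-rank MDS input).
    Penalty 0 returns the input unchanged.
    """
    grid = list(penalty_grid)
    if not grid:
        raise ValueError("penalty grid is empty")
    n = coords.coords.shape[0]
    if dm is not None:
        if list(dm.labels) != list(coords.labels):
            raise ValueError("labels of distance matrix and coordinates disagree")
        ref_full = np.sqrt(dm.values)
    else:
        diff = coords.coords[:, None, :] - coords.coords[None, :, :]
        ref_full = np.sqrt(np.sum(diff**2, axis=-1))
    iu = np.vstack(np.triu_indices(n, k=1)).T
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(iu))
    folds = np.array_split(perm, cv_folds)
    cv_err = []
    for pen in grid:
        thr = scad_threshold(coords.coords, pen, a=a)
        diff = thr[:, None, :] - thr[None, :, :]
        emb = np.sqrt(np.sum(diff**2, axis=-1))
        errs = []
        for fold in folds:
            pairs = iu[fold]
            res = emb[pairs[:, 0], pairs[:, 1]] - ref_full[pairs[:, 0], pairs[:, 1]]
            errs.append(np.mean(res**2))
        cv_err.append(float(np.mean(errs)))
    best = int(np.argmin(cv_err))
    out = scad_threshold(coords.coords, grid[best], a=a)
    result = LeafCoordinates(list(coords.labels), out, coords.eigenvalues.copy())
    if return_trace:
        trace = pd.DataFrame({"penalty": grid, "cv_error": cv_err})
        return result, grid[best], trace
    return result
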