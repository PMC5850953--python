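"""Compositional synthetic data with controlled class separation.

Relative-abundance profiles live on the Aitchison simplex (positive parts
summing to one).  The generator works in isometric-log-ratio (ilr) space,
where unconstrained Gaussian statistics apply: it takes per-class ilr
means and covariances (estimated from data or drawn at random), shifts the
two class means symmetrically away from their midpoint by a separation
parameter alpha — scaled by the pooled spread sigma of the samples
projected on the between-mean direction — and draws multivariate-normal
samples that are mapped back to the simplex by the inverse ilr.

alpha = 0 makes the class means identical (chance-level task); larger
alpha gives easier tasks; alpha = 1 restores roughly the original
separation of the two estimated classes.

The ilr uses a fixed Helmert-type orthonormal basis so every number is
reproducible: coordinate j of ilr(x) is
sqrt(j/(j+1)) * ln( geometric_mean(x_1..x_j) / x_{j+1} ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import PhyloTree, parse_newick

__all__ = [
    "CompositionTable",
    "ClassStats",
    "GeneratorConfig",
    "ilr_forward",
    "ilr_inverse",
    "class_statistics",
    "alpha_shift_means",
    "sample_dataset",
    "random_tree",
    "random_fixture",
    "zero_replace",
]


def _helmert_basis(p: int) -> np.ndarray:
    """Orthonormal (p x p-1) contrast basis for the ilr, columns unit norm."""
    v = np.zeros((p, p - 1))
    for j in range(1, p):
        v[:j, j - 1] = 1.0 / j
        v[j, j - 1] = -1.0
        v[:, j - 1] *= np.sqrt(j / (j + 1.0))
    return v


def ilr_forward(x: np.ndarray) -> np.ndarray:
    """Isometric log-ratio transform, simplex (p parts) -> R^(p-1).

    Accepts a single composition or a (n, p) matrix of compositions.  Parts
    must be strictly positive; use :func:`zero_replace` first on count data
    with zeros.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ilr needs strictly positive parts; apply zero_replace first")
    single = x.ndim == 1
    xm = np.atleast_2d(x)
    v = _helmert_basis(xm.shape[1])
    z = np.log(xm) @ v
    return z[0] if single else z


def ilr_inverse(z: np.ndarray) -> np.ndarray:
    """Inverse ilr: R^(p-1) -> strictly positive composition summing to 1."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    zm = np.atleast_2d(z)
    v = _helmert_basis(zm.shape[1] + 1)
    clr = zm @ v.T
    clr -= clr.max(axis=1, keepdims=True)
    x = np.exp(clr)
    x /= x.sum(axis=1, keepdims=True)
    return x[0] if single else x


def zero_replace(x: np.ndarray, delta: float = 1e-6) -> np.ndarray:
    """Multiplicative zero replacement: zeros -> delta, rows renormalised."""
    x = np.asarray(x, dtype=float)
    xm = np.atleast_2d(x).copy()
    zero = xm <= 0
    nz = zero.sum(axis=1, keepdims=True)
    # shrink the nonzero parts so the row still sums to ~1, then renormalise
    xm = np.where(zero, delta, xm * (1 - nz * delta))
    xm /= xm.sum(axis=1, keepdims=True)
    return xm[0] if x.ndim == 1 else xm


@dataclass
class CompositionTable:
    """Samples x features relative abundances with per-sample class labels."""

    values: pd.DataFrame  # rows: sample ids, columns: feature labels
    labels: pd.Series     # class per sample, index matching values

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any(v < 0):
            raise ValueError("abundances must be nonnegative")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row must sum to 1 (relative abundances)")
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index must match sample ids")

    @property
    def feature_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)


@dataclass
class ClassStats:
    """Mean and covariance of one class in ilr space, plus its sample size."""

    mean_ilr: np.ndarray          # (p-1,)
    cov_ilr: np.ndarray           # (p-1, p-1) symmetric PSD
    n_samples: int

    def __post_init__(self) -> None:
        self.mean_ilr = np.asarray(self.mean_ilr, float)
        self.cov_ilr = np.asarray(self.cov_ilr, float)
        if self.cov_ilr.shape != (len(self.mean_ilr),) * 2:
            raise ValueError("covariance shape inconsistent with mean")
        if not np.allclose(self.cov_ilr, self.cov_ilr.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        ev = np.linalg.eigvalsh(self.cov_ilr)
        if ev[0] < -1e-9 * max(ev[-1], 1.0):
            raise ValueError("covariance must be positive semidefinite")


@dataclass
class GeneratorConfig:
    """Knobs of the compositional generator.

    alpha is the class-separation multiplier (0 = identical means);
    n_per_class may be one integer or a pair (n_A, n_B).
    """

    alpha: float = 1.0
    n_per_class: int | tuple[int, int] = 50
    p: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        ns = self.n_per_class if isinstance(self.n_per_class, tuple) else (self.n_per_class,) * 2
        if min(ns) < 2:
            raise ValueError("need at least 2 samples per class")

    @property
    def class_sizes(self) -> tuple[int, int]:
        if isinstance(self.n_per_class, tuple):
            return self.n_per_class
        return (self.n_per_class, self.n_per_class)


def class_statistics(table: CompositionTable, class_label) -> ClassStats:
    """ilr mean and covariance (n-1 denominator) of one class's samples."""
    mask = (table.labels == class_label).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"class {class_label!r} has fewer than 2 samples")
    z = ilr_forward(table.values.to_numpy(dtype=float)[mask])
    mean = z.mean(axis=0)
    cov = np.cov(z, rowvar=False, ddof=1)
    return ClassStats(mean, np.atleast_2d(cov), int(mask.sum()))


def alpha_shift_means(stats_A: ClassStats, stats_B: ClassStats, alpha: float):
    """Shifted class means for separation level alpha.

    With u = mu_A - mu_B, the pooled spread sigma is the root mean square of
    the class-centred sample projections onto u; since only (mean, cov, n)
    are available, the sum of squared centred projections of class C is
    evaluated exactly as (n_C - 1) * u' Sigma_C u.  The midpoint is
    mu = (mu_A + mu_B)/2, and the shifted means are
    m_C = mu + alpha * sigma * mu_C / ||mu_C||.

    Returns (m_A, m_B, sigma, mu_mid).  For alpha = 0, m_A = m_B = mu_mid.
    """
    mu_a, mu_b = stats_A.mean_ilr, stats_B.mean_ilr
    u = mu_a - mu_b
    if not np.any(u):
        raise ValueError("class means coincide: separation direction undefined")
    na, nb = stats_A.n_samples, stats_B.n_samples
    ss_a = (na - 1) * float(u @ stats_A.cov_ilr @ u)
    ss_b = (nb - 1) * float(u @ stats_B.cov_ilr @ u)
    sigma = float(np.sqrt((ss_a + ss_b) / (na + nb)))
    mu_mid = 0.5 * (mu_a + mu_b)
    norm_a, norm_b = np.linalg.norm(mu_a), np.linalg.norm(mu_b)
    if norm_a == 0 or norm_b == 0:
        raise ValueError("zero-norm class mean: unit direction undefined")
    m_a = mu_mid + alpha * sigma * mu_a / norm_a
    m_b = mu_mid + alpha * sigma * mu_b / norm_b
    return m_a, m_b, sigma, mu_mid


def _mvn_draw(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray,
              n: int) -> np.ndarray:
    ev = np.linalg.eigvalsh(cov)
    if ev[0] < -1e-9 * max(ev[-1], 1.0):
        cov = cov + 1e-9 * max(ev[-1], 1.0) * np.eye(cov.shape[0])
        ev = np.linalg.eigvalsh(cov)
        if ev[0] < 0 and ev[0] < -1e-9 * max(ev[-1], 1.0):
            raise ValueError("covariance not positive semidefinite")
    return rng.multivariate_normal(mean, cov, size=n, method="svd")


def sample_dataset(config: GeneratorConfig, stats_A: ClassStats,
                   stats_B: ClassStats,
                   class_names: tuple[str, str] = ("A", "B"),
                   feature_labels: list[str] | None = None) -> CompositionTable:
    """Draw a class-labelled compositional dataset at separation alpha.

    Per class: n samples from the multivariate normal with the alpha-shifted
    mean and the class's original covariance, mapped back to the simplex by
    the inverse ilr.  Class A rows first, then class B; deterministic per
    config.seed.
    """
    m_a, m_b, _, _ = alpha_shift_means(stats_A, stats_B, config.alpha)
    n_a, n_b = config.class_sizes
    rng = np.random.default_rng(config.seed)
    za = _mvn_draw(rng, m_a, stats_A.cov_ilr, n_a)
    zb = _mvn_draw(rng, m_b, stats_B.cov_ilr, n_b)
    x = ilr_inverse(np.vstack([za, zb]))
    p = x.shape[1]
    if feature_labels is None:
        feature_labels = [f"OTU_{i:04d}" for i in range(p)]
    sample_ids = [f"S{i:05d}" for i in range(n_a + n_b)]
    values = pd.DataFrame(x, index=sample_ids, columns=feature_labels)
    labels = pd.Series([class_names[0]] * n_a + [class_names[1]] * n_b,
                       index=sample_ids, name="class")
    return CompositionTable(values, labels)


def random_tree(rng: np.random.Generator, leaf_labels: list[str],
                branch_mean: float = 0.1) -> PhyloTree:
    """Random binary phylogeny over the given leaves.

    Topology from recursive random bipartition; branch lengths i.i.d.
    exponential with the given mean (a crude but standard stand-in for
    inferred substitution-rate branch lengths).
    """
    def build(labels: list[str]) -> str:
        if len(labels) == 1:
            return f"{labels[0]}:{rng.exponential(branch_mean):.8f}"
        cut = int(rng.integers(1, len(labels)))
        perm = list(rng.permutation(labels))
        left, right = perm[:cut], perm[cut:]
        bl = rng.exponential(branch_mean)
        return f"({build(left)},{build(right)}):{bl:.8f}"

    newick = f"({build(list(leaf_labels))});" if len(leaf_labels) == 1 \
        else build(list(leaf_labels)) + ";"
    return parse_newick(newick)


def random_fixture(seed: int, p: int = 64, n_per_class: int = 50,
                   alpha: float = 1.0,
                   class_names: tuple[str, str] = ("HS", "CDf")):
    """Self-contained study fixture: tree + class statistics + dataset.

    Emulates the structure of a two-class gut-microbiome cohort without any
    external data: a random binary phylogeny over p leaves (features), two
    synthetic ilr-space class statistics (unit-norm random means; low-rank
    plus diagonal covariances, so features are correlated as in real
    communities), and a compositional dataset drawn at separation alpha.

    Returns ``(tree, table, (stats_A, stats_B))``, all reproducible per seed.
    """
    if p < 4:
        raise ValueError("need at least 4 features")
    rng = np.random.default_rng(seed)
    feature_labels = [f"OTU_{i:04d}" for i in range(p)]
    tree = random_tree(rng, feature_labels)
    q = p - 1
    stats = []
    # the two class covariances share a common low-rank backbone with a small
    # class-specific component: both classes come from the same community, so
    # their correlation structure is similar but not identical.  Fully
    # independent covariances would make the classes separable by covariance
    # alone even with coincident means, which the construction rules out.
    w_shared = rng.normal(size=(q, 5)) * np.sqrt(0.1 / 5)
    for _ in range(2):
        mean = rng.normal(size=q)
        mean /= np.linalg.norm(mean)
        w = w_shared + 0.1 * rng.normal(size=(q, 5)) * np.sqrt(0.1 / 5)
        cov = w @ w.T + 0.1 * np.eye(q)
        stats.append(ClassStats(mean, cov, n_per_class))
    cfg = GeneratorConfig(alpha=alpha, n_per_class=n_per_class, p=p,
                          seed=int(rng.integers(2**31)))
    table = sample_dataset(cfg, stats[0], stats[1], class_names=class_names,
                           feature_labels=feature_labels)
    return tree, table, (stats[0], stats[1])
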