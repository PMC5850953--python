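"""MAQC/SEQC-style Data Analysis Protocol.

Repeated stratified cross-validation with in-fold feature ranking, Borda
fusion of the per-fold ranked lists, MCC scoring with studentized
bootstrap confidence intervals, refit-on-the-whole-training-set external
validation, and the two randomisation sanity checks (permuted labels,
random feature selection).  Feature ranking happens strictly inside each
training fold, never on validation data — that is the point of the
protocol: an unbiased estimate of the selection + classification pipeline.

The protocol is classifier-agnostic: any object with ``fit``/``predict``
plugs in through a factory, so the phylogeny-aware CNN, a linear SVM, a
random forest and an MLP all run under the identical schema.
"""

from __future__ import annotations

import inspect
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

__all__ = [
    "DAPConfig",
    "RankedList",
    "MetricReport",
    "stratified_partition",
    "anova_f_scores",
    "confusion_from_labels",
    "mcc",
    "borda_fuse",
    "studentized_bootstrap_ci",
    "make_classifier",
    "run_dap",
    "sanity_randomization",
]


@dataclass
class DAPConfig:
    """Protocol settings: 10 repeats of stratified 5-fold CV by default,
    80/20 external split, models at 25/50/75/100% of the ranked features."""

    n_repeats: int = 10
    n_folds: int = 5
    test_fraction: float = 0.2
    feature_fractions: tuple = (0.25, 0.50, 0.75, 1.00)
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if not all(0 < f <= 1 for f in self.feature_fractions):
            raise ValueError("feature fractions must lie in (0, 1]")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be >= 100")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class RankedList:
    """Feature ids best-first with their ranking scores (same order)."""

    features: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.intp)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.features) != len(set(self.features.tolist())):
            raise ValueError("ranked list must be a permutation (no repeats)")
        if self.scores.shape != self.features.shape:
            raise ValueError("scores must align with features")

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class MetricReport:
    """Per-feature-fraction MCC with bootstrap CIs, internal and external."""

    table: pd.DataFrame  # columns: split, n_features, mcc, ci_low, ci_high

    def __post_init__(self) -> None:
        t = self.table
        if np.any(t["mcc"] < -1 - 1e-9) or np.any(t["mcc"] > 1 + 1e-9):
            raise ValueError("MCC out of [-1, 1]")
        internal = t[t["split"] == "internal"]
        if np.any(internal["ci_low"] > internal["mcc"] + 1e-9) or \
           np.any(internal["ci_high"] < internal["mcc"] - 1e-9):
            raise ValueError("CI must bracket the estimate")


def stratified_partition(labels, test_fraction: float, seed: int):
    """Stratified train/test index split preserving per-class ratios."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    idx = np.arange(len(y))
    train, test = train_test_split(idx, test_size=test_fraction,
                                   stratify=y, random_state=seed)
    return np.sort(train), np.sort(test)


def anova_f_scores(X, y) -> RankedList:
    """Rank features by one-way ANOVA F, descending; ties by ascending index.

    Conventions at the edges: a feature constant across all samples has no
    between-class variance and gets F = 0 (ranked last among zeros); a
    feature with zero within-class variance but distinct class means gets
    F = +inf and is ranked first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, _ = f_classif(X, y)
    f = np.asarray(f, dtype=float)
    const = X.var(axis=0) == 0
    f[const] = 0.0
    f[np.isnan(f)] = 0.0
    order = np.lexsort((np.arange(X.shape[1]), -f))
    return RankedList(order, f[order])


def confusion_from_labels(y_true, y_pred, classes=None) -> np.ndarray:
    """Confusion matrix C[i, j] = count(true class i predicted as class j)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    k = len(classes)
    lookup = {c: i for i, c in enumerate(classes.tolist())}
    c = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        c[lookup[t], lookup[p]] += 1
    return c


def mcc(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient from a confusion matrix.

    Binary case reduces to the classical TP/TN/FP/FN formula; the general
    K-class form is the covariance-based generalisation.  Degenerate
    denominators (e.g. every prediction in one class) return 0, matching
    the chance-level convention.
    """
    c = np.asarray(confusion, dtype=float)
    if c.size == 0:
        raise ValueError("empty confusion matrix")
    if np.any(c < 0) or c.sum() == 0:
        raise ValueError("confusion matrix needs nonnegative counts, not all zero")
    s = c.sum()
    trace = np.trace(c)
    t = c.sum(axis=1)  # true-class totals
    p = c.sum(axis=0)  # predicted-class totals
    num = trace * s - t @ p
    den = np.sqrt(s**2 - p @ p) * np.sqrt(s**2 - t @ t)
    if den == 0:
        return 0.0
    return float(num / den)


def borda_fuse(lists) -> RankedList:
    """Borda fusion: each feature scores (list length - position) per list,
    summed; re-rank by total score descending, ties by ascending feature id."""
    lists = list(lists)
    if not lists:
        raise ValueError("no lists to fuse")
    ref = set(lists[0].features.tolist())
    n = len(lists[0])
    scores = np.zeros(n)
    feat_sorted = np.sort(lists[0].features)
    pos_of = {f: i for i, f in enumerate(feat_sorted.tolist())}
    for rl in lists:
        if set(rl.features.tolist()) != ref:
            raise ValueError("all lists must rank the same feature set")
        for pos, f in enumerate(rl.features.tolist()):
            scores[pos_of[f]] += n - pos
    order = np.lexsort((feat_sorted, -scores))
    return RankedList(feat_sorted[order], scores[order])


def studentized_bootstrap_ci(values, level: float = 0.95, reps: int = 1000,
                             seed: int = 0):
    """Studentized (bootstrap-t) confidence interval for the mean.

    Resamples, studentizes each resampled mean by its own bootstrap
    standard error, and inverts the pivot's quantiles.  Zero-variance input
    collapses to the point estimate.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    n = len(v)
    theta = v.mean()
    se = v.std(ddof=1) / np.sqrt(n)
    if se == 0:
        return float(theta), float(theta)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    boots = v[idx]
    bmean = boots.mean(axis=1)
    bse = boots.std(axis=1, ddof=1) / np.sqrt(n)
    tstat = np.where(bse > 0, (bmean - theta) / np.where(bse > 0, bse, 1.0), 0.0)
    lo_q, hi_q = np.quantile(tstat, [(1 - level) / 2, (1 + level) / 2])
    return float(theta - hi_q * se), float(theta - lo_q * se)


def make_classifier(name: str, coords=None, config=None):
    """Factory of factories: returns ``factory(seed) -> estimator``.

    Supported: 'linear_svm', 'random_forest', 'mlp', 'phylocnn' (the last
    needs the leaf coordinates and optionally a PhyloCNNConfig).
    """
    if name == "linear_svm":
        return lambda seed: LinearSVC(random_state=seed)
    if name == "random_forest":
        return lambda seed: RandomForestClassifier(n_estimators=500, random_state=seed)
    if name == "mlp":
        return lambda seed: MLPClassifier(random_state=seed, max_iter=500)
    if name == "phylocnn":
        from dataclasses import replace
        from .model import PhyloCNNClassifier, PhyloCNNConfig
        base = config or PhyloCNNConfig()

        def factory(seed):
            return PhyloCNNClassifier(coords, replace(base, seed=seed))
        return factory
    raise ValueError(f"unknown classifier {name!r}")


def _fit(est, X, y, feature_indices):
    if "feature_indices" in inspect.signature(est.fit).parameters:
        est.fit(X, y, feature_indices=feature_indices)
    else:
        est.fit(X, y)
    return est


def _check_class_sizes(y, n_folds):
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < n_folds:
            raise ValueError(
                f"class {cls!r} has {cnt} training samples, fewer than "
                f"n_folds={n_folds}")


def run_dap(X, y, config: DAPConfig, classifier_factory,
            ranker=anova_f_scores, return_fold_mccs: bool = False):
    """Run the full protocol.

    1. Hold out the stratified external validation split.
    2. ``n_repeats`` rounds of stratified ``n_folds``-fold CV on the
       training part; in each fold the features are ranked on the training
       fold only, a model is fitted at each feature fraction (fractions of
       the features non-constant on the training part, counts rounded up)
       and scored by MCC on the internal validation fold.
    3. The per-fold ranked lists (n_repeats x n_folds of them) are fused by
       the Borda method.
    4. At each fraction, a model on the fused list's top features is refit
       on the whole training part and scored on the external split.
    5. The report carries, per fraction, the mean internal MCC with a
       studentized bootstrap CI over the fold MCCs, and the external MCC.

    Returns ``(MetricReport, fused RankedList)``; with
    ``return_fold_mccs=True`` also a DataFrame of per-fold MCCs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    train_idx, test_idx = stratified_partition(y, config.test_fraction, config.seed)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]
    _check_class_sizes(ytr, config.n_folds)
    classes = np.unique(y)
    active = np.flatnonzero(Xtr.var(axis=0) > 0)
    n_active = len(active)
    fractions = sorted(config.feature_fractions)
    n_sel = {f: int(np.ceil(f * n_active)) for f in fractions}

    fold_records = []
    ranked_lists = []
    fold_id = 0
    for rep in range(config.n_repeats):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=config.seed + 1000 * (rep + 1))
        for tr_f, va_f in skf.split(Xtr, ytr):
            rl = ranker(Xtr[np.ix_(tr_f, active)], ytr[tr_f])
            # ranked list is over positions in `active`; map to feature ids
            ranked_lists.append(RankedList(active[rl.features], rl.scores))
            for frac in fractions:
                feats = active[rl.features[: n_sel[frac]]]
                est = classifier_factory(config.seed + fold_id)
                _fit(est, Xtr[np.ix_(tr_f, feats)], ytr[tr_f], feats)
                pred = est.predict(Xtr[np.ix_(va_f, feats)])
                m = mcc(confusion_from_labels(ytr[va_f], pred, classes=classes))
                fold_records.append({"repeat": rep, "fold": fold_id % config.n_folds,
                                     "fraction": frac, "mcc": m})
            fold_id += 1

    fused = borda_fuse(ranked_lists)
    folds_df = pd.DataFrame(fold_records)

    rows = []
    for frac in fractions:
        vals = folds_df.loc[folds_df["fraction"] == frac, "mcc"].to_numpy()
        lo, hi = studentized_bootstrap_ci(vals, level=config.ci_level,
                                          reps=config.bootstrap_reps,
                                          seed=config.seed)
        est_mean = float(vals.mean())
        rows.append({"split": "internal", "n_features": n_sel[frac],
                     "fraction": frac, "mcc": est_mean,
                     "ci_low": min(lo, est_mean), "ci_high": max(hi, est_mean)})
    for frac in fractions:
        feats = fused.features[: n_sel[frac]]
        est = classifier_factory(config.seed + 999983)
        _fit(est, Xtr[:, feats], ytr, feats)
        pred = est.predict(Xte[:, feats])
        m = mcc(confusion_from_labels(yte, pred, classes=classes))
        rows.append({"split": "external", "n_features": n_sel[frac],
                     "fraction": frac, "mcc": m,
                     "ci_low": np.nan, "ci_high": np.nan})
    report = MetricReport(pd.DataFrame(rows))
    if return_fold_mccs:
        return report, fused, folds_df
    return report, fused


def _random_ranker_factory(seed: int):
    rng = np.random.default_rng(seed)

    def ranker(X, y):
        n = X.shape[1]
        perm = rng.permutation(n)
        return RankedList(perm, np.arange(n, 0, -1, dtype=float))
    return ranker


def sanity_randomization(X, y, config: DAPConfig, classifier_factory,
                         mode: str = "random-labels"):
    """Randomisation sanity check for the protocol.

    'random-labels' permutes the class labels (seeded) before running the
    protocol — any systematic bias would show up as MCC away from 0.
    'random-features' keeps the labels but replaces the in-fold ANOVA
    ranking with a seeded random permutation of the features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if mode == "random-labels":
        rng = np.random.default_rng(config.seed + 7919)
        y_perm = rng.permutation(y)
        return run_dap(X, y_perm, config, classifier_factory)
    if mode == "random-features":
        return run_dap(X, y, config, classifier_factory,
                       ranker=_random_ranker_factory(config.seed + 104729))
    raise ValueError("mode must be 'random-labels' or 'random-features'")
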