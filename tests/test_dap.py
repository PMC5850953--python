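"""Data Analysis Protocol: splits, ranking, MCC, Borda, bootstrap, leakage."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import matthews_corrcoef

import phylocnn as pc


# ------------------------------------------------------------------- splits
def test_stratified_partition_exact_ratio():
    y = np.array([0] * 25 + [1] * 25)
    tr, te = pc.stratified_partition(y, 0.2, seed=0)
    assert len(te) == 10
    assert np.sum(y[te] == 0) == 5 and np.sum(y[te] == 1) == 5
    assert len(np.intersect1d(tr, te)) == 0
    assert len(tr) + len(te) == 50


def test_stratified_partition_38_60():
    y = np.array(["HS"] * 38 + ["CDf"] * 60)
    _, te = pc.stratified_partition(y, 0.2, seed=1)
    n_hs = np.sum(y[te] == "HS")
    n_cd = np.sum(y[te] == "CDf")
    assert abs(n_hs - 7.6) <= 1 and abs(n_cd - 12) <= 1


def test_stratified_partition_deterministic():
    y = np.array([0] * 30 + [1] * 20)
    assert np.array_equal(pc.stratified_partition(y, 0.25, seed=3)[0],
                          pc.stratified_partition(y, 0.25, seed=3)[0])


# ------------------------------------------------------------------ ranking
def test_anova_constant_feature_ranked_last(rng):
    X = rng.normal(size=(40, 5))
    X[:, 2] = 1.0  # constant
    y = np.array([0] * 20 + [1] * 20)
    rl = pc.anova_f_scores(X, y)
    assert rl.features[-1] == 2 or rl.scores[list(rl.features).index(2)] == 0.0


def test_anova_indicator_feature_ranked_first(rng):
    X = rng.normal(size=(40, 6))
    y = np.array([0] * 20 + [1] * 20)
    X[:, 4] = y + rng.normal(scale=1e-3, size=40)
    rl = pc.anova_f_scores(X, y)
    assert rl.features[0] == 4


def test_anova_f_equals_squared_t(rng):
    """Two-class one-way F equals the squared pooled-variance t statistic."""
    X = rng.normal(size=(30, 4))
    y = np.array([0] * 14 + [1] * 16)
    rl = pc.anova_f_scores(X, y)
    score_of = dict(zip(rl.features.tolist(), rl.scores.tolist()))
    for j in range(4):
        t, _ = sps.ttest_ind(X[y == 0, j], X[y == 1, j], equal_var=True)
        assert score_of[j] == pytest.approx(t**2, rel=1e-9)


def test_anova_needs_two_classes(rng):
    with pytest.raises(ValueError, match="2 classes"):
        pc.anova_f_scores(rng.normal(size=(10, 2)), np.zeros(10))


# ---------------------------------------------------------------------- MCC
def test_mcc_perfect_and_antiperfect():
    assert pc.mcc(np.diag([5, 7, 3])) == pytest.approx(1.0)
    assert pc.mcc(np.array([[0, 4], [6, 0]])) == pytest.approx(-1.0)


def test_mcc_all_one_class_is_zero():
    assert pc.mcc(np.array([[10, 0], [5, 0]])) == 0.0


def test_mcc_binary_matches_classical_formula(rng):
    for _ in range(20):
        c = rng.integers(0, 30, size=(2, 2))
        if c.sum() == 0:
            continue
        tn, fp, fn, tp = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
        den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        ref = 0.0 if den == 0 else (tp * tn - fp * fn) / den
        assert pc.mcc(c) == pytest.approx(ref, abs=1e-12)


def test_mcc_multiclass_matches_direct_formula_and_sklearn(rng):
    for _ in range(10):
        c = rng.integers(0, 15, size=(4, 4))
        if c.sum() == 0:
            continue
        # direct covariance-form evaluation
        s, tr = c.sum(), np.trace(c)
        t, p = c.sum(1), c.sum(0)
        den = np.sqrt(float(s**2 - p @ p)) * np.sqrt(float(s**2 - t @ t))
        ref = 0.0 if den == 0 else (tr * s - t @ p) / den
        assert pc.mcc(c) == pytest.approx(ref, abs=1e-12)
        # independent route: expand to label vectors, use sklearn
        y_true = np.repeat(np.arange(4), c.sum(1))
        y_pred = np.concatenate([np.repeat(np.arange(4), c[i]) for i in range(4)])
        assert pc.mcc(c) == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-9)


def test_mcc_invariant_under_class_permutation(rng):
    c = rng.integers(0, 20, size=(5, 5))
    perm = rng.permutation(5)
    assert pc.mcc(c[np.ix_(perm, perm)]) == pytest.approx(pc.mcc(c), abs=1e-12)


def test_mcc_empty_errors():
    with pytest.raises(ValueError):
        pc.mcc(np.zeros((0, 0)))


# -------------------------------------------------------------------- Borda
def test_borda_single_list_unchanged():
    rl = pc.RankedList(np.array([3, 1, 0, 2]), np.array([9.0, 5.0, 2.0, 1.0]))
    fused = pc.borda_fuse([rl])
    assert fused.features.tolist() == [3, 1, 0, 2]


def test_borda_reversed_lists_tie_by_index():
    a = pc.RankedList(np.array([0, 1, 2, 3]), np.arange(4, 0, -1, dtype=float))
    b = pc.RankedList(np.array([3, 2, 1, 0]), np.arange(4, 0, -1, dtype=float))
    fused = pc.borda_fuse([a, b])
    assert len(set(fused.scores.tolist())) == 1
    assert fused.features.tolist() == [0, 1, 2, 3]


def test_borda_identical_lists_returned():
    rl = pc.RankedList(np.array([2, 0, 1]), np.array([3.0, 2.0, 1.0]))
    fused = pc.borda_fuse([rl] * 5)
    assert fused.features.tolist() == [2, 0, 1]


def test_borda_matches_counting_oracle(rng):
    n = 10
    lists = [pc.RankedList(rng.permutation(n), np.arange(n, 0, -1, dtype=float))
             for _ in range(5)]
    fused = pc.borda_fuse(lists)
    score = {f: 0 for f in range(n)}
    for rl in lists:
        for pos, f in enumerate(rl.features.tolist()):
            score[f] += n - pos
    ref = sorted(range(n), key=lambda f: (-score[f], f))
    assert fused.features.tolist() == ref


def test_borda_mismatched_sets_error():
    a = pc.RankedList(np.array([0, 1]), np.array([2.0, 1.0]))
    b = pc.RankedList(np.array([1, 2]), np.array([2.0, 1.0]))
    with pytest.raises(ValueError, match="same feature set"):
        pc.borda_fuse([a, b])


# ---------------------------------------------------------------- bootstrap
def test_bootstrap_constant_collapses():
    lo, hi = pc.studentized_bootstrap_ci([2.0] * 10)
    assert lo == hi == 2.0


def test_bootstrap_matches_t_interval_asymptotically(rng):
    v = rng.normal(5.0, 2.0, size=400)
    lo, hi = pc.studentized_bootstrap_ci(v, reps=2000, seed=1)
    se = v.std(ddof=1) / np.sqrt(len(v))
    t = sps.t.ppf(0.975, len(v) - 1)
    assert lo == pytest.approx(v.mean() - t * se, abs=0.35 * se)
    assert hi == pytest.approx(v.mean() + t * se, abs=0.35 * se)


def test_bootstrap_coverage():
    """95% studentized interval covers the true normal mean ~95% of the time."""
    rng = np.random.default_rng(7)
    cover = 0
    n_sim = 500
    for s in range(n_sim):
        v = rng.normal(1.0, 1.0, size=30)
        lo, hi = pc.studentized_bootstrap_ci(v, reps=400, seed=s)
        cover += lo <= 1.0 <= hi
    assert abs(cover / n_sim - 0.95) <= 0.03


# ------------------------------------------------------------ full protocol
@pytest.fixture(scope="module")
def dap_fixture():
    _, table, _ = pc.random_fixture(20, p=32, n_per_class=100, alpha=3.0)
    return table.values.to_numpy(), table.labels.to_numpy()


def test_dap_separable_data_high_mcc(dap_fixture):
    X, y = dap_fixture
    cfg = pc.DAPConfig(n_repeats=2, seed=0, feature_fractions=(0.5, 1.0),
                       bootstrap_reps=200)
    report, fused = pc.run_dap(X, y, cfg, pc.make_classifier("linear_svm"))
    t = report.table
    assert np.all(t.loc[t.split == "internal", "mcc"] >= 0.9)
    assert np.all(t.loc[t.split == "external", "mcc"] >= 0.9)
    assert sorted(fused.features.tolist()) == list(range(32))
    internal = t[t.split == "internal"]
    assert np.all(internal.ci_low <= internal.mcc)
    assert np.all(internal.mcc <= internal.ci_high)


def test_dap_no_signal_near_zero():
    """With coincident class means there is no signal: MCC averages to ~0
    (a single external split of a few hundred samples is noisy, so the
    chance-level property is asserted on the mean over seeds)."""
    ext, internal = [], []
    for seed in range(3):
        _, table, _ = pc.random_fixture(21 + seed, p=32, n_per_class=500, alpha=0.0)
        X, y = table.values.to_numpy(), table.labels.to_numpy()
        cfg = pc.DAPConfig(n_repeats=1, seed=seed, feature_fractions=(1.0,),
                           bootstrap_reps=200)
        report, _ = pc.run_dap(X, y, cfg, pc.make_classifier("linear_svm"))
        t = report.table
        ext.append(t.loc[t.split == "external", "mcc"].iloc[0])
        internal.append(t.loc[t.split == "internal", "mcc"].iloc[0])
    assert abs(np.mean(ext)) <= 0.1
    assert abs(np.mean(internal)) <= 0.1


def test_dap_no_leakage_from_external_split(dap_fixture):
    """Feature ranking happens inside folds: scrambling the features of the
    external-split rows must leave every internal fold MCC unchanged."""
    X, y = dap_fixture
    cfg = pc.DAPConfig(n_repeats=1, seed=4, feature_fractions=(0.5,),
                       bootstrap_reps=200)
    _, te = pc.stratified_partition(y, cfg.test_fraction, cfg.seed)
    X2 = X.copy()
    X2[te] = X2[np.ix_(te, np.random.default_rng(0).permutation(X.shape[1]))]
    _, _, folds1 = pc.run_dap(X, y, cfg, pc.make_classifier("linear_svm"),
                              return_fold_mccs=True)
    _, _, folds2 = pc.run_dap(X2, y, cfg, pc.make_classifier("linear_svm"),
                              return_fold_mccs=True)
    assert np.allclose(folds1["mcc"], folds2["mcc"])


def test_dap_small_class_errors():
    X = np.random.default_rng(0).normal(size=(12, 4))
    y = np.array([0] * 9 + [1] * 3)
    cfg = pc.DAPConfig(n_repeats=1, seed=0, bootstrap_reps=100)
    with pytest.raises(ValueError, match="fewer than"):
        pc.run_dap(X, y, cfg, pc.make_classifier("linear_svm"))


def test_sanity_random_labels_chance_level(dap_fixture):
    X, y = dap_fixture
    cfg = pc.DAPConfig(n_repeats=2, seed=1, feature_fractions=(1.0,),
                       bootstrap_reps=200)
    report, _ = pc.sanity_randomization(X, y, cfg, pc.make_classifier("linear_svm"),
                                        mode="random-labels")
    t = report.table
    assert abs(t.loc[t.split == "internal", "mcc"].iloc[0]) <= 0.15


def test_sanity_random_features_keeps_signal_at_full_fraction(dap_fixture):
    X, y = dap_fixture
    cfg = pc.DAPConfig(n_repeats=1, seed=2, feature_fractions=(1.0,),
                       bootstrap_reps=200)
    report, _ = pc.sanity_randomization(X, y, cfg, pc.make_classifier("linear_svm"),
                                        mode="random-features")
    t = report.table
    # the full feature set is used either way, so signal survives
    assert t.loc[t.split == "internal", "mcc"].iloc[0] >= 0.9


def test_sanity_deterministic(dap_fixture):
    X, y = dap_fixture
    cfg = pc.DAPConfig(n_repeats=1, seed=5, feature_fractions=(1.0,),
                       bootstrap_reps=200)
    r1, _ = pc.sanity_randomization(X, y, cfg, pc.make_classifier("linear_svm"))
    r2, _ = pc.sanity_randomization(X, y, cfg, pc.make_classifier("linear_svm"))
    assert r1.table.equals(r2.table)
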