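"""Unit tests for the boosted-tree learner: split search, offsets, tuning."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from landboost.evaluation import auroc
from landboost.gbm import (
    BoostedEnsemble,
    SingleClassWarning,
    TrainConfig,
    TreeNode,
    find_best_split,
    fit_gbm,
    logit,
    make_holdout,
    sigmoid,
    tune_by_cv,
)


# ---------------------------------------------------------------------------
# brute-force split oracle
# ---------------------------------------------------------------------------

def brute_force_split(X, g, h, lam=1.0, mcw=1.0):
    """Enumerate every (feature, observed split point, missing direction)
    plus present-vs-missing splits; return (best gain, best left-row set)."""
    n, p = X.shape
    Gt, Ht = g.sum(), h.sum()

    def gain_of(left):
        GL, HL = g[left].sum(), h[left].sum()
        GR, HR = Gt - GL, Ht - HL
        if HL < mcw or HR < mcw:
            return -np.inf
        return 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam) - Gt**2 / (Ht + lam))

    best_gain, best_left = -np.inf, None
    for j in range(p):
        v = X[:, j]
        isna = np.isnan(v)
        for thr in np.unique(v[~isna]):
            for miss_left in (False, True):
                left = np.where(isna, miss_left, v <= thr)
                gn = gain_of(left)
                if gn > best_gain + 1e-12:
                    best_gain, best_left = gn, left.copy()
        if isna.any() and (~isna).any():
            left = ~isna  # pure present-vs-missing
            gn = gain_of(left)
            if gn > best_gain + 1e-12:
                best_gain, best_left = gn, left.copy()
    return best_gain, best_left


def apply_split(X, split):
    v = X[:, split.feature]
    isna = np.isnan(v)
    return np.where(isna, split.missing_left, v < split.threshold)


@pytest.mark.parametrize("trial", range(25))
def test_split_matches_bruteforce_on_random_instances(trial):
    """The exact greedy split equals exhaustive gain maximisation, missing
    values included."""
    rng = np.random.default_rng(1000 + trial)
    n, p = 20, 3
    X = rng.normal(size=(n, p))
    X[rng.random((n, p)) < 0.25] = np.nan
    g = rng.normal(size=n)
    h = rng.uniform(0.1, 1.0, size=n)
    split = find_best_split(X, g, h, reg_lambda=1.0, min_child_weight=0.5)
    oracle_gain, oracle_left = brute_force_split(X, g, h, lam=1.0, mcw=0.5)
    if split is None:
        assert oracle_gain <= 1e-12
        return
    assert split.gain == pytest.approx(oracle_gain, abs=1e-9)
    left = apply_split(X, split)
    # the same partition may be labelled left/right either way
    assert np.array_equal(left, oracle_left) or np.array_equal(left, ~oracle_left)


def test_split_missing_direction_is_learned():
    """Missing rows are routed to whichever side lowers the loss."""
    # positives all missing; negatives observed low values
    X = np.array([[np.nan], [np.nan], [np.nan], [0.1], [0.2], [0.3]])
    g = np.array([-0.5, -0.5, -0.5, 0.5, 0.5, 0.5])
    h = np.full(6, 0.25)
    split = find_best_split(X, g, h, min_child_weight=0.1)
    left = apply_split(X, split)
    # the split must separate missing from observed
    assert set(np.flatnonzero(left)) in ({0, 1, 2}, {3, 4, 5})


# ---------------------------------------------------------------------------
# fitting behaviour
# ---------------------------------------------------------------------------

def test_constant_feature_converges_to_class_rate():
    X = np.ones((200, 1))
    y = np.r_[np.ones(50), np.zeros(150)]
    ens = fit_gbm(X, y, config=TrainConfig(max_trees=400, learning_rate=0.1))
    p = ens.predict_proba(X)
    assert np.allclose(p, 0.25, atol=1e-3)


def test_perfect_separator_reaches_auroc_one_with_one_tree():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=40).astype(float)
    X = y[:, None] + 0.0
    ens = fit_gbm(X, y, config=TrainConfig(max_trees=1))
    assert auroc(ens.predict_margin(X), y) == 1.0


def test_training_logloss_monotone_nonincreasing():
    """Each Newton step with lambda >= 0 cannot increase training log-loss."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(150, 4))
    y = (X[:, 0] - X[:, 1] + rng.normal(size=150) > 0).astype(float)
    cfg = TrainConfig(max_trees=60, learning_rate=0.1)
    ens = fit_gbm(X, y, config=cfg)
    margin = np.zeros(len(y))
    last_ll = np.inf
    rows = np.arange(len(y))
    for tree in ens.trees:
        raw = np.zeros(len(y))
        from landboost.gbm import _tree_raw
        _tree_raw(tree, X, rows, raw)
        margin = margin + cfg.learning_rate * raw
        p = sigmoid(margin)
        ll = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert ll <= last_ll + 1e-12
        last_ll = ll


def test_base_margin_offsets_predictions():
    """An empty ensemble is the identity on its base margin; a nonzero offset
    shifts fitted log-odds additively."""
    ens = BoostedEnsemble(feature_names=["a"], learning_rate=0.1)
    m = np.array([-1.0, 0.0, 2.0])
    X = np.zeros((3, 1))
    assert np.allclose(ens.predict_proba(X, m), sigmoid(m))
    assert np.allclose(ens.predict_margin(X), 0.0)


def test_all_missing_row_routes_by_missing_directions():
    """Hand-traced 2-node tree: an all-NaN row follows the stored missing
    directions to a leaf."""
    root = TreeNode(feature=0, threshold=0.5, missing_left=False, gain=1.0)
    root.left = TreeNode(weight=-1.0)
    right = TreeNode(feature=1, threshold=0.0, missing_left=True, gain=1.0)
    right.left = TreeNode(weight=2.0)
    right.right = TreeNode(weight=-3.0)
    root.right = right
    ens = BoostedEnsemble(feature_names=["a", "b"], trees=[root], learning_rate=0.5)
    X = np.full((1, 2), np.nan)
    # missing at root -> right; missing at right -> left leaf (weight 2)
    assert ens.predict_margin(X)[0] == pytest.approx(0.5 * 2.0)


def test_single_class_labels_give_constant_ensemble():
    X = np.random.default_rng(1).normal(size=(20, 2))
    y = np.zeros(20)
    with pytest.warns(SingleClassWarning):
        ens = fit_gbm(X, y, config=TrainConfig(max_trees=10))
    assert ens.n_trees == 0
    assert np.all(ens.predict_proba(X) < 1e-5)


def test_rejects_empty_design_and_misaligned_margin():
    with pytest.raises(ValueError):
        fit_gbm(np.zeros((0, 2)), np.array([]))
    with pytest.raises(ValueError):
        fit_gbm(np.zeros((3, 1)), np.array([0, 1, 0]), base_margin=np.zeros(2))


def test_reproducibility_and_row_permutation_invariance():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(120, 3))
    y = (X[:, 0] + rng.normal(size=120) > 0).astype(float)
    cfg = TrainConfig(max_trees=30, seed=5)
    p1 = fit_gbm(X, y, config=cfg).predict_proba(X)
    p2 = fit_gbm(X, y, config=cfg).predict_proba(X)
    assert np.array_equal(p1, p2)
    perm = rng.permutation(120)
    p3 = fit_gbm(X[perm], y[perm], config=cfg).predict_proba(X[perm])
    assert np.allclose(p1[perm], p3)


def test_early_stopping_truncates_to_best_iteration():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(300, 3))
    y = (X[:, 0] + 1.5 * rng.normal(size=300) > 0).astype(float)
    cfg = TrainConfig(max_trees=200, early_stop_rounds=10, seed=2)
    ho = make_holdout(y, 0.25, seed=3)
    ens = fit_gbm(X, y, config=cfg, holdout=ho)
    assert ens.best_iteration == ens.n_trees
    assert ens.n_trees < 200  # stagnation on noisy data stops the run


def test_serialization_round_trips_bit_exactly(tmp_path):
    rng = np.random.default_rng(13)
    X = rng.normal(size=(80, 3))
    X[rng.random((80, 3)) < 0.2] = np.nan
    y = (np.nan_to_num(X[:, 0]) > 0).astype(float)
    ens = fit_gbm(X, y, config=TrainConfig(max_trees=15))
    path = tmp_path / "model.json"
    ens.save(path)
    back = BoostedEnsemble.load(path)
    assert np.array_equal(ens.predict_margin(X), back.predict_margin(X))
    assert json.dumps(ens.to_dict()) == json.dumps(back.to_dict())


def test_predict_handles_missing_columns_as_missing_values():
    rng = np.random.default_rng(17)
    X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
    y = (X["a"].to_numpy() > 0).astype(float)
    ens = fit_gbm(X, y, config=TrainConfig(max_trees=5))
    sub = pd.DataFrame({"a": X["a"]})  # column b absent -> treated as NaN
    full = pd.DataFrame({"a": X["a"], "b": np.nan})
    assert np.array_equal(ens.predict_margin(sub), ens.predict_margin(full))


# ---------------------------------------------------------------------------
# config validation & tuning
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        {"max_depth": 0},
        {"max_depth": 11},
        {"learning_rate": 0.0},
        {"min_child_weight": -1.0},
        {"reg_lambda": -0.1},
        {"cv_folds": 1},
    ],
)
def test_config_ranges_enforced(kwargs):
    with pytest.raises(ValueError):
        TrainConfig(**kwargs)


def test_tune_single_config_returned():
    rng = np.random.default_rng(19)
    X = rng.normal(size=(60, 2))
    y = (X[:, 0] > 0).astype(float)
    cfg = TrainConfig(max_trees=10)
    best, table = tune_by_cv(X, y, grid=[cfg], folds=3, seed=0)
    assert best is cfg
    assert len(table) == 1


def test_tune_tie_breaks_by_depth_then_rate():
    rng = np.random.default_rng(23)
    X = rng.normal(size=(60, 2))
    y = (X[:, 0] > 0).astype(float)
    a = TrainConfig(max_depth=4, learning_rate=0.1, max_trees=5, seed=1)
    b = TrainConfig(max_depth=4, learning_rate=0.1, max_trees=5, seed=1)
    best, table = tune_by_cv(X, y, grid=[a, b], folds=3, seed=0)
    assert best is a  # identical configs: first wins
    assert table["mean_auroc"].nunique() == 1


def test_tune_prefers_interaction_capable_depth():
    """On XOR-style data a depth-2 model should out-cross-validate stumps in
    the vast majority of seeded replicates."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(40 + seed)
        X = rng.normal(size=(240, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(float)
        flip = rng.random(240) < 0.1
        y[flip] = 1 - y[flip]
        grid = [
            TrainConfig(max_depth=1, max_trees=40, seed=seed),
            TrainConfig(max_depth=2, max_trees=40, seed=seed),
        ]
        best, _ = tune_by_cv(X, y, grid=grid, folds=4, seed=seed)
        wins += best.max_depth == 2
    assert wins >= 8


def test_tune_reduces_folds_with_warning_when_rows_scarce():
    X = np.arange(8, dtype=float).reshape(-1, 1)
    y = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
    with pytest.warns(UserWarning, match="reducing cv folds"):
        tune_by_cv(X, y, grid=[TrainConfig(max_trees=3)], folds=10, seed=0)


def test_crosscheck_against_established_boosting_library():
    """On dense complete data, identically configured xgboost predictions
    agree within 0.05 mean absolute probability."""
    xgb = pytest.importorskip("xgboost")
    rng = np.random.default_rng(29)
    X = rng.normal(size=(400, 4))
    y = (0.8 * X[:, 0] - 0.6 * X[:, 2] + rng.normal(size=400) > 0).astype(float)
    cfg = TrainConfig(max_depth=3, learning_rate=0.1, min_child_weight=1.0,
                      max_trees=60, reg_lambda=1.0)
    mine = fit_gbm(X, y, config=cfg).predict_proba(X)
    model = xgb.XGBClassifier(
        n_estimators=60, max_depth=3, learning_rate=0.1, min_child_weight=1.0,
        reg_lambda=1.0, tree_method="exact", base_score=0.5,
    )
    model.fit(X, y)
    theirs = model.predict_proba(X)[:, 1]
    assert np.mean(np.abs(mine - theirs)) < 0.05


def test_logit_sigmoid_roundtrip_and_clipping():
    p = np.array([1e-9, 0.25, 0.5, 1 - 1e-9])
    m = logit(p)
    assert math.isfinite(m[0]) and math.isfinite(m[-1])
    assert np.allclose(sigmoid(logit(np.array([0.25, 0.5, 0.9]))), [0.25, 0.5, 0.9])
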