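"""Gradient-boosted trees with logistic loss, offsets and missing-value splits.

This is a compact second-order (Newton) boosting implementation in the style
of sparsity-aware tree boosting: at every internal node both routings of the
missing values are scored and the gain-maximising direction is stored, so
informative missingness (a lab never ordered) is usable signal.  Two features
matter for the landmark models built on top:

* **base margin** — a fixed per-row log-odds offset added before the trees,
  which is how a previous landmark's predicted risk is carried forward;
* **early stopping on holdout AUROC** — tree count is chosen by watching a
  holdout set and stopping after ``early_stop_rounds`` rounds without
  improvement.

Numeric cells use NaN for "missing"; binary/categorical absence is encoded
as 0 upstream, so those columns are dense.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import auroc

_EPS_GAIN = 1e-12
_PROB_CLIP = 1e-6


class SingleClassWarning(UserWarning):
    """Training labels contain a single class; the fit is a constant."""


@dataclass
class TrainConfig:
    """Hyperparameters for one boosted ensemble.

    ``max_depth`` 2–10, ``learning_rate`` 0.01–0.1 and ``min_child_weight``
    1–10 are the conventional tuning ranges; depth 1 (stumps) is additionally
    allowed for diagnostics.  ``reg_lambda`` is the L2 penalty on leaf
    weights (default 1.0).
    """

    max_depth: int = 3
    learning_rate: float = 0.1
    min_child_weight: float = 1.0
    max_trees: int = 1000
    early_stop_rounds: int = 100
    cv_folds: int = 10
    reg_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= int(self.max_depth) <= 10):
            raise ValueError("max_depth must be in [1, 10]")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.min_child_weight < 0:
            raise ValueError("min_child_weight must be >= 0")
        if self.max_trees < 0:
            raise ValueError("max_trees must be >= 0")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TreeNode:
    """One node of a regression tree on log-odds residuals.

    A leaf holds ``weight`` (a log-odds increment, before the learning-rate
    scaling).  An internal node routes ``value < threshold`` to the left
    child, ``value >= threshold`` to the right, and missing values to the
    side given by ``missing_left``.  ``threshold = +inf`` encodes a pure
    present-vs-missing split.
    """

    feature: int = -1
    threshold: float = math.nan
    missing_left: bool = True
    gain: float = 0.0
    weight: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self, feature_names: Sequence[str]) -> dict:
        if self.is_leaf:
            return {"weight": self.weight.hex() if isinstance(self.weight, float) else self.weight}
        return {
            "feature": feature_names[self.feature],
            "threshold": float(self.threshold).hex(),
            "missing_left": self.missing_left,
            "gain": float(self.gain).hex(),
            "left": self.left.to_dict(feature_names),
            "right": self.right.to_dict(feature_names),
        }

    @staticmethod
    def from_dict(d: dict, feature_index: dict) -> "TreeNode":
        if "weight" in d:
            return TreeNode(weight=float.fromhex(d["weight"]))
        return TreeNode(
            feature=feature_index[d["feature"]],
            threshold=float.fromhex(d["threshold"]),
            missing_left=bool(d["missing_left"]),
            gain=float.fromhex(d["gain"]),
            left=TreeNode.from_dict(d["left"], feature_index),
            right=TreeNode.from_dict(d["right"], feature_index),
        )


@dataclass
class SplitDecision:
    """Best split found at a node (None-like when no valid split exists)."""

    feature: int
    threshold: float
    missing_left: bool
    gain: float


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def logit(p: np.ndarray | float, clip: float = _PROB_CLIP) -> np.ndarray | float:
    p = np.clip(p, clip, 1.0 - clip)
    return np.log(p / (1.0 - p))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Accept a FeatureMatrix-like object, DataFrame or ndarray."""
    if hasattr(X, "values") and hasattr(X, "columns"):
        names = [str(c) for c in X.columns]
        vals = np.asarray(X.values, dtype=float)
        return vals, names
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return arr, [f"f{j}" for j in range(arr.shape[1])]


def find_best_split(
    X: np.ndarray,
    grad: np.ndarray,
    hess: np.ndarray,
    reg_lambda: float = 1.0,
    min_child_weight: float = 1.0,
    presorted: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> Optional[SplitDecision]:
    """Exact greedy split search over all features and both missing directions.

    Candidates are the midpoints between consecutive distinct observed values
    of each feature, plus a pure present-vs-missing split (threshold +inf).
    Gain is the standard second-order loss reduction
    ``1/2 [GL^2/(HL+lam) + GR^2/(HR+lam) - G^2/(H+lam)]`` and both children
    must carry a hessian sum of at least ``min_child_weight``.

    Ties are broken deterministically by candidate order: missing-right
    before missing-left, then feature index, then ascending threshold.
    """
    n, p = X.shape
    if n < 2 or p == 0:
        return None
    Gt = grad.sum()
    Ht = hess.sum()
    if presorted is None:
        order = np.argsort(X, axis=0, kind="stable")  # NaNs sort last
        Xo = np.take_along_axis(X, order, axis=0)
    else:
        order, Xo = presorted
    go = grad[order]
    ho = hess[order]
    present = ~np.isnan(Xo)
    n_present = present.sum(axis=0)  # per feature
    cg = np.cumsum(go, axis=0)
    ch = np.cumsum(ho, axis=0)

    # Present-only prefix sums; Gm/Hm are the missing-value totals per feature.
    idx_last = np.maximum(n_present - 1, 0)
    Gp = np.where(n_present > 0, cg[idx_last, np.arange(p)], 0.0)
    Hp = np.where(n_present > 0, ch[idx_last, np.arange(p)], 0.0)
    Gm = Gt - Gp
    Hm = Ht - Hp

    parent_score = Gt * Gt / (Ht + reg_lambda)

    def child_gain(GL, HL):
        GR = Gt - GL
        HR = Ht - HL
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = 0.5 * (
                GL * GL / (HL + reg_lambda)
                + GR * GR / (HR + reg_lambda)
                - parent_score / 1.0
            )
        ok = (HL >= min_child_weight) & (HR >= min_child_weight)
        return np.where(ok, gain, -np.inf)

    best: Optional[SplitDecision] = None

    if n >= 2:
        # Split after sorted position k (k = 0 .. n-2); requires both sides of
        # the boundary observed and strictly increasing value.
        GLp = cg[:-1]
        HLp = ch[:-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            boundary_ok = present[1:] & (Xo[:-1] < Xo[1:])
        gain_right = np.where(boundary_ok, child_gain(GLp, HLp), -np.inf)
        gain_left = np.where(
            boundary_ok, child_gain(GLp + Gm[None, :], HLp + Hm[None, :]), -np.inf
        )
        for missing_left, gains in ((False, gain_right), (True, gain_left)):
            for j in range(p):
                col = gains[:, j]
                k = int(np.argmax(col))
                g = col[k]
                if g > _EPS_GAIN and (best is None or g > best.gain + _EPS_GAIN):
                    thr = 0.5 * (Xo[k, j] + Xo[k + 1, j])
                    if thr <= Xo[k, j]:  # guard against midpoint rounding down
                        thr = np.nextafter(Xo[k + 1, j], -np.inf)
                    best = SplitDecision(j, float(thr), missing_left, float(g))

    # Pure present-vs-missing split: all observed left, all missing right.
    has_both = (n_present > 0) & (n_present < n)
    gain_pm = np.where(has_both, child_gain(Gp, Hp), -np.inf)
    for j in range(p):
        g = gain_pm[j]
        if g > _EPS_GAIN and (best is None or g > best.gain + _EPS_GAIN):
            best = SplitDecision(j, math.inf, False, float(g))
    return best


def _grow_tree(
    X: np.ndarray,
    grad: np.ndarray,
    hess: np.ndarray,
    rows: np.ndarray,
    depth: int,
    config: TrainConfig,
    root_presort: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> TreeNode:
    g = grad[rows]
    h = hess[rows]
    if depth >= config.max_depth or rows.size < 2:
        return TreeNode(weight=float(-g.sum() / (h.sum() + config.reg_lambda)))
    split = find_best_split(
        X[rows], g, h, reg_lambda=config.reg_lambda,
        min_child_weight=config.min_child_weight,
        presorted=root_presort if depth == 0 else None,
    )
    if split is None:
        return TreeNode(weight=float(-g.sum() / (h.sum() + config.reg_lambda)))
    v = X[rows, split.feature]
    isna = np.isnan(v)
    go_left = np.where(isna, split.missing_left, v < split.threshold)
    node = TreeNode(
        feature=split.feature,
        threshold=split.threshold,
        missing_left=split.missing_left,
        gain=split.gain,
    )
    node.left = _grow_tree(X, grad, hess, rows[go_left], depth + 1, config)
    node.right = _grow_tree(X, grad, hess, rows[~go_left], depth + 1, config)
    return node


def _tree_raw(node: TreeNode, X: np.ndarray, rows: np.ndarray, out: np.ndarray) -> None:
    if node.is_leaf:
        out[rows] += node.weight
        return
    v = X[rows, node.feature]
    isna = np.isnan(v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        go_left = np.where(isna, node.missing_left, v < node.threshold)
    _tree_raw(node.left, X, rows[go_left], out)
    _tree_raw(node.right, X, rows[~go_left], out)


@dataclass
class BoostedEnsemble:
    """Additive tree model on the log-odds scale with an offset.

    ``margin(x) = base_margin + intercept + learning_rate * sum_m tree_m(x)``
    and probabilities are the sigmoid of the margin.  An empty ensemble is
    the identity on its base margin.
    """

    feature_names: list[str]
    trees: list[TreeNode] = field(default_factory=list)
    learning_rate: float = 0.1
    intercept: float = 0.0
    config: Optional[TrainConfig] = None
    best_iteration: Optional[int] = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _align(self, X) -> np.ndarray:
        vals, names = _as_matrix(X)
        if names == self.feature_names:
            return vals
        pos = {c: j for j, c in enumerate(names)}
        out = np.full((vals.shape[0], len(self.feature_names)), np.nan)
        for j, c in enumerate(self.feature_names):
            if c in pos:
                out[:, j] = vals[:, pos[c]]
        return out

    def predict_margin(self, X, base_margin=None) -> np.ndarray:
        vals = self._align(X)
        n = vals.shape[0]
        raw = np.zeros(n)
        rows = np.arange(n)
        for tree in self.trees:
            _tree_raw(tree, vals, rows, raw)
        margin = self.intercept + self.learning_rate * raw
        if base_margin is not None:
            margin = margin + np.asarray(base_margin, dtype=float)
        return margin

    def predict_proba(self, X, base_margin=None) -> np.ndarray:
        return sigmoid(self.predict_margin(X, base_margin))

    def feature_gains(self) -> dict[str, float]:
        """Total split gain per feature (gain-based importance, unnormalised)."""
        gains: dict[str, float] = {}

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            name = self.feature_names[node.feature]
            gains[name] = gains.get(name, 0.0) + node.gain
            walk(node.left)
            walk(node.right)

        for t in self.trees:
            walk(t)
        return gains

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "learning_rate": float(self.learning_rate).hex(),
            "intercept": float(self.intercept).hex(),
            "best_iteration": self.best_iteration,
            "config": asdict(self.config) if self.config else None,
            "trees": [t.to_dict(self.feature_names) for t in self.trees],
        }

    @staticmethod
    def from_dict(d: dict) -> "BoostedEnsemble":
        names = list(d["feature_names"])
        fidx = {c: j for j, c in enumerate(names)}
        cfg = TrainConfig(**d["config"]) if d.get("config") else None
        ens = BoostedEnsemble(
            feature_names=names,
            learning_rate=float.fromhex(d["learning_rate"]),
            intercept=float.fromhex(d["intercept"]),
            config=cfg,
            best_iteration=d.get("best_iteration"),
        )
        ens.trees = [TreeNode.from_dict(t, fidx) for t in d["trees"]]
        return ens

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def load(path) -> "BoostedEnsemble":
        with open(path) as fh:
            return BoostedEnsemble.from_dict(json.load(fh))


def make_holdout(y: np.ndarray, fraction: float = 0.2, seed: int = 0) -> np.ndarray:
    """Seeded stratified holdout row indices (for early stopping)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    idx = []
    for cls in np.unique(y):
        cls_rows = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * cls_rows.size)))
        idx.append(rng.permutation(cls_rows)[:k])
    return np.sort(np.concatenate(idx))


def fit_gbm(
    X,
    y,
    base_margin=None,
    config: Optional[TrainConfig] = None,
    holdout=None,
) -> BoostedEnsemble:
    """Stagewise Newton boosting of the binomial log-loss.

    Per round, gradients ``g_i = p_i - y_i`` and hessians ``h_i = p_i(1-p_i)``
    are evaluated at the current margin (which includes the per-row
    ``base_margin`` offset), a depth-limited tree is grown by exact greedy
    gain search, and the margin is updated by ``learning_rate`` times the
    leaf weights ``-G/(H+lambda)``.

    ``holdout`` may be an array of row indices (excluded from tree fitting,
    used for AUROC early stopping), the string ``"auto"`` (a seeded
    stratified 20% split), or None (no early stopping; runs to
    ``max_trees``).
    """
    config = config or TrainConfig()
    vals, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if vals.shape[0] == 0 or vals.shape[1] == 0:
        raise ValueError("empty design matrix")
    if vals.shape[0] != y.shape[0]:
        raise ValueError("X and y have different lengths")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    if base_margin is None:
        base = np.zeros(y.shape[0])
    else:
        base = np.asarray(base_margin, dtype=float)
        if base.shape[0] != y.shape[0]:
            raise ValueError("base_margin misaligned with y")

    ens = BoostedEnsemble(
        feature_names=names, learning_rate=config.learning_rate, config=config
    )
    if len(np.unique(y)) < 2:
        warnings.warn(
            "single-class labels: returning a constant-margin ensemble",
            SingleClassWarning,
        )
        ens.intercept = float(logit(float(y.mean())))
        ens.best_iteration = 0
        return ens

    if isinstance(holdout, str) and holdout == "auto":
        holdout = make_holdout(y, 0.2, config.seed)
    if holdout is not None:
        holdout = np.asarray(holdout, dtype=int)
        mask = np.ones(y.shape[0], dtype=bool)
        mask[holdout] = False
        train_rows = np.flatnonzero(mask)
        if len(np.unique(y[holdout])) < 2 or len(np.unique(y[train_rows])) < 2:
            raise ValueError("holdout split must leave both classes on both sides")
    else:
        train_rows = np.arange(y.shape[0])

    # Newton-fitted scalar intercept before any trees: with an informative
    # base margin this absorbs population-level shifts in the event rate
    # that AUROC-driven early stopping would never credit.  A zero tree
    # budget skips it so the ensemble stays the identity on its offset.
    if config.max_trees > 0:
        c = 0.0
        for _ in range(10):
            pr = sigmoid(base[train_rows] + c)
            step = (pr.sum() - y[train_rows].sum()) / max(
                (pr * (1.0 - pr)).sum(), 1e-12
            )
            c -= step
            if abs(step) < 1e-12:
                break
        ens.intercept = float(c)
    margin = base + ens.intercept
    best_score = -np.inf
    best_iter = 0
    rounds_since_best = 0
    # the root node sees the same rows every round: sort its columns once
    if config.max_trees > 0 and train_rows.size >= 2:
        Xroot = vals[train_rows]
        root_order = np.argsort(Xroot, axis=0, kind="stable")
        root_presort = (root_order, np.take_along_axis(Xroot, root_order, axis=0))
    else:
        root_presort = None
    for m in range(config.max_trees):
        p = sigmoid(margin)
        grad = p - y
        hess = p * (1.0 - p)
        tree = _grow_tree(vals, grad, hess, train_rows, 0, config, root_presort)
        raw = np.zeros(y.shape[0])
        _tree_raw(tree, vals, np.arange(y.shape[0]), raw)
        margin = margin + config.learning_rate * raw
        ens.trees.append(tree)
        if holdout is not None:
            score = auroc(margin[holdout], y[holdout])
            if score > best_score + 1e-12:
                best_score = score
                best_iter = m + 1
                rounds_since_best = 0
            else:
                rounds_since_best += 1
                if rounds_since_best >= config.early_stop_rounds:
                    break
    if holdout is not None:
        ens.trees = ens.trees[:best_iter]
        ens.best_iteration = best_iter
    else:
        ens.best_iteration = len(ens.trees)
    return ens


def predict_margin(ensemble: BoostedEnsemble, X, base_margin=None) -> np.ndarray:
    """Functional form of :meth:`BoostedEnsemble.predict_margin`."""
    return ensemble.predict_margin(X, base_margin)


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        rows = rng.permutation(np.flatnonzero(y == cls))
        assignment[rows] = np.arange(rows.size) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def tune_by_cv(
    X,
    y,
    base_margin=None,
    grid: Iterable[TrainConfig] = (),
    folds: int = 10,
    seed: int = 0,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Pick hyperparameters by stratified K-fold cross-validated AUROC.

    Each grid point is scored by the mean out-of-fold AUROC; the out-of-fold
    set also serves as the early-stopping holdout within each fold.  Ties go
    to the smaller ``max_depth``, then the smaller ``learning_rate``, then
    grid order.  Returns the winning config and the full score table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty tuning grid")
    y = np.asarray(y, dtype=float)
    n_pos = int(y.sum())
    n_min = min(n_pos, y.shape[0] - n_pos)
    if folds > n_min:
        warnings.warn(f"reducing cv folds from {folds} to {max(2, n_min)}")
        folds = max(2, n_min)
    fold_rows = _stratified_folds(y, folds, seed)
    vals, names = _as_matrix(X)
    base = np.zeros(y.shape[0]) if base_margin is None else np.asarray(base_margin, float)

    rows = []
    scores = []
    for gi, cfg in enumerate(grid):
        fold_scores = []
        for f, test_rows in enumerate(fold_rows):
            ens = fit_gbm(
                pd.DataFrame(vals, columns=names), y, base, cfg, holdout=test_rows
            )
            m = ens.predict_margin(pd.DataFrame(vals[test_rows], columns=names), base[test_rows])
            fold_scores.append(auroc(m, y[test_rows]))
        mean_score = float(np.mean(fold_scores))
        scores.append(mean_score)
        rows.append(
            {
                "grid_index": gi,
                "max_depth": cfg.max_depth,
                "learning_rate": cfg.learning_rate,
                "min_child_weight": cfg.min_child_weight,
                "mean_auroc": mean_score,
                **{f"fold{f}_auroc": s for f, s in enumerate(fold_scores)},
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(grid)),
        key=lambda i: (-scores[i], grid[i].max_depth, grid[i].learning_rate, i),
    )
    return grid[order[0]], table
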