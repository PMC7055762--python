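"""Landmark-boosting and the three comparator temporal training schemes.

At every yearly landmark t the task is the same: among patients still at
risk and observable, predict the probability of a first event in the coming
year from everything recorded strictly before the landmark.  Four training
schemes are provided:

* ``landmark_boosting`` — the sequential scheme: the model at landmark t is
  boosted *on top of* the previous landmark's predicted risk, carried in as
  a per-patient log-odds base margin, with new trees fit to the updated
  (latest-value) predictors.  Patients eligible at t with no prediction at
  t-1 (an NA year) enter at a cold-start margin, the log-odds of the
  training prevalence at t.
* ``latest_value`` — an independent boosted model per landmark on the
  latest-value design.
* ``stack_temporal`` — an independent model per landmark on the stacked
  per-window design.
* ``discrete_survival`` — one pooled model over person-period rows, applied
  per landmark at prediction time.

Hyperparameters are tuned by stratified 10-fold CV at each landmark (a
``retune_each_landmark=False`` switch reuses the first landmark's choice);
tree counts are governed by holdout-AUROC early stopping under a per-landmark
cap (1000 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import LandmarkDataset
from .gbm import (
    BoostedEnsemble,
    TrainConfig,
    _as_matrix,
    _stratified_folds,
    fit_gbm,
    logit,
    sigmoid,
    tune_by_cv,
)

#: carried margins are clipped to the log-odds of [1e-6, 1 - 1e-6]
_MARGIN_CLIP = float(logit(1.0 - 1e-6))

METHODS = ("landmark_boosting", "latest_value", "stack_temporal", "discrete_survival")


@dataclass
class FittedMethod:
    """Per-landmark trained ensembles for one temporal scheme.

    ``discrete_survival`` holds a single pooled ensemble; the others hold
    one per landmark.  ``cold_margins[t]`` is the log-odds entry point for
    patients without a carried prediction (landmark-boosting only).
    """

    method: str
    ensembles: list[BoostedEnsemble]
    configs: list[TrainConfig]
    cold_margins: list[float] = field(default_factory=list)
    cv_tables: list[Optional[pd.DataFrame]] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.ensembles)


def _pick_config(
    X, y, base_margin, grid: Sequence[TrainConfig], folds: int, seed: int
) -> tuple[TrainConfig, Optional[pd.DataFrame]]:
    grid = list(grid)
    if len(grid) == 1:
        return grid[0], None
    best, table = tune_by_cv(X, y, base_margin, grid, folds=folds, seed=seed)
    return best, table


def _cross_fitted_margins(
    X, y: np.ndarray, base: np.ndarray, cfg: TrainConfig, n_folds: int = 3
) -> np.ndarray:
    """Out-of-fold predicted margins for the training patients.

    The margin carried to the next landmark for a *training* patient must
    not come from a model that saw that patient's label, or the carried
    baseline is optimistic in training but not at prediction time and the
    incremental trees underfit the real correction.  Each fold is predicted
    by an auxiliary ensemble fit on the remaining folds with the same
    hyperparameters (early-stopped on an internal holdout).
    """
    vals, _ = _as_matrix(X)
    out = np.empty(y.shape[0])
    folds = _stratified_folds(y, n_folds, cfg.seed)
    for f, rows in enumerate(folds):
        mask = np.ones(y.shape[0], dtype=bool)
        mask[rows] = False
        tr = np.flatnonzero(mask)
        aux_cfg = replace(cfg, seed=cfg.seed + 101 * (f + 1))
        aux = fit_gbm(
            vals[tr], y[tr], base[tr], aux_cfg,
            holdout="auto" if aux_cfg.max_trees else None,
        )
        out[rows] = aux.predict_margin(vals[rows], base[rows])
    return out


def fit_landmark_boosting(
    datasets: Sequence[LandmarkDataset],
    grid: Sequence[TrainConfig],
    folds: int = 10,
    max_trees_per_landmark: Optional[Sequence[int]] = None,
    tree_cap: int = 1000,
    retune_each_landmark: bool = True,
    cold_start: str = "prevalence",
    carry_folds: int = 3,
) -> FittedMethod:
    """Sequentially boosted landmark models with carried baseline risk.

    ``datasets`` are the per-landmark latest-value designs, ordered by t.
    t=0 is fit with a zero base margin; for t >= 1 each patient's base
    margin is the previous landmark's predicted log-odds (the logit of the
    predicted probability, clipped to [1e-6, 1-1e-6]), computed
    recursively.  Margins carried for training patients are *out-of-fold*
    (``carry_folds``-fold cross-fitting) so the baseline is as honest in
    training as it will be at prediction time; pass ``carry_folds=0`` to
    carry in-sample margins instead.  Patients eligible at t without a t-1
    prediction cold-start at the logit of landmark-t training prevalence
    (or 0 with ``cold_start="zero"``).  ``max_trees_per_landmark``
    overrides the tree cap per landmark (0 carries the previous prediction
    through unchanged); an empty landmark dataset copies the previous model
    forward with a warning.
    """
    ensembles: list[BoostedEnsemble] = []
    configs: list[TrainConfig] = []
    cold_margins: list[float] = []
    cv_tables: list[Optional[pd.DataFrame]] = []
    margins: dict = {}
    chosen: Optional[TrainConfig] = None
    n_landmarks = len(datasets)
    for t, ds in enumerate(datasets):
        if ds.n == 0:
            if not ensembles:
                raise ValueError("first landmark dataset is empty")
            warnings.warn(f"empty dataset at landmark {t}: copying model forward")
            ensembles.append(ensembles[-1])
            configs.append(configs[-1])
            cold_margins.append(cold_margins[-1])
            cv_tables.append(None)
            continue
        if t == 0:
            cold = 0.0
            base = np.zeros(ds.n)
        else:
            prev = float(np.mean(ds.y)) if cold_start == "prevalence" else None
            cold = float(logit(prev)) if prev is not None else 0.0
            base = np.array([margins.get(pid, cold) for pid in ds.patient_ids])
        if chosen is None or retune_each_landmark:
            chosen, table = _pick_config(
                ds.X, ds.y, base, grid, folds, grid[0].seed
            )
        else:
            table = None
        cap = tree_cap
        if max_trees_per_landmark is not None:
            cap = max_trees_per_landmark[t]
        cfg = replace(chosen, max_trees=min(chosen.max_trees, cap))
        ens = fit_gbm(ds.X, ds.y, base, cfg, holdout="auto" if cfg.max_trees else None)
        if t + 1 < n_landmarks:
            if carry_folds and cfg.max_trees and len(np.unique(ds.y)) == 2:
                carried = _cross_fitted_margins(ds.X, ds.y, base, cfg, carry_folds)
            else:
                carried = ens.predict_margin(ds.X, base)
            carried = np.clip(carried, -_MARGIN_CLIP, _MARGIN_CLIP)
            for pid, m in zip(ds.patient_ids, carried):
                margins[pid] = float(m)
        ensembles.append(ens)
        configs.append(cfg)
        cold_margins.append(cold)
        cv_tables.append(table)
    return FittedMethod(
        method="landmark_boosting",
        ensembles=ensembles,
        configs=configs,
        cold_margins=cold_margins,
        cv_tables=cv_tables,
    )


def fit_comparator(
    method: str,
    datasets: Sequence[LandmarkDataset] | LandmarkDataset,
    grid: Sequence[TrainConfig],
    folds: int = 10,
    retune_each_landmark: bool = True,
) -> FittedMethod:
    """Train a comparator scheme.

    ``latest_value`` and ``stack_temporal`` fit one independent model per
    landmark on their designs; ``discrete_survival`` fits exactly one pooled
    model on the person-period dataset regardless of the horizon.
    """
    if method == "landmark_boosting":
        return fit_landmark_boosting(
            datasets, grid, folds=folds, retune_each_landmark=retune_each_landmark
        )
    if method in ("latest_value", "stack_temporal"):
        ensembles, configs, tables = [], [], []
        chosen = None
        for ds in datasets:
            if chosen is None or retune_each_landmark:
                chosen, table = _pick_config(
                    ds.X, ds.y, None, grid, folds, grid[0].seed
                )
            else:
                table = None
            ensembles.append(fit_gbm(ds.X, ds.y, None, chosen, holdout="auto"))
            configs.append(chosen)
            tables.append(table)
        return FittedMethod(method, ensembles, configs, cv_tables=tables)
    if method == "discrete_survival":
        ds = datasets if isinstance(datasets, LandmarkDataset) else datasets[0]
        chosen, table = _pick_config(ds.X, ds.y, None, grid, folds, grid[0].seed)
        ens = fit_gbm(ds.X, ds.y, None, chosen, holdout="auto")
        return FittedMethod(method, [ens], [chosen], cv_tables=[table])
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def predict_landmarks(
    fitted: FittedMethod, test_datasets: Sequence[LandmarkDataset] | LandmarkDataset
) -> dict[int, tuple[list, np.ndarray]]:
    """Per-landmark predicted probabilities for the eligible test patients.

    Returns ``{t: (patient_ids, probabilities)}``.  For landmark-boosting
    the recursion over carried margins is replayed on the test cohort; for
    the pooled discrete-survival model the person-period rows are predicted
    at once and split by window.
    """
    out: dict[int, tuple[list, np.ndarray]] = {}
    if fitted.method == "discrete_survival":
        ds = test_datasets if isinstance(test_datasets, LandmarkDataset) else test_datasets[0]
        probs = fitted.ensembles[0].predict_proba(ds.X)
        for (pid, t), p in zip(ds.patient_ids, probs):
            ids, ps = out.setdefault(t, ([], []))
            ids.append(pid)
            ps.append(p)
        return {t: (ids, np.asarray(ps)) for t, (ids, ps) in sorted(out.items())}
    if fitted.method == "landmark_boosting":
        margins: dict = {}
        for t, ds in enumerate(test_datasets):
            if t >= len(fitted.ensembles):
                break
            cold = fitted.cold_margins[t]
            base = (
                np.zeros(ds.n)
                if t == 0
                else np.array([margins.get(pid, cold) for pid in ds.patient_ids])
            )
            margin = fitted.ensembles[t].predict_margin(ds.X, base)
            clipped = np.clip(margin, -_MARGIN_CLIP, _MARGIN_CLIP)
            for pid, m in zip(ds.patient_ids, clipped):
                margins[pid] = float(m)
            out[t] = (list(ds.patient_ids), sigmoid(margin))
        return out
    for t, ds in enumerate(test_datasets):
        if t >= len(fitted.ensembles):
            break
        out[t] = (list(ds.patient_ids), fitted.ensembles[t].predict_proba(ds.X))
    return out


def risk_percentiles(scores: np.ndarray) -> np.ndarray:
    """Average-rank percentile of each score within its population, on [0, 100].

    Constant scores all land on the midpoint (50)."""
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores, method="average")
    return (ranks - 0.5) / scores.size * 100.0


def predict_rolling(
    fitted: FittedMethod,
    test_datasets,
    labels_by_landmark: Optional[dict[int, dict]] = None,
) -> pd.DataFrame:
    """Rolling per-landmark predictions with within-landmark percentiles.

    Returns one row per (patient, landmark) the patient is eligible for:
    ``patient_id, landmark, probability, percentile, label``.  A patient's
    risk trajectory is their rows across landmarks (see
    :func:`risk_trajectories`).
    """
    per_lm = predict_landmarks(fitted, test_datasets)
    rows = []
    for t, (pids, probs) in sorted(per_lm.items()):
        pct = risk_percentiles(probs)
        for pid, p, q in zip(pids, probs, pct):
            label = None
            if labels_by_landmark is not None:
                label = labels_by_landmark.get(t, {}).get(pid)
            rows.append(
                {
                    "patient_id": pid,
                    "landmark": t,
                    "probability": float(p),
                    "percentile": float(q),
                    "label": label,
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "landmark", "probability", "percentile", "label"]
    )


def risk_trajectories(predictions: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group a predictions table into per-patient risk trajectories."""
    return {
        str(pid): grp.sort_values("landmark").reset_index(drop=True)
        for pid, grp in predictions.groupby("patient_id")
    }
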