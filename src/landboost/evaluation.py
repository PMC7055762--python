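"""Discrimination, top-40% threshold metrics, bootstrap CIs and O:E calibration.

The metric suite mirrors the evaluation protocol of a rolling 1-year risk
model: AUROC and AUPRC for overall discrimination; sensitivity, specificity,
PPV and NPV with the top 40th percentile of predicted risk treated as the
positive call (a fair fixed-workload comparison between models); percentile
bootstrap confidence intervals from a configurable number of resamples; and
regional calibration via observed-to-expected (O:E) event ratios in 20
equal-width probability bins, each tested for significant miscalibration
with an exact binomial test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined on the given sample (e.g. one class)."""


def _check_pair(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d arrays")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    return s, y


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(random positive outranks random negative), ties 1/2."""
    s, y = _check_pair(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes")
    ranks = stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve (no interpolation).

    Sweeping thresholds downward over distinct scores, the area is
    ``sum_k precision_k * (recall_k - recall_{k-1})``.  With constant scores
    this degenerates to a single point and returns the prevalence.
    """
    s, y = _check_pair(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    # threshold boundaries: last index of each tied block of scores
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp_b = tp[last_of_block]
    fp_b = fp[last_of_block]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum(precision * (recall - prev_recall)))


@dataclass
class ThresholdMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_flagged: int
    n: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def threshold_metrics(scores, labels, top_fraction: float = 0.40) -> ThresholdMetrics:
    """2x2 metrics flagging the ``ceil(top_fraction * n)`` highest scores positive.

    Ties at the cut are broken by stable score-then-original-index order.
    Metrics whose denominator is empty come back as NaN with a warning.
    """
    s, y = _check_pair(scores, labels)
    n = s.size
    if n < 1:
        raise ValueError("empty sample")
    n_flag = int(math.ceil(top_fraction * n))
    order = np.argsort(-s, kind="stable")
    flagged = np.zeros(n, dtype=bool)
    flagged[order[:n_flag]] = True
    tp = float(np.sum(flagged & (y == 1)))
    fp = float(np.sum(flagged & (y == 0)))
    fn = float(np.sum(~flagged & (y == 1)))
    tn = float(np.sum(~flagged & (y == 0)))

    def ratio(a, b, name):
        if b == 0:
            warnings.warn(f"{name} undefined (empty denominator)")
            return math.nan
        return a / b

    return ThresholdMetrics(
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        n_flagged=n_flag,
        n=n,
    )


def bootstrap_ci(metric, scores, labels, n_boot: int = 30, seed: int = 0):
    """(2.5th, 50th, 97.5th) percentiles of ``metric`` over bootstrap resamples.

    Rows are resampled with replacement; a resample on which the metric is
    undefined (e.g. a single class) is redrawn, up to 100 attempts each, then
    skipped with a warning.  The metric must be computable on the full
    sample.
    """
    s, y = _check_pair(scores, labels)
    metric(s, y)  # raises if undefined on the full sample
    rng = np.random.default_rng(seed)
    n = s.size
    values = []
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            try:
                values.append(metric(s[idx], y[idx]))
                break
            except UndefinedMetricError:
                continue
        else:
            warnings.warn("bootstrap resample skipped: metric undefined 100 times")
    if not values:
        raise UndefinedMetricError("metric undefined on every bootstrap resample")
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
    return float(lo), float(med), float(hi)


@dataclass
class CalibrationBins:
    """Per-bin O:E calibration table on the predicted-probability scale."""

    table: pd.DataFrame = field(repr=False)
    n_bins: int = 20
    alpha: float = 0.05

    @property
    def total_observed(self) -> float:
        return float(self.table["observed"].sum())

    @property
    def total_expected(self) -> float:
        return float(self.table["expected"].sum())

    @property
    def overall_oe(self) -> float:
        return self.total_observed / self.total_expected


def calibration_bins(
    scores, labels, n_bins: int = 20, alpha: float = 0.05, test: str = "binomial"
) -> CalibrationBins:
    """Equal-width probability bins with exact-binomial miscalibration flags.

    Per non-empty bin: ``O`` observed events, ``E`` the sum of predicted
    probabilities, and an exact binomial tail test of O against
    ``Binomial(n_bin, E/n_bin)`` in the direction of the discrepancy
    (``P(X <= O)`` when O < E, ``P(X >= O)`` when O > E).  A bin is
    *overpredicted* when p < alpha and O < E, *underpredicted* when p <
    alpha and O > E, else *calibrated*.  ``test="poisson"`` swaps in a
    Poisson tail test with mean E.
    """
    s, y = _check_pair(scores, labels)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must be probabilities in [0, 1]")
    bin_idx = np.minimum((s * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = bin_idx == b
        nb = int(in_bin.sum())
        lo, hi = b / n_bins, (b + 1) / n_bins
        if nb == 0:
            rows.append(
                {
                    "bin": b, "lower": lo, "upper": hi, "n": 0,
                    "observed": 0.0, "expected": 0.0,
                    "oe_ratio": math.nan, "p_value": math.nan, "flag": "",
                }
            )
            continue
        obs = float(y[in_bin].sum())
        exp = float(s[in_bin].sum())
        if test == "binomial":
            rate = min(exp / nb, 1.0)
            if obs < exp:
                p = float(stats.binom.cdf(obs, nb, rate))
            elif obs > exp:
                p = float(stats.binom.sf(obs - 1, nb, rate))
            else:
                p = 1.0
        elif test == "poisson":
            if obs < exp:
                p = float(stats.poisson.cdf(obs, exp))
            elif obs > exp:
                p = float(stats.poisson.sf(obs - 1, exp))
            else:
                p = 1.0
        else:
            raise ValueError(f"unknown calibration test {test!r}")
        if exp > 0 and p < alpha and obs < exp:
            flag = "overpredicted"
        elif exp > 0 and p < alpha and obs > exp:
            flag = "underpredicted"
        else:
            flag = "calibrated"
        rows.append(
            {
                "bin": b, "lower": lo, "upper": hi, "n": nb,
                "observed": obs, "expected": exp,
                "oe_ratio": obs / exp if exp > 0 else math.nan,
                "p_value": float(p), "flag": flag,
            }
        )
    return CalibrationBins(table=pd.DataFrame(rows), n_bins=n_bins, alpha=alpha)


def pearson_pred_actual(scores, labels) -> float:
    """Pearson r between predicted probability and the 0/1 outcome."""
    s, y = _check_pair(scores, labels)
    if np.std(s) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("Pearson correlation undefined at zero variance")
    return float(stats.pearsonr(s, y).statistic)


def metric_report_row(scores, labels, n_boot: int = 30, seed: int = 0,
                      top_fraction: float = 0.40) -> dict:
    """All headline metrics with bootstrap percentiles, as one flat dict."""
    s, y = _check_pair(scores, labels)
    out = {"n": int(s.size), "prevalence": float(y.mean())}
    metrics = {
        "auroc": auroc,
        "auprc": auprc,
        "pearson_r": pearson_pred_actual,
        **{
            name: (lambda sc, yy, _n=name: getattr(
                threshold_metrics(sc, yy, top_fraction), _n))
            for name in ("sensitivity", "specificity", "ppv", "npv")
        },
    }
    for name, fn in metrics.items():
        try:
            out[name] = fn(s, y)
            lo, med, hi = bootstrap_ci(fn, s, y, n_boot=n_boot, seed=seed)
        except UndefinedMetricError:
            out[name] = math.nan
            lo = med = hi = math.nan
        out[f"{name}_lo"] = lo
        out[f"{name}_med"] = med
        out[f"{name}_hi"] = hi
    return out


def importance_rank_drift(landmark_ensemble) -> pd.DataFrame:
    """Per-feature importance-rank trajectories across landmark models.

    Features are ranked within each landmark model by normalised total split
    gain (dense ranks, 1 = most important); a feature absent from a model is
    assigned rank ``n_features + 1`` for that model.  The drift statistic is
    the Pearson correlation between a feature's rank and the landmark index:
    r < 0 means the feature became *more* important over time.  Features
    whose rank never changes have undefined r and are reported as stable.
    """
    ensembles = getattr(landmark_ensemble, "ensembles", landmark_ensemble)
    ensembles = list(ensembles)
    if len(ensembles) < 2:
        raise ValueError("rank drift needs at least two landmark models")
    gain_maps = []
    for ens in ensembles:
        gains = ens.feature_gains()
        total = sum(gains.values())
        gain_maps.append({k: v / total for k, v in gains.items()} if total > 0 else {})
    features = sorted(set().union(*gain_maps))
    rank_maps = []
    for gains in gain_maps:
        present = sorted(gains, key=lambda f: (-gains[f], f))
        dense = {}
        last_gain, rank = None, 0
        for f in present:
            if gains[f] != last_gain:
                rank += 1
                last_gain = gains[f]
            dense[f] = rank
        absent_rank = len(gains) + 1
        rank_maps.append({f: dense.get(f, absent_rank) for f in features})
    t = np.arange(len(ensembles), dtype=float)
    rows = []
    for f in features:
        ranks = np.array([rm[f] for rm in rank_maps], dtype=float)
        if np.std(ranks) == 0:
            r = math.nan
            trend = "stable"
        else:
            r = float(stats.pearsonr(ranks, t).statistic)
            trend = "rising" if r < 0 else ("falling" if r > 0 else "stable")
        rows.append(
            {"feature": f, **{f"rank_t{int(ti)}": rk for ti, rk in zip(t, ranks)},
             "pearson_r": r, "trend": trend}
        )
    return pd.DataFrame(rows)
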