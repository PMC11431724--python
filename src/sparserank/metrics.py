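"""Evaluation metrics and the train/test split protocol.

R-squared uses its sum-of-squared-errors form (1 - SSE/SST), so it can be
negative on test data when a model predicts worse than the mean; for
meta-analysis and reporting, negative values are clamped to zero (never
inside a tuning loss).  AUC is the Mann-Whitney rank statistic with the
midrank convention for ties.  Binomial deviance is -2 x log-likelihood and
penalizes confident wrong predictions more than uncertain ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split as _sk_split

__all__ = [
    "PredictionSet",
    "MetricReport",
    "rmse",
    "r_squared",
    "clamp_r_squared",
    "auc",
    "binomial_deviance",
    "train_test_split",
    "evaluate_predictions",
]

PROB_CLIP = 1e-10


@dataclass
class PredictionSet:
    truth: np.ndarray
    prediction: np.ndarray

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=float)
        self.prediction = np.asarray(self.prediction, dtype=float)
        if self.truth.shape != self.prediction.shape:
            raise ValueError("truth and prediction lengths differ")


@dataclass
class MetricReport:
    n: int
    rmse: float | None = None
    r_squared: float | None = None
    r_squared_clamped: float | None = None
    auc: float | None = None
    deviance: float | None = None


def rmse(truth, prediction) -> float:
    t = np.asarray(truth, dtype=float)
    p = np.asarray(prediction, dtype=float)
    return float(np.sqrt(np.mean((t - p) ** 2)))


def r_squared(truth, prediction) -> float:
    """1 - SSE/SST; 0 means no better than predicting the mean, may be < 0."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(prediction, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 observations")
    sst = np.sum((t - t.mean()) ** 2)
    if sst == 0:
        raise ValueError("constant truth: R-squared undefined")
    return float(1.0 - np.sum((t - p) ** 2) / sst)


def clamp_r_squared(value: float) -> float:
    """max(value, 0) — the clamping rule applied before meta-modeling."""
    return max(float(value), 0.0)


def auc(truth, score) -> float:
    """Probability that a random positive outranks a random negative."""
    t = np.asarray(truth)
    if len(np.unique(t)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(t, np.asarray(score, dtype=float)))


def binomial_deviance(truth, probability) -> float:
    """-2 * sum[y log p + (1-y) log(1-p)] with probabilities clipped."""
    y = np.asarray(truth, dtype=float)
    p = np.clip(np.asarray(probability, dtype=float), PROB_CLIP, 1 - PROB_CLIP)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_test_split(n: int, test_fraction: float = 0.20, seed: int = 0, labels=None):
    """Disjoint, exhaustive train/test index partition; |test| = round(n * fraction)."""
    if n < 5:
        raise ValueError("need at least 5 observations to split")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    strat = None
    if labels is not None:
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < 2:
            warnings.warn("a class has fewer than 2 members; stratification relaxed")
        else:
            strat = labels
    train_idx, test_idx = _sk_split(
        np.arange(n), test_size=n_test, random_state=seed, stratify=strat
    )
    return np.sort(train_idx), np.sort(test_idx)


def evaluate_predictions(truth, prediction, family: str) -> MetricReport:
    """All applicable metrics for one prediction set."""
    ps = PredictionSet(truth, prediction)
    if family == "gaussian":
        rsq = r_squared(ps.truth, ps.prediction)
        return MetricReport(
            n=ps.truth.size,
            rmse=rmse(ps.truth, ps.prediction),
            r_squared=rsq,
            r_squared_clamped=clamp_r_squared(rsq),
        )
    return MetricReport(
        n=ps.truth.size,
        auc=auc(ps.truth, ps.prediction),
        deviance=binomial_deviance(ps.truth, ps.prediction),
    )
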