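"""ROC curves, AUC, concave-curve flipping, and single-feature weak learners.

A feature whose empirical ROC curve lies below the chance diagonal
(AUC < 0.5) is a *reversed* predictor: flipping its polarity reflects the
curve above the diagonal, so the usable selection strength of a feature is
|AUC − 0.5| regardless of direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present")
    return pos


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann–Whitney AUC: P(pos score > neg score) + 0.5·P(tie).

    Computed from midranks, so tied scores get exactly half credit.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _check_binary(labels)
    n_pos = int(pos.sum())
    n_neg = scores.size - n_pos
    ranks = rankdata(scores)  # average ranks; exact multiples of 0.5
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u) / (n_pos * n_neg)


def signed_auc(scores, labels) -> float:
    """a − 0.5: negative exactly when the ROC curve is concave (a < 0.5)."""
    return auc(scores, labels) - 0.5


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC polyline from (0,0) to (1,1); ties give diagonal steps."""

    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def points(self):
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def area(self) -> float:
        """Area under the polyline by the trapezoid rule."""
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores, labels) -> RocCurve:
    """Standard empirical ROC from sweeping the threshold over the scores."""
    scores = np.asarray(scores, dtype=float)
    pos = _check_binary(labels)
    fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr)


@dataclass(frozen=True)
class WeakClassifier:
    """Single-feature threshold rule: positive iff polarity·(value − θ) > 0."""

    feature_index: int
    threshold: float
    polarity: int
    auc: float

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be ±1")

    @property
    def strength(self) -> float:
        return abs(self.auc - 0.5)

    def predict(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return self.polarity * (values - self.threshold) > 0

    def to_dict(self) -> dict:
        return {
            "feature_id": int(self.feature_index),
            "threshold": float(self.threshold),
            "polarity": int(self.polarity),
            "auc": float(self.auc),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeakClassifier":
        return cls(
            feature_index=int(d["feature_id"]),
            threshold=float(d["threshold"]),
            polarity=int(d["polarity"]),
            auc=float(d["auc"]),
        )


@dataclass
class WeakFitDiagnostics:
    """Operating-point counts of a fitted weak classifier on its data."""

    youden_j: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    degenerate: bool


def _fit_weak_batch(values: np.ndarray, labels: np.ndarray):
    """Fit one weak classifier per column of ``values`` (vectorized).

    Polarity follows the sign of a − 0.5 (ties → +1).  The threshold is the
    midpoint between consecutive distinct sorted values maximizing Youden's
    J = sensitivity + specificity − 1 under that polarity; J-ties break
    toward higher specificity, then the smaller threshold.  Columns with a
    single distinct value are degenerate (threshold at that value, J = 0,
    everything predicted negative).

    Returns arrays (auc, polarity, threshold, J, sensitivity, specificity,
    tp, tn, degenerate), one entry per column.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    pos = _check_binary(labels)
    n, n_feat = values.shape
    n_pos = int(pos.sum())
    n_neg = n - n_pos
    cols = np.arange(n_feat)

    ranks = rankdata(values, axis=0)
    u2 = np.rint(2.0 * (ranks[pos].sum(axis=0) - n_pos * (n_pos + 1) / 2.0)).astype(np.int64)
    aucs = u2 / (2.0 * n_pos * n_neg)
    polarity = np.where(u2 >= n_pos * n_neg, 1, -1)  # ties (a == 0.5) -> +1

    order = np.argsort(values, axis=0, kind="stable")
    v_sorted = np.take_along_axis(values, order, axis=0)
    if n < 2:
        raise ValueError("need at least 2 examples")
    y_sorted = np.take_along_axis(np.broadcast_to(pos[:, None], values.shape), order, axis=0)

    # cut i places the threshold between sorted positions i and i+1;
    # only cuts between distinct values are admissible midpoints
    pos_cum = np.cumsum(y_sorted, axis=0)[:-1].astype(np.int64)
    neg_cum = np.arange(1, n, dtype=np.int64)[:, None] - pos_cum
    valid = np.diff(v_sorted, axis=0) > 0
    degenerate = ~valid.any(axis=0)

    # tp/tn counts under the chosen polarity (+1: predict positive above cut)
    plus = polarity[None, :] == 1
    tp_cut = np.where(plus, n_pos - pos_cum, pos_cum)
    tn_cut = np.where(plus, neg_cum, n_neg - neg_cum)

    # lexicographic argmax in exact integer arithmetic:
    # J ordering == ordering of tp*N + tn*P; J-ties -> higher specificity
    # (higher tn); remaining ties -> first (smallest threshold) via argmax.
    key = (tp_cut * n_neg + tn_cut * n_pos) * np.int64(n_neg + 1) + tn_cut
    best = np.argmax(np.where(valid, key, np.int64(-1)), axis=0)

    thresholds = (v_sorted[best, cols] + v_sorted[best + 1, cols]) / 2.0
    tp = tp_cut[best, cols]
    tn = tn_cut[best, cols]

    if degenerate.any():
        d = degenerate
        thresholds = np.where(d, v_sorted[0, cols], thresholds)
        polarity = np.where(d, 1, polarity)
        tp = np.where(d, 0, tp)
        tn = np.where(d, n_neg, tn)  # constant rule predicts all negative

    sens_best = tp / n_pos
    spec_best = tn / n_neg
    j_best = sens_best + spec_best - 1.0
    return aucs, polarity, thresholds, j_best, sens_best, spec_best, tp, tn, degenerate


def fit_weak(values, labels) -> tuple[WeakClassifier, WeakFitDiagnostics]:
    """Fit a single-feature threshold classifier (see ``_fit_weak_batch``)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("fit_weak expects a single feature column")
    aucs, pol, thr, j, sens, spec, tp, tn, degen = _fit_weak_batch(values[:, None], labels)
    clf = WeakClassifier(
        feature_index=0, threshold=float(thr[0]), polarity=int(pol[0]), auc=float(aucs[0])
    )
    diag = WeakFitDiagnostics(
        youden_j=float(j[0]),
        sensitivity=float(sens[0]),
        specificity=float(spec[0]),
        tp=int(tp[0]),
        tn=int(tn[0]),
        degenerate=bool(degen[0]),
    )
    return clf, diag


def classifiers_to_json(classifiers: Sequence[WeakClassifier], path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in classifiers], indent=1))


def classifiers_from_json(path: str | Path) -> list[WeakClassifier]:
    return [WeakClassifier.from_dict(d) for d in json.loads(Path(path).read_text())]
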