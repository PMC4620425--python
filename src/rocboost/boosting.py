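"""ROC-space boosting feature selection.

Each round fits a threshold weak learner to every remaining feature,
admits the features that pass the configured selection condition, and
picks the admissible feature with the largest strength |a − 0.5|.  The
examples the chosen learner classifies correctly and the chosen feature
are then removed, and the loop restarts on what is left.  The loop stops
when no admissible feature remains, when one class of examples is
exhausted, or at a safety bound on rounds.

Selection conditions:

* ``auc_only`` — strength > epsilon_stop.
* ``ratio``   — additionally |r − r′| ≤ ratio_tolerance, where r = p/n is
  the positive/negative class ratio of the original training set and
  r′ = p′/n′ the same ratio among the training examples the candidate
  classifies correctly.  Candidates correct on only one class (p′ = 0 or
  n′ = 0) are inadmissible.  This penalizes features that serve one class
  only — the failure mode of pure-AUC selection under class imbalance —
  and, because it is judged on the whole training set, also features whose
  threshold was overfitted to a residual handful of examples.
* ``sens_spec`` — sensitivity and specificity of the fitted learner must
  each exceed stated minima (the cascade-style rule this method
  generalizes).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .roc import WeakClassifier, _fit_weak_batch, auc

logger = logging.getLogger(__name__)

_MODE_ALIASES = {"ratio_constrained": "ratio"}
MODES = ("auc_only", "ratio", "sens_spec")


@dataclass(frozen=True)
class SelectionCondition:
    mode: str = "ratio"
    epsilon_stop: float = 0.0  # strength must strictly exceed this
    ratio_tolerance: float = 1.0
    min_sensitivity: float = 0.0
    min_specificity: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", _MODE_ALIASES.get(self.mode, self.mode))
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.epsilon_stop < 0:
            raise ValueError("epsilon_stop must be >= 0")
        if self.mode == "ratio" and self.ratio_tolerance <= 0:
            raise ValueError("ratio_tolerance must be > 0 in ratio mode")


@dataclass(frozen=True)
class RatioStats:
    """Class-ratio bookkeeping for one candidate's predictions."""

    p: int
    n: int
    p_prime: int
    n_prime: int

    @property
    def r(self) -> float:
        return self.p / self.n

    @property
    def r_prime(self) -> float | None:
        return None if self.n_prime == 0 else self.p_prime / self.n_prime

    @property
    def ratio_gap(self) -> float:
        """|r − r′|, infinite when r′ is undefined (n′ == 0)."""
        rp = self.r_prime
        return math.inf if rp is None else abs(self.r - rp)


def compute_ratio_stats(labels, predictions) -> RatioStats:
    """p, n, and correctly-classified counts p′, n′ for one prediction set."""
    labels = np.asarray(labels).astype(bool)
    predictions = np.asarray(predictions).astype(bool)
    p = int(labels.sum())
    n = int((~labels).sum())
    if n == 0 or p == 0:
        raise ValueError("both classes must be present")
    correct = labels == predictions
    return RatioStats(
        p=p,
        n=n,
        p_prime=int((correct & labels).sum()),
        n_prime=int((correct & ~labels).sum()),
    )


@dataclass
class RoundDiagnostics:
    round_index: int
    chosen_feature: int
    strength: float
    r: float
    r_prime: float | None
    p: int
    n: int
    p_prime: int
    n_prime: int
    n_removed: int
    n_remaining_after: int

    def to_dict(self) -> dict:
        return {
            "round": self.round_index,
            "feature_id": self.chosen_feature,
            "strength": self.strength,
            "r": self.r,
            "r_prime": self.r_prime,
            "p": self.p,
            "n": self.n,
            "p_prime": self.p_prime,
            "n_prime": self.n_prime,
            "n_removed": self.n_removed,
            "n_remaining_after": self.n_remaining_after,
        }


@dataclass
class BoostResult:
    classifiers: list[WeakClassifier]
    rounds: list[RoundDiagnostics]
    stop_reason: str
    condition: SelectionCondition = field(default_factory=SelectionCondition)

    @property
    def selected_features(self) -> list[int]:
        return [c.feature_index for c in self.classifiers]


STOP_REASONS = (
    "no_feature_beats_guess",
    "ratio_condition_unmet",
    "class_exhausted",
    "max_rounds",
)


def _evaluate_candidates(values, labels, condition, ratio_values=None, ratio_labels=None):
    """Fit every column, apply the selection condition, rank candidates.

    Weak learners are fitted on the (remaining-example) view.  The ratio
    condition, however, judges each candidate's correctly-classified counts
    p′/n′ against the class ratio r = p/n of the *reference* set
    (``ratio_values``/``ratio_labels``, defaulting to the view): in the
    full loop the reference is the original training set, so a candidate
    whose threshold was fitted on a residual handful of examples is still
    required to serve both classes of the whole dataset.

    Returns (best column position or None, per-column fit arrays, a flag
    telling whether any column passed the strength test at all).
    """
    aucs, pol, thr, j, sens, spec, tp, tn, degen = _fit_weak_batch(values, labels)
    strength = np.abs(aucs - 0.5)

    if ratio_values is None:
        ratio_values, ratio_labels = values, labels
    ref_pos = np.asarray(ratio_labels).astype(bool)
    n_pos = int(ref_pos.sum())
    n_neg = ref_pos.size - n_pos
    ref_values = np.asarray(ratio_values, dtype=float)
    # candidate predictions on the reference set, all columns at once
    pred = (pol[None, :] * (ref_values - thr[None, :])) > 0
    tp_ref = (pred & ref_pos[:, None]).sum(axis=0)
    tn_ref = (~pred & ~ref_pos[:, None]).sum(axis=0)

    passes_strength = (strength > condition.epsilon_stop) & ~degen
    admissible = passes_strength.copy()
    ratio_gap = np.full(len(aucs), math.inf)
    defined = tn_ref > 0
    ratio_gap[defined] = np.abs(n_pos / n_neg - tp_ref[defined] / tn_ref[defined])
    if condition.mode == "ratio":
        admissible &= (tp_ref > 0) & (tn_ref > 0) & (ratio_gap <= condition.ratio_tolerance)
    elif condition.mode == "sens_spec":
        admissible &= (sens >= condition.min_sensitivity) & (spec >= condition.min_specificity)

    best = None
    if admissible.any():
        cand = np.flatnonzero(admissible)
        # max strength; ties -> smaller |r − r'|; then lowest column
        order = sorted(cand, key=lambda c: (-strength[c], ratio_gap[c], c))
        best = int(order[0])
    fits = (aucs, pol, thr, j, sens, spec, tp_ref, tn_ref, degen, strength)
    return best, fits, bool(passes_strength.any())


def select_feature(values, labels, condition: SelectionCondition,
                   feature_ids=None, ratio_values=None, ratio_labels=None):
    """One selection round on a view of remaining examples × features.

    ``ratio_values``/``ratio_labels`` optionally supply the reference set
    on which the ratio condition counts correct classifications (defaults
    to the view itself; the full loop passes the original training set).
    Returns ``(feature_id, WeakClassifier)`` for the admissible feature of
    maximal strength, or ``None`` when no feature is admissible.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("values must be a non-empty examples x features array")
    ids = np.arange(values.shape[1]) if feature_ids is None else np.asarray(feature_ids)
    best, fits, _ = _evaluate_candidates(values, labels, condition, ratio_values, ratio_labels)
    if best is None:
        return None
    aucs, pol, thr = fits[0], fits[1], fits[2]
    clf = WeakClassifier(
        feature_index=int(ids[best]),
        threshold=float(thr[best]),
        polarity=int(pol[best]),
        auc=float(aucs[best]),
    )
    return int(ids[best]), clf


def run_boosting(values, labels, condition: SelectionCondition = SelectionCondition(),
                 max_rounds: int = 100, feature_ids=None) -> BoostResult:
    """Run the full selection loop; see the module docstring."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if values.ndim != 2 or values.shape[0] != labels.size:
        raise ValueError("values must be examples x features matching labels")
    if values.shape[1] < 1:
        raise ValueError("need at least one feature")
    ids = np.arange(values.shape[1]) if feature_ids is None else np.asarray(feature_ids).copy()

    ex_mask = np.ones(values.shape[0], dtype=bool)
    ft_mask = np.ones(values.shape[1], dtype=bool)
    classifiers: list[WeakClassifier] = []
    rounds: list[RoundDiagnostics] = []
    stop_reason = "max_rounds"

    for round_index in range(1, max_rounds + 1):
        sub_labels = labels[ex_mask]
        # a class with < 2 remaining examples cannot support a two-sample
        # ROC estimate, so it counts as exhausted
        if sub_labels.sum() < 2 or (~sub_labels).sum() < 2:
            stop_reason = "class_exhausted"
            break
        if not ft_mask.any():
            stop_reason = "no_feature_beats_guess"
            break
        sub_values = values[np.ix_(ex_mask, ft_mask)]
        cols = np.flatnonzero(ft_mask)
        best, fits, any_strength = _evaluate_candidates(
            sub_values, sub_labels, condition,
            ratio_values=values[:, ft_mask], ratio_labels=labels,
        )
        if best is None:
            stop_reason = "ratio_condition_unmet" if any_strength else "no_feature_beats_guess"
            break
        aucs, pol, thr = fits[0], fits[1], fits[2]
        col = cols[best]
        clf = WeakClassifier(
            feature_index=int(ids[col]),
            threshold=float(thr[best]),
            polarity=int(pol[best]),
            auc=float(aucs[best]),
        )
        # diagnostics: p/n of the remaining view, p'/n' of the full
        # training set (the counts the ratio condition gates on)
        stats_full = compute_ratio_stats(labels, clf.predict(values[:, col]))
        predictions = clf.predict(sub_values[:, best])
        stats = compute_ratio_stats(sub_labels, predictions)
        correct = predictions == sub_labels
        n_removed = int(correct.sum())
        assert n_removed > 0, "a weak learner with strength > 0 must classify >= 1 example correctly"

        remaining_idx = np.flatnonzero(ex_mask)
        ex_mask[remaining_idx[correct]] = False
        ft_mask[col] = False
        classifiers.append(clf)
        rounds.append(
            RoundDiagnostics(
                round_index=round_index,
                chosen_feature=clf.feature_index,
                strength=clf.strength,
                r=stats.r,
                r_prime=stats_full.r_prime,
                p=stats.p,
                n=stats.n,
                p_prime=stats_full.p_prime,
                n_prime=stats_full.n_prime,
                n_removed=n_removed,
                n_remaining_after=int(ex_mask.sum()),
            )
        )
        logger.info(
            "round %d: feature %d strength=%.5f r=%.4f r'=%s removed=%d remaining=%d",
            round_index, clf.feature_index, clf.strength, stats.r,
            "undef" if stats_full.r_prime is None else f"{stats_full.r_prime:.4f}",
            n_removed, int(ex_mask.sum()),
        )
    else:
        stop_reason = "max_rounds"

    logger.info("boosting stopped after %d round(s): %s", len(rounds), stop_reason)
    return BoostResult(classifiers=classifiers, rounds=rounds,
                       stop_reason=stop_reason, condition=condition)


# ---------------------------------------------------------------------------
# Ensemble


def ensemble_score(classifiers: Sequence[WeakClassifier], values,
                   feature_ids=None, weighted: bool = False) -> np.ndarray:
    """Vote-sum score per example: each learner votes ±1 (its prediction),
    optionally weighted by its strength |a − 0.5|."""
    if len(classifiers) == 0:
        raise ValueError("need at least one classifier")
    values = np.asarray(values, dtype=float)
    ids = np.arange(values.shape[1]) if feature_ids is None else np.asarray(feature_ids)
    scores = np.zeros(values.shape[0])
    for clf in classifiers:
        pos = np.flatnonzero(ids == clf.feature_index)
        if pos.size == 0:
            raise ValueError(f"feature id {clf.feature_index} missing from matrix")
        vote = np.where(clf.predict(values[:, pos[0]]), 1.0, -1.0)
        scores += clf.strength * vote if weighted else vote
    return scores


def ensemble_auc(classifiers, values, labels, feature_ids=None, weighted=False) -> float:
    return auc(ensemble_score(classifiers, values, feature_ids, weighted), labels)


# ---------------------------------------------------------------------------
# Serialization


def result_to_json(result: BoostResult, path: str | Path) -> None:
    payload = {
        "stop_reason": result.stop_reason,
        "condition": {
            "mode": result.condition.mode,
            "epsilon_stop": result.condition.epsilon_stop,
            "ratio_tolerance": result.condition.ratio_tolerance,
            "min_sensitivity": result.condition.min_sensitivity,
            "min_specificity": result.condition.min_specificity,
        },
        "classifiers": [c.to_dict() for c in result.classifiers],
        "rounds": [r.to_dict() for r in result.rounds],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def result_from_json(path: str | Path) -> BoostResult:
    payload = json.loads(Path(path).read_text())
    cond = SelectionCondition(**payload["condition"])
    classifiers = [WeakClassifier.from_dict(d) for d in payload["classifiers"]]
    rounds = [
        RoundDiagnostics(
            round_index=r["round"],
            chosen_feature=r["feature_id"],
            strength=r["strength"],
            r=r["r"],
            r_prime=r["r_prime"],
            p=r["p"],
            n=r["n"],
            p_prime=r["p_prime"],
            n_prime=r["n_prime"],
            n_removed=r["n_removed"],
            n_remaining_after=r["n_remaining_after"],
        )
        for r in payload["rounds"]
    ]
    return BoostResult(classifiers=classifiers, rounds=rounds,
                       stop_reason=payload["stop_reason"], condition=cond)


def rounds_to_csv(result: BoostResult, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([r.to_dict() for r in result.rounds]).to_csv(path, index=False)
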