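"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (explicit loops, pairwise counts,
exhaustive threshold scans) and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def naive_feature_value(image: np.ndarray, spec) -> int:
    """Center-minus-border pixel sum by direct slicing (no integral image)."""
    plane = image[:, :, spec.channel_index].astype(int)
    r, c, w, h, t = spec.y - 1, spec.x - 1, spec.w, spec.h, spec.t
    center = plane[r + t : r + t + h, c + t : c + t + w].sum()
    top = plane[r : r + t, c + t : c + t + w].sum()
    bottom = plane[r + t + h : r + 2 * t + h, c + t : c + t + w].sum()
    left = plane[r + t : r + t + h, c : c + t].sum()
    right = plane[r + t : r + t + h, c + t + w : c + 2 * t + w].sum()
    return int(center - top - bottom - left - right)


def naive_grid_positions(w: int, h: int, t: int, frame_w: int = 100, frame_h: int = 120,
                         x_start: int = 1, x_step: int = 5, y_start: int = 1, y_step: int = 6):
    """All admissible 1-based (x, y) positions by direct scanning."""
    out = []
    for y in range(y_start, frame_h + 1, y_step):
        for x in range(x_start, frame_w + 1, x_step):
            if x + w + 2 * t - 1 <= frame_w and y + h + 2 * t - 1 <= frame_h:
                out.append((x, y))
    return out


def naive_auc2(values, labels) -> int:
    """Twice the Mann–Whitney U count: 2 per concordant pair, 1 per tie."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    u2 = 0
    for p in pos:
        for q in neg:
            u2 += 2 if p > q else (1 if p == q else 0)
    return u2


def naive_auc(values, labels) -> float:
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    return naive_auc2(values, labels) / (2.0 * n_pos * n_neg)


def naive_fit(values, labels):
    """Exhaustive weak-learner fit: polarity from the AUC sign, threshold
    from a scan over every midpoint between consecutive distinct values,
    ranked by (Youden J, specificity, smaller threshold) in exact integer
    arithmetic.  Returns (polarity, threshold, auc, tp, tn, degenerate)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    u2 = naive_auc2(values, labels)
    auc = u2 / (2.0 * n_pos * n_neg)
    polarity = 1 if u2 >= n_pos * n_neg else -1
    distinct = sorted(set(values.tolist()))
    if len(distinct) < 2:
        return 1, float(distinct[0]), auc, 0, n_neg, True
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        theta = (lo + hi) / 2.0
        pred = polarity * (values - theta) > 0
        tp = int((pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        key = (tp * n_neg + tn * n_pos, tn, -theta)
        if best is None or key > best[0]:
            best = (key, theta, tp, tn)
    return polarity, best[1], auc, best[2], best[3], False


def naive_select(values, labels, condition, ratio_values=None, ratio_labels=None):
    """Exhaustive selection round.  Returns (column, polarity, threshold)
    or None, plus whether any column passed the strength test."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if ratio_values is None:
        ratio_values, ratio_labels = values, labels
    ratio_values = np.asarray(ratio_values, dtype=float)
    ratio_labels = np.asarray(ratio_labels).astype(bool)
    rp = int(ratio_labels.sum())
    rn = ratio_labels.size - rp
    candidates = []
    any_strength = False
    for col in range(values.shape[1]):
        polarity, theta, auc, _, _, degenerate = naive_fit(values[:, col], labels)
        strength = abs(auc - 0.5)
        if degenerate or not strength > condition.epsilon_stop:
            continue
        any_strength = True
        pred_ref = polarity * (ratio_values[:, col] - theta) > 0
        tp_ref = int((pred_ref & ratio_labels).sum())
        tn_ref = int((~pred_ref & ~ratio_labels).sum())
        gap = math.inf if tn_ref == 0 else abs(rp / rn - tp_ref / tn_ref)
        if condition.mode == "ratio":
            if tp_ref == 0 or tn_ref == 0 or gap > condition.ratio_tolerance:
                continue
        candidates.append((-strength, gap, col, polarity, theta))
    if not candidates:
        return None, any_strength
    candidates.sort()
    _, _, col, polarity, theta = candidates[0]
    return (col, polarity, theta), any_strength


def naive_run(values, labels, condition, max_rounds):
    """Full selection-loop replay.  Returns ([(feature, polarity, theta)...],
    stop_reason)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n0, n_feat = values.shape
    ex = np.ones(n0, dtype=bool)
    ft = np.ones(n_feat, dtype=bool)
    chosen = []
    stop = "max_rounds"
    for _ in range(max_rounds):
        yv = labels[ex]
        if yv.sum() < 2 or (~yv).sum() < 2:
            stop = "class_exhausted"
            break
        if not ft.any():
            stop = "no_feature_beats_guess"
            break
        cols = np.flatnonzero(ft)
        picked, any_strength = naive_select(
            values[np.ix_(ex, ft)], yv, condition,
            ratio_values=values[:, ft], ratio_labels=labels,
        )
        if picked is None:
            stop = "ratio_condition_unmet" if any_strength else "no_feature_beats_guess"
            break
        local_col, polarity, theta = picked
        col = int(cols[local_col])
        chosen.append((col, polarity, theta))
        pred = polarity * (values[ex, col] - theta) > 0
        correct = pred == yv
        idx = np.flatnonzero(ex)
        ex[idx[correct]] = False
        ft[col] = False
    else:
        stop = "max_rounds"
    return chosen, stop
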