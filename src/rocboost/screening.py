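"""Per-feature two-sample t-test screening.

With ~3×10^5 Haar features and only ~10^3 images, the feature pool is
reduced before boosting by keeping every feature whose two-sample t-test
p-value falls below a raw (uncorrected) threshold.  This is a screen, not
inference: no multiplicity correction is applied, by design.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """p_threshold: keep features with p < threshold (strict).

    equal_var selects Student's pooled-variance statistic; the default is
    Welch's unequal-variance variant.
    """

    p_threshold: float = 0.05
    equal_var: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")


@dataclass
class ScreenResult:
    kept_indices: np.ndarray
    p_values: np.ndarray
    degenerate_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_kept(self) -> int:
        return int(self.kept_indices.size)


def t_screen(values: np.ndarray, labels: np.ndarray, config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Screen feature columns by two-sample t-test p-value.

    ``values`` is examples × features; ``labels`` is binary per example.
    Features constant within both classes have no defined t statistic and
    are dropped with a warning.  Returns p-values for every input column
    (NaN for degenerate ones) and the kept column indices in ascending
    order.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim != 2 or labels.shape != (values.shape[0],):
        raise ValueError("values must be examples x features with one label per row")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two label classes, got {classes.size}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 examples")

    degenerate = (np.ptp(a, axis=0) == 0) & (np.ptp(b, axis=0) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns
        result = stats.ttest_ind(a, b, axis=0, equal_var=config.equal_var)
    p_values = np.asarray(result.pvalue, dtype=float)
    p_values[degenerate] = np.nan
    if degenerate.any():
        logger.warning(
            "dropping %d feature(s) with zero variance in both classes",
            int(degenerate.sum()),
        )
    kept = np.flatnonzero(~degenerate & (p_values < config.p_threshold))
    return ScreenResult(
        kept_indices=kept,
        p_values=p_values,
        degenerate_indices=np.flatnonzero(degenerate),
    )


def screen_to_csv(result: ScreenResult, path: str | Path, feature_ids=None) -> None:
    ids = feature_ids if feature_ids is not None else np.arange(result.p_values.size)
    kept = set(int(i) for i in result.kept_indices)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature_id", "p_value", "kept"])
        for col, fid in enumerate(ids):
            writer.writerow([int(fid), repr(float(result.p_values[col])), int(col in kept)])


def screen_from_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back (feature_ids, p_values, kept-mask)."""
    ids, ps, kept = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ids.append(int(row["feature_id"]))
            ps.append(float(row["p_value"]))
            kept.append(bool(int(row["kept"])))
    return np.array(ids), np.array(ps), np.array(kept)
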