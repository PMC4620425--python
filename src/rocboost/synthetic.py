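"""Synthetic tongue-style image datasets with planted group differences.

The clinical images behind the original three-group study (healthy A,
ill-with-normal-tongue B, ill-with-abnormal-tongue C) are not public, so
this module generates stand-ins that exercise the full pipeline: an
elliptical foreground ("tongue") on a zero background at a fixed pinkish
base color, with i.i.d. Gaussian pixel noise.  Group C receives a localized
per-channel intensity shift inside a planted rectangle; group B receives a
(default zero) subtle shift in the same region.  The planted rectangle is
the ground truth against which selected Haar features can be scored.

Binary contrasts mirror the study design: test 1 = A vs B, test 2 = A vs C,
test 3 = A vs B∪C, with healthy (A) as the positive class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .haar import FRAME_HEIGHT, FRAME_WIDTH, HaarSpec

GROUPS = ("A", "B", "C")
_ELLIPSE_MARGIN = 5  # px between the ellipse and every frame edge

#: Group sizes of the original study (healthy / ill-normal-tongue / ill).
FULL_SCALE_COUNTS = (148, 332, 842)
#: Desk-speed default: the study's group sizes scaled down by ~5.
DEFAULT_COUNTS = (30, 66, 168)


@dataclass(frozen=True)
class SyntheticConfig:
    n_healthy: int = DEFAULT_COUNTS[0]
    n_ill_normal_tongue: int = DEFAULT_COUNTS[1]
    n_ill: int = DEFAULT_COUNTS[2]
    base_color: tuple[float, float, float] = (170.0, 110.0, 110.0)
    #: planted rectangle (x, y, width, height) in 1-based grid coordinates
    patch_rect: tuple[int, int, int, int] = (31, 41, 40, 30)
    patch_shift: tuple[float, float, float] = (-30.0, 0.0, 0.0)
    subtle_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        x, y, w, h = self.patch_rect
        if not (1 <= x and 1 <= y and w >= 1 and h >= 1
                and x + w - 1 <= FRAME_WIDTH and y + h - 1 <= FRAME_HEIGHT):
            raise ValueError(f"patch_rect {self.patch_rect} must lie inside the frame")
        if min(self.n_healthy, self.n_ill_normal_tongue, self.n_ill) < 0:
            raise ValueError("group counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def full_scale(cls, **kwargs) -> "SyntheticConfig":
        """The study's group sizes (148/332/842) instead of the desk default."""
        return cls(
            n_healthy=FULL_SCALE_COUNTS[0],
            n_ill_normal_tongue=FULL_SCALE_COUNTS[1],
            n_ill=FULL_SCALE_COUNTS[2],
            **kwargs,
        )


@lru_cache(maxsize=4)
def _ellipse_mask(margin: int = _ELLIPSE_MARGIN) -> np.ndarray:
    rows = np.arange(FRAME_HEIGHT)[:, None]
    cols = np.arange(FRAME_WIDTH)[None, :]
    cr, cc = (FRAME_HEIGHT - 1) / 2.0, (FRAME_WIDTH - 1) / 2.0
    ar, ac = FRAME_HEIGHT / 2.0 - margin, FRAME_WIDTH / 2.0 - margin
    mask = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0
    mask.setflags(write=False)
    return mask


def _patch_mask(patch_rect) -> np.ndarray:
    x, y, w, h = patch_rect
    mask = np.zeros((FRAME_HEIGHT, FRAME_WIDTH), dtype=bool)
    mask[y - 1 : y - 1 + h, x - 1 : x - 1 + w] = True
    return mask & _ellipse_mask()


def generate_image(group: str, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """One 120×100 RGB image of the given group; background exactly 0."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    ellipse = _ellipse_mask()
    pixels = np.zeros((FRAME_HEIGHT, FRAME_WIDTH, 3), dtype=float)
    pixels[ellipse] = np.asarray(config.base_color)
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=pixels.shape)
        pixels[ellipse] += noise[ellipse]
    shift = {"A": None, "B": config.subtle_shift, "C": config.patch_shift}[group]
    if shift is not None and any(s != 0 for s in shift):
        patch = _patch_mask(config.patch_rect)
        pixels[patch] += np.asarray(shift)
    return np.clip(np.rint(pixels), 0, 255).astype(np.uint8)


@dataclass
class SyntheticDataset:
    images: list[np.ndarray]
    group_labels: list[str]
    binary_labels: np.ndarray  # 1 = healthy (positive), 0 = ill (negative)
    truth_rect: tuple[int, int, int, int]
    test: int
    image_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.image_ids:
            self.image_ids = [f"img{i:04d}" for i in range(len(self.images))]


_TEST_GROUPS = {1: ("A", "B"), 2: ("A", "C"), 3: ("A", "B", "C")}


def generate_dataset(config: SyntheticConfig, test: int = 3) -> SyntheticDataset:
    """Generate the binary contrast of one test (1: A/B, 2: A/C, 3: A/B+C).

    Each image draws from its own seed substream keyed by (seed, group,
    index), so changing one group's count never changes another group's
    images.
    """
    if test not in _TEST_GROUPS:
        raise ValueError(f"test must be 1, 2 or 3, got {test}")
    counts = {"A": config.n_healthy, "B": config.n_ill_normal_tongue, "C": config.n_ill}
    images, groups, ids = [], [], []
    for gi, group in enumerate(GROUPS):
        if group not in _TEST_GROUPS[test]:
            continue
        if counts[group] < 1:
            raise ValueError(f"test {test} needs at least one image in group {group}")
        for i in range(counts[group]):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, gi, i)))
            images.append(generate_image(group, config, rng))
            groups.append(group)
            ids.append(f"{group}{i:04d}")
    labels = np.array([1 if g == "A" else 0 for g in groups], dtype=np.int8)
    return SyntheticDataset(
        images=images,
        group_labels=groups,
        binary_labels=labels,
        truth_rect=config.patch_rect,
        test=test,
        image_ids=ids,
    )


def recovery_score(selected: Sequence[HaarSpec], truth_rect) -> float:
    """Mean fractional overlap of selected features with the planted patch.

    For each spec, the fraction of its outer rectangle's area inside
    ``truth_rect`` (1-based x, y, w, h); 1.0 iff every spec lies entirely
    inside the planted region.
    """
    if len(selected) == 0:
        raise ValueError("need at least one selected spec")
    tx, ty, tw, th = truth_rect
    total = 0.0
    for s in selected:
        ox0, oy0 = s.x, s.y
        ox1, oy1 = s.x + s.outer_width - 1, s.y + s.outer_height - 1
        ix = max(0, min(ox1, tx + tw - 1) - max(ox0, tx) + 1)
        iy = max(0, min(oy1, ty + th - 1) - max(oy0, ty) + 1)
        total += (ix * iy) / (s.outer_width * s.outer_height)
    return total / len(selected)


def imbalanced_feature_benchmark(
    seed: int,
    n_pos: int = 25,
    n_neg: int = 200,
    n_one_sided: int = 3,
    n_balanced: int = 6,
    n_noise: int = 20,
    balanced_shift: float = 0.8,
    chunk_fraction: float = 0.6,
    chunk_offset: float = -5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature-matrix benchmark for selection behavior under class imbalance.

    Returns ``(values, labels)`` with a 1:8 positive:negative imbalance by
    default and three kinds of feature columns:

    * *one-sided* features that separate a clean chunk of the majority
      (negative) class perfectly and carry no information about the rest —
      the kind of feature that "serves one class only": strong AUC, but its
      fitted threshold classifies every positive the same way;
    * *balanced* features with a modest mean shift (``balanced_shift``, in
      within-class standard deviations) between the classes;
    * pure-noise features.

    The balanced shift default is calibrated so that ensembles selected
    with and without the ratio condition reach closely matched AUCs, which
    is what makes their predicted-positive rates comparable.
    """
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.zeros(n, dtype=np.int8)
    labels[:n_pos] = 1
    columns = []
    for _ in range(n_one_sided):
        v = rng.normal(0.0, 1.0, n)
        chunk = rng.choice(np.arange(n_pos, n), int(chunk_fraction * n_neg), replace=False)
        v[chunk] += chunk_offset
        columns.append(v)
    for _ in range(n_balanced):
        v = rng.normal(0.0, 1.0, n)
        v[:n_pos] += balanced_shift
        columns.append(v)
    for _ in range(n_noise):
        columns.append(rng.normal(0.0, 1.0, n))
    return np.column_stack(columns), labels


def reseeded(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of the config with a different master seed."""
    return replace(config, seed=seed)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write PNG images plus a ``labels.csv`` (image_id, group, label)."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    with open(outdir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "group", "label"])
        for image, group, label, image_id in zip(
            dataset.images, dataset.group_labels, dataset.binary_labels, dataset.image_ids
        ):
            iio.imwrite(outdir / "images" / f"{image_id}.png", image)
            writer.writerow([image_id, group, int(label)])
    return outdir


def read_labels(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    ids, groups, labels = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ids.append(row["image_id"])
            groups.append(row["group"])
            labels.append(int(row["label"]))
    return ids, groups, np.array(labels, dtype=np.int8)
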