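"""Five-partition Haar-like features on standardized tongue images.

A feature is a W×H center rectangle surrounded by a border of width T, with
T chosen so the center and the (corner-free) border cover approximately the
same number of pixels.  The feature value is the pixel-sum of the center
minus the pixel-sum of the four border side-rectangles, computed in O(1)
per feature from a per-channel integral image.

Coordinates: the public grid is 1-based with ``x`` horizontal (width 100)
and ``y`` vertical (height 120), matching the convention of the feature
grid; internal array indexing is 0-based (row, column).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

FRAME_HEIGHT = 120
FRAME_WIDTH = 100
CHANNELS = ("red", "green", "blue")

_RESAMPLE = {
    "nearest": Image.Resampling.NEAREST,
    "bilinear": Image.Resampling.BILINEAR,
    "bicubic": Image.Resampling.BICUBIC,
    "lanczos": Image.Resampling.LANCZOS,
}


def compute_t(w: int, h: int, rounding: str = "nearest") -> int:
    """Border width T for a w×h center partition.

    T is WH/(2W+2H) rounded to an integer so that the center pixel count
    ``w*h`` and the corner-free border pixel count ``2*t*(w+h)`` are as
    close as possible.  ``rounding="nearest"`` (round half up, the default)
    reproduces the published grid of 98,592 features per channel;
    ``rounding="floor"`` truncates instead.
    """
    if w < 1 or h < 1:
        raise ValueError(f"center partition must be at least 1x1, got {w}x{h}")
    num, den = w * h, 2 * (w + h)
    if rounding == "floor":
        return num // den
    if rounding == "nearest":  # half up
        return (2 * num + den) // (2 * den)
    raise ValueError(f"unknown rounding mode {rounding!r}")


@dataclass(frozen=True)
class HaarSpec:
    """One five-partition Haar-like feature in 1-based grid coordinates."""

    channel: str
    x: int
    y: int
    w: int
    h: int
    t: int

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if min(self.w, self.h, self.t) < 1 or min(self.x, self.y) < 1:
            raise ValueError(f"non-positive Haar parameter in {self}")
        if self.x + self.w + 2 * self.t - 1 > FRAME_WIDTH:
            raise ValueError(f"{self} exceeds frame width {FRAME_WIDTH}")
        if self.y + self.h + 2 * self.t - 1 > FRAME_HEIGHT:
            raise ValueError(f"{self} exceeds frame height {FRAME_HEIGHT}")

    @property
    def outer_width(self) -> int:
        return self.w + 2 * self.t

    @property
    def outer_height(self) -> int:
        return self.h + 2 * self.t

    @property
    def channel_index(self) -> int:
        return CHANNELS.index(self.channel)


@dataclass(frozen=True)
class GridConfig:
    """Parameter grid enumerating Haar specs.

    Defaults reproduce the published grid: W from 10 to 60 and H from 10 to
    72 in steps of 2, X from 1 in steps of 5, Y from 1 in steps of 6, all
    three color channels, which yields 98,592 specs per channel.
    """

    w_values: tuple[int, ...] = tuple(range(10, 61, 2))
    h_values: tuple[int, ...] = tuple(range(10, 73, 2))
    x_start: int = 1
    x_step: int = 5
    y_start: int = 1
    y_step: int = 6
    channels: tuple[str, ...] = CHANNELS
    t_rounding: str = "nearest"

    def __post_init__(self) -> None:
        if not self.w_values or not self.h_values or not self.channels:
            raise ValueError("grid value sets must be non-empty")
        if self.x_step < 1 or self.y_step < 1:
            raise ValueError("grid steps must be positive")


#: A small grid for desk-speed pipeline runs (a few hundred specs/channel).
COARSE_GRID = GridConfig(
    w_values=(16, 24, 32, 40),
    h_values=(16, 24, 32, 40),
    x_step=8,
    y_step=8,
)


def enumerate_grid(config: GridConfig = GridConfig()) -> list[HaarSpec]:
    """Enumerate every admissible spec of the grid.

    Order is deterministic: channel-major, then w, h, y, x.  A (w, h) pair
    whose outer rectangle fits nowhere contributes no specs.
    """
    specs: list[HaarSpec] = []
    for channel in config.channels:
        for w in config.w_values:
            for h in config.h_values:
                t = compute_t(w, h, config.t_rounding)
                x_max = FRAME_WIDTH - w - 2 * t + 1
                y_max = FRAME_HEIGHT - h - 2 * t + 1
                if x_max < config.x_start or y_max < config.y_start:
                    continue
                for y in range(config.y_start, y_max + 1, config.y_step):
                    for x in range(config.x_start, x_max + 1, config.x_step):
                        specs.append(HaarSpec(channel, x, y, w, h, t))
    return specs


# ---------------------------------------------------------------------------
# Images and integral images


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check a standardized 120×100 RGB uint8 array and return it."""
    arr = np.asarray(image)
    if arr.shape != (FRAME_HEIGHT, FRAME_WIDTH, 3):
        raise ValueError(
            f"expected image of shape ({FRAME_HEIGHT}, {FRAME_WIDTH}, 3), got {arr.shape}"
        )
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("image intensities must be integers in [0, 255]")
    return arr


def load_image(path: str | Path, resample: str = "bilinear") -> np.ndarray:
    """Load a raster image, convert to RGB and rescale to 120×100."""
    with Image.open(path) as im:
        rgb = im.convert("RGB")
        if rgb.size != (FRAME_WIDTH, FRAME_HEIGHT):
            rgb = rgb.resize((FRAME_WIDTH, FRAME_HEIGHT), _RESAMPLE[resample])
        return np.asarray(rgb, dtype=np.uint8)


def compute_integral(image: np.ndarray, channel: str | int) -> np.ndarray:
    """Cumulative-sum table of one channel, shape (121, 101), zero border.

    ``table[r+1, c+1]`` is the sum of pixels in rows 0..r, columns 0..c, so
    any rectangle sum needs four lookups.
    """
    arr = validate_image(image)
    idx = channel if isinstance(channel, int) else CHANNELS.index(channel)
    plane = arr[:, :, idx].astype(np.int64)
    table = np.zeros((FRAME_HEIGHT + 1, FRAME_WIDTH + 1), dtype=np.int64)
    np.cumsum(np.cumsum(plane, axis=0), axis=1, out=table[1:, 1:])
    return table


def _rect_sum(table: np.ndarray, r0, c0, r1, c1):
    """Sum over rows r0..r1, columns c0..c1 (0-based, inclusive)."""
    return (
        table[..., r1 + 1, c1 + 1]
        - table[..., r0, c1 + 1]
        - table[..., r1 + 1, c0]
        + table[..., r0, c0]
    )


def _partition_bounds(spec: HaarSpec):
    """0-based inclusive (r0, c0, r1, c1) for center and the 4 border sides."""
    r, c, w, h, t = spec.y - 1, spec.x - 1, spec.w, spec.h, spec.t
    center = (r + t, c + t, r + t + h - 1, c + t + w - 1)
    top = (r, c + t, r + t - 1, c + t + w - 1)
    bottom = (r + t + h, c + t, r + 2 * t + h - 1, c + t + w - 1)
    left = (r + t, c, r + t + h - 1, c + t - 1)
    right = (r + t, c + t + w, r + t + h - 1, c + 2 * t + w - 1)
    return center, (top, bottom, left, right)


def feature_value(integral: np.ndarray, spec: HaarSpec) -> int:
    """Center pixel-sum minus corner-free border pixel-sum, exact integer."""
    center, sides = _partition_bounds(spec)
    value = _rect_sum(integral, *center)
    for side in sides:
        value -= _rect_sum(integral, *side)
    return int(value)


@dataclass
class FeatureMatrix:
    """Examples × features value matrix with optional binary labels.

    ``values[i, j]`` is the feature value of ``specs[j]`` (or, after
    screening, of column ``feature_ids[j]``) on image ``i``.  Labels are
    1 for the positive (healthy) class and 0 for the negative (ill) class.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    labels: np.ndarray | None = None
    image_ids: list[str] = field(default_factory=list)
    specs: list[HaarSpec] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.feature_ids = np.asarray(self.feature_ids)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_ids):
            raise ValueError("values must be 2-D with one column per feature id")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).astype(np.int8)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels must have one entry per row")

    @property
    def n_examples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, feature_id: int) -> np.ndarray:
        pos = np.flatnonzero(self.feature_ids == feature_id)
        if pos.size == 0:
            raise ValueError(f"feature id {feature_id} not in matrix")
        return self.values[:, pos[0]]

    def select(self, keep: Sequence[int]) -> "FeatureMatrix":
        keep = np.asarray(keep)
        return FeatureMatrix(
            values=self.values[:, keep],
            feature_ids=self.feature_ids[keep],
            labels=None if self.labels is None else self.labels.copy(),
            image_ids=list(self.image_ids),
            specs=None if self.specs is None else [self.specs[int(k)] for k in keep],
        )


def extract_features(
    images: Sequence[np.ndarray], specs: Sequence[HaarSpec]
) -> FeatureMatrix:
    """Evaluate every spec on every image (vectorized over both axes)."""
    if len(images) == 0 or len(specs) == 0:
        raise ValueError("need at least one image and one spec")
    stacked = np.stack([validate_image(im) for im in images]).astype(np.int64)
    # per-channel integral stacks, shape (n_images, 121, 101)
    tables = {}
    for ci in {s.channel_index for s in specs}:
        tab = np.zeros((len(images), FRAME_HEIGHT + 1, FRAME_WIDTH + 1), dtype=np.int64)
        np.cumsum(np.cumsum(stacked[:, :, :, ci], axis=1), axis=2, out=tab[:, 1:, 1:])
        tables[ci] = tab

    out = np.empty((len(images), len(specs)), dtype=np.int64)
    order = {}  # channel -> (column positions, bounds arrays)
    for j, spec in enumerate(specs):
        order.setdefault(spec.channel_index, []).append(j)
    for ci, cols in order.items():
        tab = tables[ci]
        bounds = [_partition_bounds(specs[j]) for j in cols]
        center = np.array([b[0] for b in bounds])  # (F, 4)
        value = _rect_sum(tab, center[:, 0], center[:, 1], center[:, 2], center[:, 3])
        for k in range(4):
            side = np.array([b[1][k] for b in bounds])
            value -= _rect_sum(tab, side[:, 0], side[:, 1], side[:, 2], side[:, 3])
        out[:, cols] = value
    return FeatureMatrix(values=out, feature_ids=np.arange(len(specs)), specs=list(specs))


# ---------------------------------------------------------------------------
# Serialization

_SPEC_FIELDS = ("channel", "x", "y", "w", "h", "t")


def specs_to_csv(specs: Iterable[HaarSpec], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SPEC_FIELDS)
        for s in specs:
            writer.writerow([s.channel, s.x, s.y, s.w, s.h, s.t])


def specs_from_csv(path: str | Path) -> list[HaarSpec]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            HaarSpec(
                row["channel"],
                *(int(row[k]) for k in ("x", "y", "w", "h", "t")),
            )
            for row in reader
        ]


def specs_to_json(specs: Iterable[HaarSpec], path: str | Path) -> None:
    records = [
        {"channel": s.channel, "x": s.x, "y": s.y, "w": s.w, "h": s.h, "t": s.t}
        for s in specs
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def specs_from_json(path: str | Path) -> list[HaarSpec]:
    records = json.loads(Path(path).read_text())
    return [
        HaarSpec(r["channel"], r["x"], r["y"], r["w"], r["h"], r["t"]) for r in records
    ]


def matrix_to_csv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: one row per image, one column per spec."""
    import pandas as pd

    index = matrix.image_ids or [f"img{i:04d}" for i in range(matrix.n_examples)]
    frame = pd.DataFrame(
        matrix.values,
        index=index,
        columns=[f"f{int(j):06d}" for j in matrix.feature_ids],
    )
    frame.index.name = "image_id"
    frame.to_csv(path)


def matrix_from_csv(path: str | Path) -> FeatureMatrix:
    import pandas as pd

    frame = pd.read_csv(path, index_col="image_id")
    return FeatureMatrix(
        values=frame.to_numpy(),
        feature_ids=np.array([int(c[1:]) for c in frame.columns]),
        image_ids=[str(i) for i in frame.index],
    )
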