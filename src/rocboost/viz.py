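"""Feature-overlay rendering: superpose selected Haar features on an image.

The background is the grayscale image; every selected feature darkens its
border partitions to a fixed fraction of the background (repeated overlap
does not darken further) and brightens its center partition by a fixed
additive increment that *does* accumulate across overlapping features, so
regions many selected features agree on stand out brightest.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .haar import FRAME_HEIGHT, FRAME_WIDTH, HaarSpec, validate_image

logger = logging.getLogger(__name__)

CENTER_INCREMENT = 25.0
BORDER_FRACTION = 0.6


def overlay_features(
    image: np.ndarray,
    specs: Sequence[HaarSpec],
    center_increment: float = CENTER_INCREMENT,
    border_fraction: float = BORDER_FRACTION,
) -> np.ndarray:
    """Render the superposition of specs over the grayscale image.

    Returns a 120×100×3 uint8 image.  With an empty spec list the result is
    the grayscale background unchanged (a warning is logged).
    """
    arr = validate_image(image)
    gray = np.rint(arr.astype(float).mean(axis=2))
    if len(specs) == 0:
        logger.warning("overlay called with no selected features; returning background")
        return np.repeat(gray.astype(np.uint8)[:, :, None], 3, axis=2)

    center_count = np.zeros((FRAME_HEIGHT, FRAME_WIDTH))
    border_mask = np.zeros((FRAME_HEIGHT, FRAME_WIDTH), dtype=bool)
    for spec in specs:
        try:
            r0, c0 = spec.y - 1, spec.x - 1
        except AttributeError as exc:  # pragma: no cover - defensive
            raise TypeError("specs must be HaarSpec instances") from exc
        if r0 + spec.outer_height > FRAME_HEIGHT or c0 + spec.outer_width > FRAME_WIDTH:
            logger.warning("skipping out-of-frame spec %s", spec)
            continue
        outer = np.zeros((FRAME_HEIGHT, FRAME_WIDTH), dtype=bool)
        outer[r0 : r0 + spec.outer_height, c0 : c0 + spec.outer_width] = True
        center = np.zeros_like(outer)
        center[
            r0 + spec.t : r0 + spec.t + spec.h, c0 + spec.t : c0 + spec.t + spec.w
        ] = True
        center_count += center
        border_mask |= outer & ~center

    out = gray.copy()
    # darker partitions stay fixed: darken once, never cumulatively
    pure_border = border_mask & (center_count == 0)
    out[pure_border] = gray[pure_border] * border_fraction
    out += center_increment * center_count
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return np.repeat(out[:, :, None], 3, axis=2)
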