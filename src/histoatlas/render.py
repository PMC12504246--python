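"""Label-map image export: 16-bit grayscale ids and RGB hierarchy overlays."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .atlas import RegionNode
from .errors import ValidationError

__all__ = ["label_map_to_png", "read_label_map_png", "label_map_to_rgb", "save_rgb_png"]


def label_map_to_png(label_map: np.ndarray, path: str | Path) -> None:
    """Write region ids as 16-bit grayscale PNG (lossless for ids < 65536)."""
    lm = np.asarray(label_map)
    if lm.min(initial=0) < 0 or lm.max(initial=0) > 65535:
        raise ValidationError("label ids must fit 16-bit unsigned for PNG export")
    Image.fromarray(lm.astype(np.uint16)).save(path)


def read_label_map_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img).astype(np.int64)


def label_map_to_rgb(
    label_map: np.ndarray, hierarchy: Sequence[RegionNode]
) -> np.ndarray:
    """Colorize a label map with the hierarchy colors (background black)."""
    lm = np.asarray(label_map)
    max_id = int(lm.max(initial=0))
    lut = np.zeros((max_id + 1, 3), dtype=np.uint8)
    for n in hierarchy:
        if n.id <= max_id:
            lut[n.id] = n.color
    return lut[lm]


def save_rgb_png(rgb: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)
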