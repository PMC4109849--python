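"""Nuclear fluorescence quantification from z-stacks.

The measurement protocol: sum the focal planes into one projection, then for
each cell average the pixel intensity of three 4x4-pixel regions inside the
nucleus, subtract the average pixel intensity of three 4x4 regions of
adjacent background, and report the mean of the three background-subtracted
nuclear values as the cell's signal.

Boxes are 4x4 = 16 pixels, given by the 0-based (row, col) of the top-left
corner with half-open extents.  Background subtraction defaults to the pooled
background mean (subtracted from every nuclear region); a paired mode
subtracts background region i from nuclear region i — the two coincide when
the background is flat.  Negative signals are kept (clamping would bias
downstream CV statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError, ParameterError

BOX = 4  # region edge length in pixels


@dataclass(frozen=True)
class RegionAnnotation:
    """Three nuclear and three background 4x4 boxes for one cell."""

    cell_id: str
    nuclear: tuple          # three (row, col) top-left corners
    background: tuple       # three (row, col) top-left corners

    def __post_init__(self):
        if len(self.nuclear) != 3 or len(self.background) != 3:
            raise ParameterError("need exactly 3 nuclear and 3 background boxes")
        boxes = [tuple(map(int, b)) for b in (*self.nuclear, *self.background)]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                (r1, c1), (r2, c2) = boxes[i], boxes[j]
                if abs(r1 - r2) < BOX and abs(c1 - c2) < BOX:
                    raise GeometryError(
                        f"boxes {boxes[i]} and {boxes[j]} overlap for cell "
                        f"{self.cell_id}")

    def as_dict(self) -> dict:
        return {"cell_id": self.cell_id,
                "nuclear": [list(map(int, b)) for b in self.nuclear],
                "background": [list(map(int, b)) for b in self.background]}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionAnnotation":
        return cls(cell_id=d["cell_id"],
                   nuclear=tuple(tuple(b) for b in d["nuclear"]),
                   background=tuple(tuple(b) for b in d["background"]))


def project_zstack(stack) -> np.ndarray:
    """Pixel-wise sum of the focal planes ("stack arithmetic: sum").

    Integer input is widened to int64 before summing so no plane combination
    can overflow; float input accumulates in float64.
    """
    frames = np.asarray(stack)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise GeometryError("stack must be a non-empty sequence of equal 2-D frames")
    dtype = np.int64 if np.issubdtype(frames.dtype, np.integer) else np.float64
    return frames.sum(axis=0, dtype=dtype)


def _box_mean(image: np.ndarray, corner) -> float:
    r, c = int(corner[0]), int(corner[1])
    h, w = image.shape
    if r < 0 or c < 0 or r + BOX > h or c + BOX > w:
        raise GeometryError(f"box at ({r}, {c}) exceeds image bounds {image.shape}")
    return float(image[r:r + BOX, c:c + BOX].mean())


def nuclear_intensity(image: np.ndarray, annotation: RegionAnnotation,
                      background_mode: str = "pooled") -> dict:
    """Background-subtracted nuclear signal of one cell on a projected image.

    Returns ``{"signal", "background", "nuclear_means", "region_values"}``
    where ``region_values`` are the three background-subtracted nuclear
    region means and ``signal`` is their average.  ``background_mode`` is
    ``"pooled"`` (default: one background mean for all nuclear regions) or
    ``"paired"`` (region-wise subtraction).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise GeometryError("nuclear_intensity expects a 2-D projected image")
    nuc = [_box_mean(image, b) for b in annotation.nuclear]
    bg = [_box_mean(image, b) for b in annotation.background]
    background = float(np.mean(bg))
    if background_mode == "pooled":
        region_values = [n - background for n in nuc]
    elif background_mode == "paired":
        region_values = [n - b for n, b in zip(nuc, bg)]
    else:
        raise ParameterError("background_mode must be 'pooled' or 'paired'")
    return {"signal": float(np.mean(region_values)),
            "background": background,
            "nuclear_means": nuc,
            "region_values": region_values}


def quantify_stack(stack, annotations: Sequence[RegionAnnotation],
                   background_mode: str = "pooled"):
    """Project a stack and measure every annotated cell.

    Returns a list of dicts (cell_id, signal, background) ready to become a
    cell table.
    """
    image = project_zstack(stack)
    out = []
    for ann in annotations:
        res = nuclear_intensity(image, ann, background_mode=background_mode)
        out.append({"cell_id": ann.cell_id, "signal": res["signal"],
                    "background": res["background"]})
    return out
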