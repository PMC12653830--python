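"""Region-of-interest construction.

Two ROIs are analysed per slice: the whole image, and an automatically
located background region made of two corner squares.  Each corner square
covers 1/8 of the image width and height; the background pair is the
admissible (non-diagonal) pair of corners with the lowest total SNR, i.e.
the corners least contaminated by anatomy, so the region isolates noise and
artifact content irrespective of axial/sagittal orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import SliceImage

__all__ = [
    "Corner",
    "RoiConfig",
    "CornerSquare",
    "RoiMask",
    "corner_squares",
    "corner_snr",
    "select_background_corners",
    "background_mask",
    "whole_mask",
]


class Corner(str, Enum):
    TL = "TL"
    TR = "TR"
    BL = "BL"
    BR = "BR"


# admissible (non-diagonal) pairs, in fixed tie-break order
NON_DIAGONAL_PAIRS: tuple[tuple[Corner, Corner], ...] = (
    (Corner.TL, Corner.TR),
    (Corner.BL, Corner.BR),
    (Corner.TL, Corner.BL),
    (Corner.TR, Corner.BR),
)


@dataclass(frozen=True)
class RoiConfig:
    corner_fraction: float = 1 / 8
    snr_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.corner_fraction <= 0.5:
            raise ValueError("corner_fraction must be in (0, 1/2]")


@dataclass
class CornerSquare:
    corner: Corner
    row_range: tuple[int, int]  # half-open
    col_range: tuple[int, int]
    snr: float = float("nan")

    def pixels(self, image: np.ndarray) -> np.ndarray:
        r0, r1 = self.row_range
        c0, c1 = self.col_range
        return image[r0:r1, c0:c1]


@dataclass
class RoiMask:
    mask: np.ndarray
    roi_kind: str  # "whole" | "background"


def _pixels(slc: SliceImage | np.ndarray) -> np.ndarray:
    return slc.pixels if isinstance(slc, SliceImage) else np.asarray(slc, float)


def corner_squares(slc: SliceImage | np.ndarray,
                   cfg: RoiConfig = RoiConfig()) -> list[CornerSquare]:
    """The four corner squares of size floor(H*f) x floor(W*f), flush to each corner."""
    img = _pixels(slc)
    h, w = img.shape
    sh, sw = int(h * cfg.corner_fraction), int(w * cfg.corner_fraction)
    if sh < 2 or sw < 2:
        raise ValueError(
            f"corner square {sh}x{sw} smaller than 2x2; image too small for "
            f"corner_fraction={cfg.corner_fraction}"
        )
    return [
        CornerSquare(Corner.TL, (0, sh), (0, sw)),
        CornerSquare(Corner.TR, (0, sh), (w - sw, w)),
        CornerSquare(Corner.BL, (h - sh, h), (0, sw)),
        CornerSquare(Corner.BR, (h - sh, h), (w - sw, w)),
    ]


def corner_snr(slc: SliceImage | np.ndarray, sq: CornerSquare,
               cfg: RoiConfig = RoiConfig()) -> float:
    """mean / (population std + epsilon) within the square.

    Low values flag noise-dominated (anatomy-free) corners; a uniform bright
    patch of anatomy has near-zero std and hence a very large SNR.
    """
    vals = sq.pixels(_pixels(slc))
    return float(vals.mean() / (vals.std() + cfg.snr_epsilon))


def score_corners(slc: SliceImage | np.ndarray,
                  cfg: RoiConfig = RoiConfig()) -> list[CornerSquare]:
    squares = corner_squares(slc, cfg)
    for sq in squares:
        sq.snr = corner_snr(slc, sq, cfg)
    return squares


def select_background_corners(squares: list[CornerSquare]) -> tuple[CornerSquare, CornerSquare]:
    """The non-diagonal corner pair minimizing total SNR.

    Diagonal pairs are excluded even when their total SNR would be lower:
    the two squares must share an image edge.  Ties break in the fixed order
    (TL,TR) < (BL,BR) < (TL,BL) < (TR,BR) for reproducibility.
    """
    by_corner = {sq.corner: sq for sq in squares}
    if set(by_corner) != set(Corner):
        raise ValueError("need exactly one scored square per corner")
    best = min(NON_DIAGONAL_PAIRS,
               key=lambda pair: (by_corner[pair[0]].snr + by_corner[pair[1]].snr,
                                 NON_DIAGONAL_PAIRS.index(pair)))
    return by_corner[best[0]], by_corner[best[1]]


def background_mask(slc: SliceImage | np.ndarray,
                    pair: tuple[CornerSquare, CornerSquare]) -> RoiMask:
    """Union of the two selected corner squares (pooled into one region)."""
    img = _pixels(slc)
    mask = np.zeros(img.shape, dtype=bool)
    for sq in pair:
        r0, r1 = sq.row_range
        c0, c1 = sq.col_range
        mask[r0:r1, c0:c1] = True
    return RoiMask(mask=mask, roi_kind="background")


def whole_mask(slc: SliceImage | np.ndarray) -> RoiMask:
    return RoiMask(mask=np.ones(_pixels(slc).shape, dtype=bool), roi_kind="whole")


def locate_background(slc: SliceImage | np.ndarray,
                      cfg: RoiConfig = RoiConfig()) -> RoiMask:
    """Score corners, pick the admissible pair, and return the pooled mask."""
    return background_mask(slc, select_background_corners(score_corners(slc, cfg)))
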