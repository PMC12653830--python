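"""Fixed-bin-size (FBS) gray-level discretization.

FBS maps intensity x to level floor((x - min)/w) + 1, referencing the bin
grid to the ROI minimum, as IBSI recommends for arbitrary-unit MRI data.
The default bin width of 54 is the mean ROI intensity range divided by a
fixed bin number of 64; width 1 on integer data leaves the gray levels
unchanged (no discretization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationConfig", "derive_bin_width", "fbs_discretize"]


@dataclass(frozen=True)
class DiscretizationConfig:
    bin_width: float = 54.0
    derived_from_fbn: int | None = 64

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def derive_bin_width(roi_intensity_ranges, fbn: int = 64) -> float:
    """Mean ROI intensity range divided by a fixed bin number.

    Rounded to the nearest integer when the result is >= 1 (sub-unit widths
    are kept exact so low-range images are not collapsed to one bin).
    """
    ranges = np.asarray(list(roi_intensity_ranges), dtype=float)
    if ranges.size == 0:
        raise ValueError("no intensity ranges supplied")
    if np.any(ranges <= 0):
        raise ValueError("intensity ranges must be positive")
    if fbn < 2:
        raise ValueError("fbn must be >= 2")
    width = float(ranges.mean() / fbn)
    return float(round(width)) if width >= 1 else width


def fbs_discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Integer gray levels (1-based) for the masked intensities.

    ``Ng = levels.max()`` is the number of gray levels fed to the texture
    matrices.  The top-of-range value lands in its own bin by the floor
    rule, matching the IBSI FBS definition.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty mask: nothing to discretize")
    return (np.floor((values - values.min()) / bin_width) + 1).astype(np.int64)
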