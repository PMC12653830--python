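"""Volume loading, intensity normalization and slice-sampling scenarios.

A quality assessment run looks at the first post-contrast phase of a DCE-MRI
series, one 3D volume per patient.  Two sampling scenarios are supported:

* ``twelve_slice`` — 12 slices per volume: 6 equidistant slices from the
  middle third of the through-plane range and 3 from each outer third, so
  that locally degraded sub-regions (coil-sensitivity falloff, foreign
  objects) are represented.
* ``middle_slice`` — the single central slice, representative of the global
  protocol quality at much lower cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeImage",
    "SliceImage",
    "read_volume",
    "read_manifest",
    "zscore_normalize",
    "sample_slice_indices",
    "sample_slices_scenario1",
    "middle_slice_scenario2",
]

Orientation = Literal["axial", "sagittal"]
Scenario = Literal["twelve_slice", "middle_slice"]


@dataclass
class VolumeImage:
    """One patient's 3D intensity volume.

    Parameters
    ----------
    voxels : ndarray
        3D array of intensities (arbitrary scanner units).
    slice_axis : int
        Index of the through-plane axis (0, 1 or 2).
    patient_id : str
        Identifier used for patient-level fold grouping.
    orientation : {"axial", "sagittal"}
        Acquisition plane; informational only.
    """

    voxels: np.ndarray
    slice_axis: int = 2
    patient_id: str = ""
    orientation: Orientation = "axial"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.voxels.ndim}D; for a 4D DCE "
                "series pass a single post-contrast phase"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("non-finite voxels in volume")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.slice_axis]

    def get_slice(self, index: int, scenario: Scenario = "middle_slice") -> "SliceImage":
        if not 0 <= index < self.n_slices:
            raise IndexError(f"slice index {index} out of range [0, {self.n_slices})")
        pixels = np.take(self.voxels, index, axis=self.slice_axis)
        return SliceImage(pixels=pixels, patient_id=self.patient_id,
                          slice_index=index, scenario=scenario)


@dataclass
class SliceImage:
    """A single 2D slice extracted from a :class:`VolumeImage`."""

    pixels: np.ndarray
    patient_id: str = ""
    slice_index: int = 0
    scenario: Scenario = "middle_slice"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")


def read_volume(path: str | Path, slice_axis: int | None = None,
                orientation: Orientation = "axial",
                patient_id: str | None = None) -> VolumeImage:
    """Load a 3D NIfTI volume.

    The through-plane axis is inferred from the header as the axis with the
    largest voxel spacing (through-plane resolution is almost always the
    coarsest in DCE-MRI), unless ``slice_axis`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim == 4:
        raise ValueError(
            "4D image: pass a single post-contrast phase of the DCE series"
        )
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite voxels")
    if slice_axis is None:
        zooms = img.header.get_zooms()[:3]
        slice_axis = int(np.argmax(zooms))
    return VolumeImage(voxels=data, slice_axis=slice_axis,
                       patient_id=patient_id or path.name.split(".")[0],
                       orientation=orientation)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV with columns patient_id, volume_path, label."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "volume_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in manifest")
    if not df["label"].isin([0, 1]).all():
        raise ValueError("labels must be 0 (high quality) or 1 (low quality)")
    return df


def zscore_normalize(slc: SliceImage | np.ndarray,
                     stats: tuple[float, float] | None = None):
    """Standardize a slice to zero mean and unit population SD.

    Statistics are computed over the whole slice (or supplied, e.g. whole-
    volume statistics) and the same affine map is applied to every pixel, so
    later ROI restrictions see a consistently scaled image.
    """
    pixels = slc.pixels if isinstance(slc, SliceImage) else np.asarray(slc, float)
    if stats is None:
        mu, sigma = float(pixels.mean()), float(pixels.std())
    else:
        mu, sigma = stats
    if sigma <= 0:
        raise ValueError("zero-variance slice")
    out = (pixels - mu) / sigma
    if isinstance(slc, SliceImage):
        return SliceImage(pixels=out, patient_id=slc.patient_id,
                          slice_index=slc.slice_index, scenario=slc.scenario)
    return out


def _equidistant(start: int, stop: int, count: int) -> np.ndarray:
    # inclusive endpoints, rounded to nearest integer
    return np.rint(np.linspace(start, stop, count)).astype(int)


def sample_slice_indices(n_slices: int) -> list[int]:
    """Indices for the 12-slice scenario: 3 / 6 / 3 across volume thirds.

    The through-plane range is split into thirds; 6 equidistant indices are
    drawn from the middle third and 3 from each outer third.  Rounding
    collisions are resolved by shifting to the nearest unused index, first
    within the same third, then anywhere in range, so exactly 12 distinct
    indices are always returned.
    """
    z = int(n_slices)
    if z < 12:
        raise ValueError(f"insufficient slices: need >= 12, got {z}")
    b1, b2 = z // 3, (2 * z) // 3
    thirds = [(0, b1 - 1, 3), (b1, b2 - 1, 6), (b2, z - 1, 3)]
    used: set[int] = set()
    for lo, hi, count in thirds:
        for cand in _equidistant(lo, hi, count):
            idx = _nearest_unused(int(cand), used, lo, hi)
            if idx is None:
                idx = _nearest_unused(int(cand), used, 0, z - 1)
            assert idx is not None  # z >= 12 guarantees capacity
            used.add(idx)
    return sorted(used)


def _nearest_unused(target: int, used: set[int], lo: int, hi: int) -> int | None:
    if target not in used and lo <= target <= hi:
        return target
    for d in range(1, hi - lo + 1):
        for cand in (target - d, target + d):
            if lo <= cand <= hi and cand not in used:
                return cand
    return None


def sample_slices_scenario1(vol: VolumeImage) -> list[SliceImage]:
    """Extract the 12 scenario-1 slices from a volume, sorted ascending."""
    return [vol.get_slice(i, scenario="twelve_slice")
            for i in sample_slice_indices(vol.n_slices)]


def middle_slice_scenario2(vol: VolumeImage) -> SliceImage:
    """Extract the central slice (index ``floor(Z/2)``) along the slice axis."""
    if vol.n_slices < 1:
        raise ValueError("empty volume")
    return vol.get_slice(vol.n_slices // 2, scenario="middle_slice")
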