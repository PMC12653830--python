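"""Dual-ROI feature extraction: 819 radiomic features + 2 NR metrics per ROI.

Per ROI the bank is 9 filtered images x 91 features (18 first-order, 22
GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM, 5 NGTDM) = 819, plus the BRISQUE-style
NSS score and total variation = 821.  Combined mode concatenates the
whole-image vector with the background vector (names suffixed ``_bg``) into
1642 values.

Ordering is fixed (filters outer, feature classes inner, NR metrics last),
so feature tables are byte-identical across runs.

Intensity handling: texture matrices are discretized from the raw-intensity
filtered images with the fixed bin width (the default width 54 is derived
from raw ROI intensity ranges at a fixed bin number of 64 and is
meaningless on z-scored data, whose range is a few units); first-order
moments use the z-scored filtered images; first-order entropy/uniformity
reuse the texture gray levels.  ``texture_on_normalized`` switches the
texture source to the z-scored bank for use with sub-unit bin widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import DiscretizationConfig, fbs_discretize
from .filters import FilterConfig, filter_bank
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .io import SliceImage, VolumeImage, middle_slice_scenario2, \
    sample_slices_scenario1, zscore_normalize
from .quality_metrics import brisque_score, total_variation
from .roi import RoiConfig, select_background_corners, score_corners, \
    whole_mask
from .texture import (GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES,
                      NGTDM_NAMES, glcm_features, gldm_features,
                      glrlm_features, glszm_features, ngtdm_features)

__all__ = ["ExtractionConfig", "feature_names", "extract_features",
           "extract_cohort", "N_RADIOMIC", "N_PER_ROI", "NR_NAMES"]

CLASS_FEATURES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}
NR_NAMES = ("brisque", "total_variation")

_N_PER_FILTER = sum(len(v) for v in CLASS_FEATURES.values())
N_RADIOMIC = 9 * _N_PER_FILTER
N_PER_ROI = N_RADIOMIC + len(NR_NAMES)
# count identities for the configured bank
assert _N_PER_FILTER == 91 and N_RADIOMIC == 819 and N_PER_ROI == 821


@dataclass(frozen=True)
class ExtractionConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    normalize_per: str = "slice"          # "slice" | "volume"
    texture_on_normalized: bool = False
    tv_normalized: bool = True


def feature_names(cfg: ExtractionConfig = ExtractionConfig(),
                  background: bool = False) -> list[str]:
    """Deterministic ordered names: ``<filter>_<class>_<feature>[_bg]``."""
    suffix = "_bg" if background else ""
    names = [f"{tag}_{cls}_{feat}{suffix}"
             for tag in cfg.filters.tags
             for cls, feats in CLASS_FEATURES.items()
             for feat in feats]
    names.extend(f"{nr}{suffix}" for nr in NR_NAMES)
    return names


def _bbox_crop(arrs: list[np.ndarray], mask: np.ndarray) -> list[np.ndarray]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return [a[sl] for a in arrs]


def _background_crop(raw: np.ndarray, pair) -> np.ndarray:
    """The two corner squares stitched along their shared edge."""
    a, b = (sq.pixels(raw) for sq in pair)
    if pair[0].row_range == pair[1].row_range:   # horizontally adjacent corners
        return np.hstack([a, b])
    return np.vstack([a, b])


def _roi_features(bank_tex: dict, bank_fo: dict, mask: np.ndarray,
                  bin_width: float) -> dict[str, float]:
    out: dict[str, float] = {}
    for tag, tex_img in bank_tex.items():
        tex_c, fo_c, mask_c = _bbox_crop([tex_img, bank_fo[tag], mask], mask)
        lv1d = fbs_discretize(tex_c[mask_c], bin_width)
        lv2d = np.zeros(mask_c.shape, dtype=np.int64)
        lv2d[mask_c] = lv1d
        feats = {"firstorder": firstorder_features(fo_c[mask_c], lv1d),
                 "glcm": glcm_features(lv2d, mask_c),
                 "gldm": gldm_features(lv2d, mask_c),
                 "glrlm": glrlm_features(lv2d, mask_c),
                 "glszm": glszm_features(lv2d, mask_c),
                 "ngtdm": ngtdm_features(lv2d, mask_c)}
        for cls in CLASS_FEATURES:
            for feat in CLASS_FEATURES[cls]:
                out[f"{tag}_{cls}_{feat}"] = feats[cls][feat]
    return out


def extract_features(slc: SliceImage, cfg: ExtractionConfig = ExtractionConfig(),
                     roi_mode: str = "combined",
                     volume_stats: tuple[float, float] | None = None
                     ) -> dict[str, float]:
    """Full feature vector(s) for one slice.

    ``roi_mode`` is "whole", "background" or "combined" (821, 821 or 1642
    values).  ``volume_stats`` supplies whole-volume (mean, SD) when the
    configuration normalizes per volume.
    """
    if roi_mode not in ("whole", "background", "combined"):
        raise ValueError(f"unknown roi_mode {roi_mode!r}")
    raw = slc.pixels
    stats = volume_stats if cfg.normalize_per == "volume" else None
    znorm = zscore_normalize(raw, stats)

    bank_raw = filter_bank(raw, cfg.filters)
    bank_z = filter_bank(znorm, cfg.filters)
    bank_tex = bank_z if cfg.texture_on_normalized else bank_raw
    w = cfg.discretization.bin_width

    out: dict[str, float] = {}
    if roi_mode in ("whole", "combined"):
        try:
            mask = whole_mask(raw).mask
            out.update(_roi_features(bank_tex, bank_z, mask, w))
            out["brisque"] = brisque_score(raw)
            out["total_variation"] = total_variation(znorm, cfg.tv_normalized)
        except Exception as exc:  # pragma: no cover - context for debugging
            raise RuntimeError(f"whole-ROI extraction failed on "
                               f"{slc.patient_id}/{slc.slice_index}") from exc
    if roi_mode in ("background", "combined"):
        try:
            pair = select_background_corners(score_corners(raw, cfg.roi))
            mask = np.zeros(raw.shape, dtype=bool)
            for sq in pair:
                mask[sq.row_range[0]:sq.row_range[1],
                     sq.col_range[0]:sq.col_range[1]] = True
            bg = _roi_features(bank_tex, bank_z, mask, w)
            crop_raw = _background_crop(raw, pair)
            crop_z = _background_crop(znorm, pair)
            bg["brisque"] = brisque_score(crop_raw)
            bg["total_variation"] = total_variation(crop_z, cfg.tv_normalized)
        except Exception as exc:
            raise RuntimeError(f"background-ROI extraction failed on "
                               f"{slc.patient_id}/{slc.slice_index}") from exc
        out.update({f"{k}_bg": v for k, v in bg.items()})
    return out


def extract_cohort(volumes: list[VolumeImage], labels: dict[str, int],
                   scenario: str = "middle_slice",
                   cfg: ExtractionConfig = ExtractionConfig(),
                   roi_mode: str = "combined") -> pd.DataFrame:
    """Feature table for a cohort: one row per (patient, slice).

    Columns: patient_id, slice_index, label, then the feature columns in
    the deterministic extraction order.
    """
    rows = []
    for vol in volumes:
        if scenario in ("twelve_slice", "twelve"):
            slices = sample_slices_scenario1(vol)
        elif scenario in ("middle_slice", "middle"):
            slices = [middle_slice_scenario2(vol)]
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        stats = (float(vol.voxels.mean()), float(vol.voxels.std()))
        for slc in slices:
            feats = extract_features(slc, cfg, roi_mode, volume_stats=stats)
            row = {"patient_id": vol.patient_id,
                   "slice_index": slc.slice_index,
                   "label": labels[vol.patient_id]}
            row.update(feats)
            rows.append(row)
    return pd.DataFrame(rows)
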