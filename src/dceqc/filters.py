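"""Filter bank: original image, one-level 2D wavelet subbands, and LoG responses.

Nine filtered images per slice: the original, the four wavelet subbands
(LL, LH, HL, HH) and four Laplacian-of-Gaussian responses at sigmas 2-5
pixels.  Wavelet subbands are brought back to the original raster by
zero-order (nearest) upsampling so a single ROI mask applies to every
filtered image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["FilterConfig", "FILTER_TAGS", "apply_log_filter", "apply_wavelet2d",
           "filter_bank"]

FILTER_TAGS = (
    "original",
    "wavelet-LL", "wavelet-LH", "wavelet-HL", "wavelet-HH",
    "log-sigma-2", "log-sigma-3", "log-sigma-4", "log-sigma-5",
)


@dataclass(frozen=True)
class FilterConfig:
    log_sigmas: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    wavelet_name: str = "coif1"
    wavelet_level: int = 1

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sigmas):
            raise ValueError("LoG sigmas must be positive")

    @property
    def tags(self) -> tuple[str, ...]:
        log = tuple(f"log-sigma-{s:g}" for s in self.log_sigmas)
        return ("original", "wavelet-LL", "wavelet-LH", "wavelet-HL",
                "wavelet-HH") + log


_LOG_DC_GAIN: dict[float, float] = {}


def _log_dc_gain(sigma: float) -> float:
    # residual DC gain of the truncated discrete LoG kernel; subtracted so a
    # constant image maps exactly to zero
    if sigma not in _LOG_DC_GAIN:
        n = 2 * int(4 * sigma + 2) + 1
        flat = ndimage.gaussian_laplace(np.ones((n, n)), sigma=sigma,
                                        mode="reflect")
        _LOG_DC_GAIN[sigma] = float(flat[n // 2, n // 2])
    return _LOG_DC_GAIN[sigma]


def apply_log_filter(pixels: np.ndarray, sigma: float) -> np.ndarray:
    """Laplacian-of-Gaussian response with reflective boundaries.

    Sigma is interpreted in pixels.  The effective kernel half-width is
    4*sigma; images smaller than the kernel are rejected.  The truncated
    kernel is DC-corrected so constant regions respond exactly zero.
    """
    pixels = np.asarray(pixels, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if min(pixels.shape) < int(2 * 4 * sigma) + 1:
        raise ValueError(
            f"image {pixels.shape} smaller than LoG kernel for sigma={sigma}"
        )
    out = ndimage.gaussian_laplace(pixels, sigma=sigma, mode="reflect")
    return out - _log_dc_gain(sigma) * pixels


def _upsample_to(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.repeat(np.repeat(arr, 2, axis=0), 2, axis=1)
    return out[: shape[0], : shape[1]]


def apply_wavelet2d(pixels: np.ndarray,
                    cfg: FilterConfig = FilterConfig()) -> dict[str, np.ndarray]:
    """One-level 2D DWT; subbands nearest-upsampled back to the input raster.

    Tag convention: LH = horizontal-detail subband (responds to variation
    along rows), HL = vertical detail, HH = diagonal detail.
    """
    pixels = np.asarray(pixels, dtype=float)
    wav = pywt.Wavelet(cfg.wavelet_name)
    if min(pixels.shape) < wav.dec_len:
        raise ValueError(
            f"image {pixels.shape} too small for wavelet '{cfg.wavelet_name}'"
        )
    ll, (lh, hl, hh) = pywt.dwt2(pixels, wav, mode="symmetric")
    shape = pixels.shape
    return {
        "wavelet-LL": _upsample_to(ll, shape),
        "wavelet-LH": _upsample_to(lh, shape),
        "wavelet-HL": _upsample_to(hl, shape),
        "wavelet-HH": _upsample_to(hh, shape),
    }


def filter_bank(pixels: np.ndarray,
                cfg: FilterConfig = FilterConfig()) -> dict[str, np.ndarray]:
    """All nine filtered images, keyed by filter tag, in fixed order."""
    pixels = np.asarray(pixels, dtype=float)
    bank: dict[str, np.ndarray] = {"original": pixels}
    bank.update(apply_wavelet2d(pixels, cfg))
    for sigma in cfg.log_sigmas:
        bank[f"log-sigma-{sigma:g}"] = apply_log_filter(pixels, sigma)
    return bank
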