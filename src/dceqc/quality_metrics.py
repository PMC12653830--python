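"""No-reference image quality metrics: total variation and a BRISQUE-style
natural-scene-statistics score.

Total variation is the anisotropic sum of absolute neighbour differences;
it grows with noise and shrinks when blur removes detail.

The BRISQUE construction computes mean-subtracted contrast-normalized
(MSCN) coefficients, fits a generalized Gaussian to them and an asymmetric
generalized Gaussian (AGGD) to the four pairwise MSCN products, at two
scales, giving the standard 36-dimensional NSS feature vector.  The scalar
score reported here is an NSS-divergence: the RMS standardized distance of
those 36 features from a reference distribution fitted once, at run time,
to clean synthetic phantom slices (fixed internal seed).  Higher means
further from clean-image statistics, i.e. worse quality; the score is
finite on degenerate (constant) input thanks to the MSCN stabilizer.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.special import gamma as _gamma

__all__ = ["total_variation", "mscn_coefficients", "brisque_features",
           "brisque_score"]

_ALPHA_GRID = np.arange(0.2, 10.001, 0.001)
_RHO_GRID = (_gamma(2.0 / _ALPHA_GRID) ** 2
             / (_gamma(1.0 / _ALPHA_GRID) * _gamma(3.0 / _ALPHA_GRID)))
_EPS = 1e-12


def total_variation(pixels: np.ndarray, normalized: bool = True) -> float:
    """Anisotropic total variation; divided by pixel count when normalized."""
    x = np.asarray(pixels, dtype=float)
    if x.ndim != 2:
        raise ValueError("total_variation expects a 2D image")
    tv = float(np.abs(np.diff(x, axis=0)).sum() + np.abs(np.diff(x, axis=1)).sum())
    return tv / x.size if normalized else tv


def mscn_coefficients(pixels: np.ndarray, c: float = 1.0) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients.

    The image is rescaled to [0, 255]; local mean and variance come from a
    7x7 Gaussian window (sigma 7/6), and ``c`` stabilizes flat regions.
    """
    x = np.asarray(pixels, dtype=float)
    rng = x.max() - x.min()
    x = (x - x.min()) / rng * 255.0 if rng > 0 else np.zeros_like(x)
    mu = ndimage.gaussian_filter(x, sigma=7 / 6, truncate=3.0, mode="reflect")
    sigma = np.sqrt(np.abs(
        ndimage.gaussian_filter(x * x, sigma=7 / 6, truncate=3.0, mode="reflect")
        - mu * mu))
    return (x - mu) / (sigma + c)


def _ggd_fit(x: np.ndarray) -> tuple[float, float]:
    """Generalized Gaussian shape and variance by moment matching."""
    m2 = float((x * x).mean())
    if m2 < _EPS:
        return float(_ALPHA_GRID[0]), 0.0
    rho = float(np.abs(x).mean()) ** 2 / m2
    alpha = float(_ALPHA_GRID[np.argmin((_RHO_GRID - rho) ** 2)])
    return alpha, m2


def _aggd_fit(x: np.ndarray) -> tuple[float, float, float, float]:
    """AGGD (alpha, eta, sigma_l^2, sigma_r^2) by the moment-matching rule."""
    left = x[x < 0]
    right = x[x > 0]
    sl = float(np.sqrt((left * left).mean())) if left.size else 0.0
    sr = float(np.sqrt((right * right).mean())) if right.size else 0.0
    m2 = float((x * x).mean())
    if m2 < _EPS or sl + sr < _EPS:
        return float(_ALPHA_GRID[0]), 0.0, sl ** 2, sr ** 2
    gammahat = sl / (sr + _EPS)
    rhat = float(np.abs(x).mean()) ** 2 / m2
    rhatnorm = rhat * (gammahat ** 3 + 1) * (gammahat + 1) / (gammahat ** 2 + 1) ** 2
    alpha = float(_ALPHA_GRID[np.argmin((_RHO_GRID - rhatnorm) ** 2)])
    const = np.sqrt(_gamma(1 / alpha) / _gamma(3 / alpha))
    eta = (sr - sl) * const * _gamma(2 / alpha) / _gamma(1 / alpha)
    return alpha, float(eta), sl ** 2, sr ** 2


def _downscale2(x: np.ndarray) -> np.ndarray:
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    y = x[:h, :w]
    return 0.25 * (y[::2, ::2] + y[1::2, ::2] + y[::2, 1::2] + y[1::2, 1::2])


def brisque_features(pixels: np.ndarray) -> np.ndarray:
    """The 36 NSS features: 18 per scale at two scales.

    Per scale: GGD (shape, variance) of the MSCN field, plus AGGD
    (shape, mean, left variance, right variance) of the four pairwise
    products (horizontal, vertical, and the two diagonals).
    """
    x = np.asarray(pixels, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2D image")
    if min(x.shape) < 8:
        raise ValueError(f"image {x.shape} too small for NSS features (min dim 8)")
    feats: list[float] = []
    for _scale in range(2):
        m = mscn_coefficients(x)
        feats.extend(_ggd_fit(m))
        for pa, pb in ((m[:, :-1], m[:, 1:]), (m[:-1, :], m[1:, :]),
                       (m[:-1, :-1], m[1:, 1:]), (m[:-1, 1:], m[1:, :-1])):
            feats.extend(_aggd_fit(pa * pb))
        x = _downscale2(x)
    return np.asarray(feats, dtype=float)


_REFERENCE: tuple[np.ndarray, np.ndarray] | None = None
_REFERENCE_SEED = 913177  # internal; not user-tunable, keeps scores comparable


def _reference_model() -> tuple[np.ndarray, np.ndarray]:
    """Mean/SD of NSS features over clean phantom slices (lazy, cached)."""
    global _REFERENCE
    if _REFERENCE is None:
        from .phantom import PhantomSpec, render_phantom

        rng = np.random.default_rng(_REFERENCE_SEED)
        rows = []
        for _ in range(24):
            spec = PhantomSpec.randomized(rng)
            vol = render_phantom(spec)
            mid = vol[:, :, vol.shape[2] // 2]
            rows.append(brisque_features(mid))
        arr = np.asarray(rows)
        _REFERENCE = (arr.mean(axis=0), arr.std(axis=0) + 1e-6)
    return _REFERENCE


def brisque_score(pixels: np.ndarray) -> float:
    """Scalar NSS-divergence score; higher = worse quality.

    RMS of the 36 NSS features standardized against the clean-phantom
    reference distribution.  Deterministic and finite for any valid input,
    including constant images.
    """
    mu, sd = _reference_model()
    z = (brisque_features(pixels) - mu) / sd
    return float(np.sqrt((z * z).mean()))
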