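"""Gray-level texture matrices and their IBSI feature sets (2D, mask-aware).

Five matrix families are computed from a discretized slice restricted to an
ROI mask:

* GLCM  — co-occurrences at distance 1 in the 4 in-plane directions,
  symmetric, features averaged over directions (22 features).
* GLRLM — run lengths of equal levels along the 4 directions, runs broken
  by the mask, features averaged over directions (16 features).
* GLSZM — 8-connected zones of equal level, single matrix (16 features).
* GLDM  — dependence sizes: 1 + number of Chebyshev-distance-1 in-mask
  neighbours whose level differs by at most alpha (= 0), (14 features).
* NGTDM — per-level absolute difference from the mean of the valid
  neighbourhood (5 features).

Pixels outside the mask never contribute: they break runs, are excluded
from neighbourhoods, and cannot pair with in-mask pixels.  Degenerate
(single-level) regions take their analytic limits: contrasts and entropies
0, uniformities 1, GLCM correlation defined as 1, NGTDM coarseness capped
at 1e6.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "GLCM_NAMES", "GLRLM_NAMES", "GLSZM_NAMES", "GLDM_NAMES", "NGTDM_NAMES",
    "glcm_matrices", "glcm_features",
    "glrlm_matrices", "glrlm_features",
    "glszm_zones", "glszm_features",
    "gldm_matrix", "gldm_features",
    "ngtdm_table", "ngtdm_features",
]

_EPS = 2.2e-16
_COARSENESS_CAP = 1e6

# distance-1 directions: horizontal, vertical, down-right, down-left
DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))
# all 8 Chebyshev-distance-1 neighbour offsets
NEIGHBOURS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1))

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def _masked_levels(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Level array with 0 outside the mask; validates inputs."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape or levels.ndim != 2:
        raise ValueError("levels and mask must be 2D arrays of equal shape")
    if not mask.any():
        raise ValueError("empty mask")
    lv = np.where(mask, levels, 0).astype(np.int64)
    if lv[mask].min() < 1:
        raise ValueError("in-mask gray levels must be >= 1")
    return lv


def _shifted(lv: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (a, b) where b is the (dr, dc)-neighbour of a."""
    h, w = lv.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return a, b


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrices(levels: np.ndarray, mask: np.ndarray,
                  ng: int | None = None) -> list[np.ndarray]:
    """Symmetric distance-1 co-occurrence count matrices, one per direction."""
    lv = _masked_levels(levels, mask)
    ng = int(ng or lv.max())
    mats = []
    for dr, dc in DIRECTIONS:
        a, b = _shifted(lv, dr, dc)
        valid = (a > 0) & (b > 0)
        i, j = a[valid] - 1, b[valid] - 1
        m = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
        mats.append(m + m.T)
    return mats


def _glcm_features_from_matrix(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        # no admissible pairs (e.g. isolated pixels): treat as single-level
        p = np.zeros((ng, ng))
        p[0, 0] = 1.0
    else:
        p = counts / total
    gl = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(gl, gl, indexing="ij")
    px = p.sum(axis=1)
    mu = float((gl * px).sum())
    sigma2 = float(((gl - mu) ** 2 * px).sum())

    ksum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(),
                       minlength=2 * ng + 1)[2:]
    kdiff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(),
                        minlength=ng)
    kd = np.arange(ng, dtype=float)
    ks = np.arange(2, 2 * ng + 1, dtype=float)

    diff_avg = float((kd * kdiff).sum())
    sup = p > 0
    hxy = float(-(p[sup] * np.log2(p[sup])).sum())
    pxs = px > 0
    hx = float(-(px[pxs] * np.log2(px[pxs])).sum())
    pipj = np.outer(px, px)
    hxy1 = float(-(p[sup] * np.log2(pipj[sup] + _EPS)).sum())
    os = pipj > 0
    hxy2 = float(-(pipj[os] * np.log2(pipj[os])).sum())
    corr_num = float((p * ii * jj).sum()) - mu * mu
    feats = {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": corr_num / sigma2 if sigma2 > 0 else 1.0,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(kdiff[kdiff > 0]
                                     * np.log2(kdiff[kdiff > 0])).sum()),
        "DifferenceVariance": float(((kd - diff_avg) ** 2 * kdiff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,  # symmetric p => HX == HY
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": float((kdiff[1:] / kd[1:] ** 2).sum()) if ng > 1 else 0.0,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-(ksum[ksum > 0] * np.log2(ksum[ksum > 0])).sum()),
        "SumSquares": sigma2,
    }
    return feats


def glcm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """22 GLCM features, computed per direction and averaged."""
    per_dir = [_glcm_features_from_matrix(m) for m in glcm_matrices(levels, mask)]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM

def _direction_lines(lv: np.ndarray, dr: int, dc: int) -> list[np.ndarray]:
    if (dr, dc) == (0, 1):
        return [row for row in lv]
    if (dr, dc) == (1, 0):
        return [col for col in lv.T]
    if (dr, dc) == (1, 1):
        return [np.diagonal(lv, k) for k in range(-lv.shape[0] + 1, lv.shape[1])]
    if (dr, dc) == (1, -1):
        f = np.fliplr(lv)
        return [np.diagonal(f, k) for k in range(-f.shape[0] + 1, f.shape[1])]
    raise ValueError(f"unsupported direction {(dr, dc)}")


def _runs(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """(level, length) of every maximal run of equal non-zero level."""
    sep = np.array([0], dtype=np.int64)
    x = np.concatenate([np.concatenate([line.astype(np.int64), sep])
                        for line in lines])
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, x.size - 1]
    vals = x[starts]
    lens = ends - starts + 1
    keep = vals > 0
    return vals[keep], lens[keep]


def glrlm_matrices(levels: np.ndarray, mask: np.ndarray,
                   ng: int | None = None) -> list[np.ndarray]:
    """Run-length count matrices (Ng x Lmax), one per direction."""
    lv = _masked_levels(levels, mask)
    ng = int(ng or lv.max())
    lmax = max(lv.shape)
    mats = []
    for dr, dc in DIRECTIONS:
        vals, lens = _runs(_direction_lines(lv, dr, dc))
        m = np.bincount((vals - 1) * lmax + (lens - 1),
                        minlength=ng * lmax).reshape(ng, lmax).astype(float)
        mats.append(m)
    return mats


def _glrlm_features_from_matrix(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = m.sum()
    g = np.arange(1, m.shape[0] + 1, dtype=float)
    r = np.arange(1, m.shape[1] + 1, dtype=float)
    pg = m.sum(axis=1)  # per gray level
    pr = m.sum(axis=0)  # per run length
    pn = m / nr
    mu_g = float((g * pn.sum(axis=1)).sum())
    mu_r = float((r * pn.sum(axis=0)).sum())
    sup = pn > 0
    gg, rr = np.meshgrid(g, r, indexing="ij")
    return {
        "ShortRunEmphasis": float((pr / r ** 2).sum() / nr),
        "LongRunEmphasis": float((pr * r ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / nr ** 2),
        "RunLengthNonUniformity": float((pr ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr ** 2).sum() / nr ** 2),
        "RunPercentage": float(nr / n_pixels),
        "GrayLevelVariance": float((pn.sum(axis=1) * (g - mu_g) ** 2).sum()),
        "RunVariance": float((pn.sum(axis=0) * (r - mu_r) ** 2).sum()),
        "RunEntropy": float(-(pn[sup] * np.log2(pn[sup])).sum()),
        "LowGrayLevelRunEmphasis": float((pg / g ** 2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((pg * g ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((m / (gg ** 2 * rr ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((m * gg ** 2 / rr ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((m * rr ** 2 / gg ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((m * gg ** 2 * rr ** 2).sum() / nr),
    }


def glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """16 GLRLM features, computed per direction and averaged."""
    n_pixels = int(np.asarray(mask, bool).sum())
    per_dir = [_glrlm_features_from_matrix(m, n_pixels)
               for m in glrlm_matrices(levels, mask)]
    return {name: float(np.mean([d[name] for d in per_dir]))
            for name in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT8 = np.ones((3, 3), dtype=int)


def glszm_zones(levels: np.ndarray, mask: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gray level, zone size, count) triplets of all 8-connected zones."""
    lv = _masked_levels(levels, mask)
    gs, ss, cs = [], [], []
    for g in range(1, int(lv.max()) + 1):
        lab, nlab = ndimage.label(lv == g, structure=_STRUCT8)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        uniq, cnt = np.unique(sizes, return_counts=True)
        gs.append(np.full(uniq.size, g))
        ss.append(uniq)
        cs.append(cnt)
    return (np.concatenate(gs).astype(float), np.concatenate(ss).astype(float),
            np.concatenate(cs).astype(float))


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """16 GLSZM features from the 8-connectivity zone matrix."""
    gv, sv, cv = glszm_zones(levels, mask)
    n_pixels = int(np.asarray(mask, bool).sum())
    nz = cv.sum()
    p = cv / nz
    # marginals by gray level and by zone size
    pg = np.bincount(gv.astype(int), weights=cv)[1:]
    _, sinv = np.unique(sv, return_inverse=True)
    ps = np.bincount(sinv, weights=cv)
    mu_g = float((p * gv).sum())
    mu_s = float((p * sv).sum())
    return {
        "SmallAreaEmphasis": float((cv / sv ** 2).sum() / nz),
        "LargeAreaEmphasis": float((cv * sv ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / nz ** 2),
        "SizeZoneNonUniformity": float((ps ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps ** 2).sum() / nz ** 2),
        "ZonePercentage": float(nz / n_pixels),
        "GrayLevelVariance": float((p * (gv - mu_g) ** 2).sum()),
        "ZoneVariance": float((p * (sv - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(p * np.log2(p)).sum()),
        "LowGrayLevelZoneEmphasis": float((cv / gv ** 2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((cv * gv ** 2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((cv / (gv ** 2 * sv ** 2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((cv * gv ** 2 / sv ** 2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((cv * sv ** 2 / gv ** 2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((cv * gv ** 2 * sv ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# GLDM

def gldm_matrix(levels: np.ndarray, mask: np.ndarray, alpha: int = 0,
                ng: int | None = None) -> np.ndarray:
    """Dependence count matrix P(g, j), j = dependence size 1..9.

    The dependence size of an in-mask pixel is 1 (itself) plus the number of
    in-mask Chebyshev-distance-1 neighbours whose level differs by at most
    ``alpha``.
    """
    lv = _masked_levels(levels, mask)
    ng = int(ng or lv.max())
    dep = np.zeros(lv.shape, dtype=np.int64)
    for dr, dc in NEIGHBOURS8:
        a, b = _shifted(lv, dr, dc)
        h, w = lv.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        dep[r0:r1, c0:c1] += ((a > 0) & (b > 0)
                              & (np.abs(a - b) <= alpha)).astype(np.int64)
    inmask = lv > 0
    j = dep[inmask] + 1  # 1..9
    g = lv[inmask]
    return np.bincount((g - 1) * 9 + (j - 1),
                       minlength=ng * 9).reshape(ng, 9).astype(float)


def gldm_features(levels: np.ndarray, mask: np.ndarray,
                  alpha: int = 0) -> dict[str, float]:
    """14 GLDM features (distance 1, default alpha = 0)."""
    m = gldm_matrix(levels, mask, alpha=alpha)
    nz = m.sum()
    g = np.arange(1, m.shape[0] + 1, dtype=float)
    j = np.arange(1, m.shape[1] + 1, dtype=float)
    pg = m.sum(axis=1)
    pj = m.sum(axis=0)
    pn = m / nz
    mu_g = float((g * pn.sum(axis=1)).sum())
    mu_j = float((j * pn.sum(axis=0)).sum())
    sup = pn > 0
    gg, jjj = np.meshgrid(g, j, indexing="ij")
    return {
        "SmallDependenceEmphasis": float((pj / j ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((pj * j ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nz),
        "DependenceNonUniformity": float((pj ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pj ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float((pn.sum(axis=1) * (g - mu_g) ** 2).sum()),
        "DependenceVariance": float((pn.sum(axis=0) * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(pn[sup] * np.log2(pn[sup])).sum()),
        "LowGrayLevelEmphasis": float((pg / g ** 2).sum() / nz),
        "HighGrayLevelEmphasis": float((pg * g ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((m / (gg ** 2 * jjj ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((m * gg ** 2 / jjj ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((m * jjj ** 2 / gg ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((m * gg ** 2 * jjj ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_table(levels: np.ndarray, mask: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gray-level (level, n_i, s_i) over pixels with >= 1 valid neighbour.

    s_i sums |level - mean of in-mask 8-neighbourhood| over the n_i pixels
    of level i.
    """
    lv = _masked_levels(levels, mask)
    nsum = np.zeros(lv.shape, dtype=float)
    ncnt = np.zeros(lv.shape, dtype=np.int64)
    for dr, dc in NEIGHBOURS8:
        h, w = lv.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a, b = _shifted(lv, dr, dc)
        nsum[r0:r1, c0:c1] += np.where(b > 0, b, 0)
        ncnt[r0:r1, c0:c1] += (b > 0)
    valid = (lv > 0) & (ncnt > 0)
    diff = np.abs(lv[valid] - nsum[valid] / ncnt[valid])
    g = lv[valid]
    ng = int(lv.max())
    n_i = np.bincount(g, minlength=ng + 1)[1:].astype(float)
    s_i = np.bincount(g, weights=diff, minlength=ng + 1)[1:]
    return np.arange(1, ng + 1, dtype=float), n_i, s_i


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """5 NGTDM features: coarseness, contrast, busyness, complexity, strength."""
    gl, n_i, s_i = ngtdm_table(levels, mask)
    n = n_i.sum()
    present = n_i > 0
    gl, n_i, s_i = gl[present], n_i[present], s_i[present]
    p_i = n_i / n
    ngp = p_i.size

    dot = float((p_i * s_i).sum())
    coarseness = min(1.0 / dot, _COARSENESS_CAP) if dot > 0 else _COARSENESS_CAP

    if ngp > 1:
        di = gl[:, None] - gl[None, :]
        pp = p_i[:, None] * p_i[None, :]
        contrast = float((pp * di ** 2).sum()) / (ngp * (ngp - 1)) * float(s_i.sum()) / n
        busy_den = float(np.abs(gl[:, None] * p_i[:, None]
                                - gl[None, :] * p_i[None, :]).sum())
        busyness = dot / busy_den if busy_den > 0 else 0.0
        ps = p_i * s_i
        complexity = float((np.abs(di) * (ps[:, None] + ps[None, :])
                            / (p_i[:, None] + p_i[None, :])).sum()) / n
        s_tot = float(s_i.sum())
        strength = (float(((p_i[:, None] + p_i[None, :]) * di ** 2).sum()) / s_tot
                    if s_tot > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0

    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}
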