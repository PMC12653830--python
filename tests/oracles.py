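"""Naive brute-force texture-matrix constructions used as test oracles.

Everything here is written with explicit Python loops and no shared code
with the package's vectorized implementations, so agreement between the
two routes is evidence of correctness of the fast path.
"""

import numpy as np

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))
NEIGHBOURS8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0)]


def _inside(levels, mask, r, c):
    h, w = levels.shape
    return 0 <= r < h and 0 <= c < w and mask[r, c]


def brute_glcm(levels, mask, ng):
    """Symmetric co-occurrence counts per direction, by pixel-pair loops."""
    h, w = levels.shape
    mats = []
    for dr, dc in DIRECTIONS:
        m = np.zeros((ng, ng))
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                for sign in (1, -1):
                    rr, cc = r + sign * dr, c + sign * dc
                    if _inside(levels, mask, rr, cc):
                        m[levels[r, c] - 1, levels[rr, cc] - 1] += 1
        mats.append(m)
    return mats


def brute_glrlm(levels, mask, ng, lmax):
    """Run-length counts per direction by walking each line pixelwise."""
    h, w = levels.shape
    mats = []
    for dr, dc in DIRECTIONS:
        m = np.zeros((ng, lmax))
        # starting points: cells whose predecessor along (dr,dc) is outside
        # the grid (runs broken by the mask are handled inside the walk)
        starts = [(r, c) for r in range(h) for c in range(w)
                  if not (0 <= r - dr < h and 0 <= c - dc < w)]
        for r0, c0 in starts:
            run_level, run_len = 0, 0
            r, c = r0, c0
            while 0 <= r < h and 0 <= c < w:
                lv = levels[r, c] if mask[r, c] else 0
                if lv == run_level and lv != 0:
                    run_len += 1
                else:
                    if run_level != 0:
                        m[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lv, 1 if lv else 0
                r, c = r + dr, c + dc
            if run_level != 0:
                m[run_level - 1, run_len - 1] += 1
        mats.append(m)
    return mats


def brute_glszm(levels, mask):
    """8-connected zones by breadth-first flood fill; {(level, size): count}."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = {}
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            g = levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGHBOURS8:
                    nr, nc = rr + dr, cc + dc
                    if (_inside(levels, mask, nr, nc) and not seen[nr, nc]
                            and levels[nr, nc] == g):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            zones[(g, size)] = zones.get((g, size), 0) + 1
    return zones


def brute_gldm(levels, mask, ng, alpha=0):
    """Dependence counts: size = 1 + #{8-neighbours in mask, |diff| <= alpha}."""
    h, w = levels.shape
    m = np.zeros((ng, 9))
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 0
            for dr, dc in NEIGHBOURS8:
                rr, cc = r + dr, c + dc
                if (_inside(levels, mask, rr, cc)
                        and abs(int(levels[rr, cc]) - int(levels[r, c])) <= alpha):
                    dep += 1
            m[levels[r, c] - 1, dep] += 1
    return m


def brute_ngtdm(levels, mask, ng):
    """(n_i, s_i) per gray level over pixels with >= 1 in-mask neighbour."""
    h, w = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nb = [levels[r + dr, c + dc] for dr, dc in NEIGHBOURS8
                  if _inside(levels, mask, r + dr, c + dc)]
            if not nb:
                continue
            g = levels[r, c]
            n[g - 1] += 1
            s[g - 1] += abs(g - sum(nb) / len(nb))
    return n, s
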