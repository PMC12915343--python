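"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths they check: HSB via the stdlib
``colorsys`` module, connected components via breadth-first flood fill,
and grid geodesics via vectorised Bellman-Ford relaxation to a fixed
point.
"""

import colorsys
import math
from collections import deque

import numpy as np

SQRT2 = math.sqrt(2.0)

_MOVES = [
    (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
    (-1, -1, SQRT2), (-1, 1, SQRT2), (1, -1, SQRT2), (1, 1, SQRT2),
]


def hsb_of_pixel(r, g, b):
    """HSB of one 8-bit pixel via colorsys (achromatic hue -> 0)."""
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return h % 1.0, s, v


def flood_components(mask):
    """8-connected components of a boolean array by BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(H):
        for c0 in range(W):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = r + dr, c + dc
                        if 0 <= nr < H and 0 <= nc < W and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
            comps.append(frozenset(comp))
    return comps


def bellman_ford_distance_map(navigable, primary):
    """Octile distance from every navigable pixel to the primary set, by
    brute-force relaxation to a fixed point (all-pairs style: every edge is
    relaxed every sweep until nothing changes)."""
    nav = np.asarray(navigable, dtype=bool)
    prim = np.asarray(primary, dtype=bool)
    H, W = nav.shape
    d = np.where(prim & nav, 0.0, np.inf)
    d[~nav] = np.inf
    for _ in range(H * W):
        nd = d.copy()
        for dr, dc, w in _MOVES:
            r0, r1 = max(0, -dr), H - max(0, dr)
            c0, c1 = max(0, -dc), W - max(0, dc)
            cand = d[r0 + dr:r1 + dr, c0 + dc:c1 + dc] + w
            nd[r0:r1, c0:c1] = np.minimum(nd[r0:r1, c0:c1], cand)
        nd[~nav] = np.inf
        if np.array_equal(nd, d, equal_nan=True):
            break
        d = nd
    return d
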