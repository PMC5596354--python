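"""Independent brute-force oracles used to validate pipeline operations.

Everything here is deliberately naive (flood fill with an explicit stack,
loop sums, point-in-polygon via shapely) and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np
import shapely


def flood_fill_count(binary: np.ndarray, connectivity: int) -> int:
    """Count connected components by explicit flood fill."""
    binary = np.asarray(binary).astype(bool)
    seen = np.zeros_like(binary)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    h, w = binary.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count


def convex_pixel_area(coords: np.ndarray, eps: float = 1e-7) -> float:
    """Lattice points inside-or-on the convex hull of pixel centers, counted
    by point-in-polygon queries against a shapely hull."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) <= 2:
        return float(len(coords))
    hull = shapely.MultiPoint([(c, r) for r, c in coords]).convex_hull
    if hull.geom_type != "Polygon":          # collinear input
        return float(len(coords))
    hull = hull.buffer(eps)
    r0, r1 = int(np.floor(coords[:, 0].min())), int(np.ceil(coords[:, 0].max()))
    c0, c1 = int(np.floor(coords[:, 1].min())), int(np.ceil(coords[:, 1].max()))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    inside = shapely.contains_xy(hull, cc.ravel(), rr.ravel())
    return float(inside.sum())


def weighted_solidity(areas, solidities) -> float:
    num = sum(a * s for a, s in zip(areas, solidities))
    return num / sum(areas)


def region_sum(image: np.ndarray, pixels: np.ndarray) -> float:
    total = 0.0
    for r, c in np.asarray(pixels):
        total += float(image[r, c])
    return total


def masked_mean(image: np.ndarray, mask: np.ndarray) -> float:
    total, n = 0.0, 0
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            if mask[r, c]:
                total += float(image[r, c])
                n += 1
    return total / n


def random_connected_blob(rng: np.random.Generator, n_steps: int = 40,
                          size: int = 25) -> np.ndarray:
    """A random connected pixel set grown by a lazy random walk from the grid
    center; returns unique (row, col) coordinates."""
    pos = np.array([size // 2, size // 2])
    pts = {tuple(pos)}
    moves = np.array([(-1, 0), (1, 0), (0, -1), (0, 1),
                      (-1, -1), (-1, 1), (1, -1), (1, 1)])
    for _ in range(n_steps):
        pos = pos + moves[rng.integers(len(moves))]
        pos = np.clip(pos, 0, size - 1)
        pts.add(tuple(pos))
    return np.array(sorted(pts))
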