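"""Maximum-intensity projection and mask construction.

Masking is done once, on the maximum-intensity projection (MIP) of the nuclear
channel, so that it is consistent across every slice of the stack.  Two masks
are derived:

* the **nucleus mask** — pixels above the central candidate threshold of the
  MIP's intensity range (split into ``n_bins`` equal-width bins); its
  connected components ("blobs") are the putative photoreceptor nuclei;
* the **background mask** — the below-threshold candidate whose blobs have
  the smallest area-weighted mean solidity (ragged masks hug the true
  inter-nuclear background), refined by morphological opening, erosion and
  hole infill.  Its blobs anchor the grouping of nuclei into ommatidia and
  provide the sampling region for digital noise subtraction.

Solidity is blob area over the pixel area of the convex hull of the blob's
pixel centers, so convex rasterized shapes score exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy import ndimage
from skimage import measure, morphology

from .errors import DegenerateInputError, EmptyMaskError
from .io import ImageStack, RunConfig


@dataclass
class Blob:
    """One connected component of a binary mask."""

    pixels: np.ndarray            # (n, 2) int array of (row, col)
    area: int
    convex_area: float            # pixel count of the filled hull of pixel centers
    solidity: float               # area / convex_area, in (0, 1]
    centroid: tuple[float, float]  # (row, col) mean of pixel coordinates


@dataclass
class MaskCandidate:
    """A below-threshold candidate background mask and its blob statistics."""

    threshold: float
    mask: np.ndarray
    blobs: list[Blob]
    weighted_solidity: float      # sum(area*solidity)/sum(area)


@dataclass
class MaskPair:
    """Nucleus mask and refined background mask derived from one MIP."""

    nucleus_mask: np.ndarray
    background_mask: np.ndarray
    mip: np.ndarray
    background_threshold: float = float("nan")
    nucleus_threshold: float = float("nan")
    candidates: list[MaskCandidate] = field(default_factory=list, repr=False)


def max_intensity_projection(stack: ImageStack) -> np.ndarray:
    """Per-pixel maximum over all slices of the stack."""
    return stack.data.max(axis=0)


def candidate_thresholds(image: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Upper edges of ``n_bins`` equal-width bins over [min, max]:
    ``t_i = min + i*(max-min)/n_bins`` for i = 1..n_bins."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise DegenerateInputError("constant image has no intensity range")
    return lo + (hi - lo) * np.arange(1, n_bins + 1) / n_bins


def nucleus_mask(mip: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Binarize the MIP strictly above the central bin's threshold.

    The central bin for an even ``n_bins`` is bin ``n_bins/2`` (1-based), so
    the threshold is the range midpoint for the default 100 bins.  Pixels
    exactly at the threshold are left out of the mask.
    """
    thresholds = candidate_thresholds(mip, n_bins)
    central = thresholds[n_bins // 2 - 1]
    return np.asarray(mip) > central


def _convex_pixel_area(coords: np.ndarray) -> float:
    """Number of integer lattice points inside-or-on the convex hull of the
    given pixel-center coordinates.

    Counts by scanline: for each integer row the hull cross-section is a
    single column interval.  The hull is computed from the component's
    boundary pixels only (interior points are never hull vertices).
    Degenerate (collinear) components are their own hull.
    """
    coords = np.asarray(coords)
    n = len(coords)
    if n <= 2:
        return float(n)
    try:
        hull = ConvexHull(coords.astype(np.float64))
    except QhullError:
        return float(n)  # collinear: a connected digital segment is its hull
    verts = coords[hull.vertices].astype(np.float64)   # counter-clockwise order
    eps = 1e-9
    r0, r1 = int(np.ceil(verts[:, 0].min() - eps)), int(np.floor(verts[:, 0].max() + eps))
    rows = np.arange(r0, r1 + 1, dtype=np.float64)
    ra, ca = verts[:, 0], verts[:, 1]
    rb, cb = np.roll(ra, -1), np.roll(ca, -1)
    denom = rb - ra
    horiz = np.abs(denom) < eps
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rows[None, :] - ra[:, None]) / denom[:, None]          # (edges, rows)
    cols = ca[:, None] + t * (cb - ca)[:, None]
    valid = ~horiz[:, None] & (t >= -eps) & (t <= 1 + eps)
    # horizontal edges contribute both endpoints on their own (integer) row
    on_row = horiz[:, None] & (np.abs(rows[None, :] - ra[:, None]) < eps)
    lo = np.where(valid, cols, np.inf)
    hi = np.where(valid, cols, -np.inf)
    lo = np.minimum(lo, np.where(on_row, np.minimum(ca, cb)[:, None], np.inf)).min(axis=0)
    hi = np.maximum(hi, np.where(on_row, np.maximum(ca, cb)[:, None], -np.inf)).max(axis=0)
    width = np.floor(hi + eps) - np.ceil(lo - eps) + 1
    return float(np.where(lo <= hi, np.maximum(width, 0), 0).sum())


def _pack_coords(rr: np.ndarray, cc: np.ndarray, offset) -> np.ndarray:
    out = np.empty((rr.size, 2), dtype=np.int64)
    out[:, 0] = rr + offset[0]
    out[:, 1] = cc + offset[1]
    return out


def _boundary_coords(region_image: np.ndarray, offset) -> np.ndarray:
    """Pixels of a component that touch its complement (hull input reduction)."""
    interior = ndimage.binary_erosion(region_image, structure=np.ones((3, 3)))
    rr, cc = np.nonzero(region_image & ~interior)
    return _pack_coords(rr, cc, offset)


def label_blobs(mask: np.ndarray, connectivity: int = 8) -> list[Blob]:
    """One :class:`Blob` per connected component of a binary mask."""
    mask = np.asarray(mask).astype(bool)
    conn = 1 if connectivity == 4 else 2
    labels = measure.label(mask, connectivity=conn)
    blobs: list[Blob] = []
    for rp in measure.regionprops(labels):
        offset = rp.bbox[:2]
        rr, cc = np.nonzero(rp.image)
        coords = _pack_coords(rr, cc, offset)
        area = int(len(coords))
        boundary = _boundary_coords(rp.image, offset)
        convex_area = _convex_pixel_area(boundary)
        convex_area = max(convex_area, float(area))  # guard: hull covers the blob
        centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
        blobs.append(Blob(pixels=coords, area=area, convex_area=convex_area,
                          solidity=area / convex_area, centroid=centroid))
    return blobs


def weighted_solidity(blobs: list[Blob]) -> float:
    """Area-weighted mean blob solidity: sum(area*solidity)/sum(area)."""
    if not blobs:
        raise EmptyMaskError("no blobs to weight")
    areas = np.array([b.area for b in blobs], dtype=np.float64)
    sols = np.array([b.solidity for b in blobs], dtype=np.float64)
    return float((areas * sols).sum() / areas.sum())


def background_candidates(mip: np.ndarray, n_bins: int = 100,
                          connectivity: int = 8) -> list[MaskCandidate]:
    """Below-threshold masks (``mip < t``) at every candidate threshold.

    Candidates with zero blobs are excluded.
    """
    mip = np.asarray(mip, dtype=np.float64)
    candidates: list[MaskCandidate] = []
    for t in candidate_thresholds(mip, n_bins):
        mask = mip < t
        if not mask.any():
            continue
        blobs = label_blobs(mask, connectivity)
        candidates.append(MaskCandidate(threshold=float(t), mask=mask, blobs=blobs,
                                        weighted_solidity=weighted_solidity(blobs)))
    if not candidates:
        raise EmptyMaskError("every candidate background mask is empty")
    return candidates


def select_background_mask(candidates: list[MaskCandidate]) -> MaskCandidate:
    """The candidate with the smallest weighted solidity (ties: lowest
    threshold) — consistently the most appropriate background threshold."""
    if not candidates:
        raise EmptyMaskError("no background-mask candidates")
    best = min(range(len(candidates)), key=lambda i: candidates[i].weighted_solidity)
    return candidates[best]


def fill_holes(mask: np.ndarray, max_hole: int) -> np.ndarray:
    """Fill interior holes of area <= max_hole.

    Holes are 4-connected components of the complement that do not touch the
    image border (the complement of an 8-connected foreground).
    """
    mask = np.asarray(mask).astype(bool)
    comp_labels, n = ndimage.label(~mask, structure=np.array([[0, 1, 0],
                                                              [1, 1, 1],
                                                              [0, 1, 0]]))
    if n == 0:
        return mask.copy()
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(comp_labels[border])) - {0}
    out = mask.copy()
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=np.int64), comp_labels,
                               index=np.arange(1, n + 1))
    for lab, area in zip(range(1, n + 1), areas):
        if lab not in border_labels and area <= max_hole:
            out[comp_labels == lab] = True
    return out


def refine_background_mask(mask: np.ndarray, config: RunConfig | None = None) -> np.ndarray:
    """Opening (disk footprint) + small-blob removal, erosion, and hole infill.

    Erosion can fragment ragged blobs, so blobs below the minimum surviving
    area are removed again after it — stray fragments would otherwise become
    spurious ommatidium anchors downstream.
    """
    config = config or RunConfig()
    mask = np.asarray(mask).astype(bool)
    opened = morphology.opening(mask, morphology.disk(config.open_disk_radius))
    # survivors must have area >= open_min_area (remove strictly smaller blobs)
    opened = morphology.remove_small_objects(opened, max_size=config.open_min_area - 1,
                                             connectivity=config.skimage_connectivity)
    eroded = morphology.erosion(opened, morphology.disk(config.erosion_radius))
    eroded = morphology.remove_small_objects(eroded, max_size=config.open_min_area - 1,
                                             connectivity=config.skimage_connectivity)
    return fill_holes(eroded, config.infill_max_hole)


def build_masks(stack: ImageStack, config: RunConfig | None = None) -> MaskPair:
    """MIP + nucleus mask + selected-and-refined background mask in one go."""
    config = config or RunConfig()
    mip = max_intensity_projection(stack)
    nmask = nucleus_mask(mip, config.n_bins)
    thresholds = candidate_thresholds(mip, config.n_bins)
    candidates = background_candidates(mip, config.n_bins, config.connectivity)
    selected = select_background_mask(candidates)
    refined = refine_background_mask(selected.mask, config)
    return MaskPair(nucleus_mask=nmask, background_mask=refined, mip=mip,
                    background_threshold=selected.threshold,
                    nucleus_threshold=float(thresholds[config.n_bins // 2 - 1]),
                    candidates=candidates)


# neighbor offsets in clockwise order starting west, image coordinates (row down)
_RING = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def trace_boundary(blob: Blob) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace with Jacob's stopping criterion.

    Returns the closed clockwise sequence of boundary pixels of a connected
    blob, starting from its raster-first pixel.  The walk stops when the start
    pixel is re-entered from its original entry direction.
    """
    pixels = {tuple(p) for p in np.asarray(blob.pixels)}
    if not pixels:
        raise EmptyMaskError("cannot trace an empty blob")
    start = min(pixels)                      # raster order: topmost, then leftmost
    if len(pixels) == 1:
        return [start]
    p, b = start, (start[0], start[1] - 1)   # entered scanning from the west
    seen: dict[tuple, int] = {}
    states: list[tuple] = []
    while (p, b) not in seen:                # Jacob: stop on repeated entry state
        seen[(p, b)] = len(states)
        states.append((p, b))
        bidx = _RING.index((b[0] - p[0], b[1] - p[1]))
        for k in range(1, 9):
            d = _RING[(bidx + k) % 8]
            q = (p[0] + d[0], p[1] + d[1])
            if q in pixels:
                prev = _RING[(bidx + k - 1) % 8]
                p, b = q, (p[0] + prev[0], p[1] + prev[1])
                break
    # the closed contour is the cycle of the walk (the artificial initial
    # backtrack may contribute a short lead-in that is not part of it)
    cycle = [s[0] for s in states[seen[(p, b)]:]]
    i = cycle.index(start)                   # raster-first pixel is always on it
    return cycle[i:] + cycle[:i]
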