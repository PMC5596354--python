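"""Grouping nucleus blobs into ommatidia and numbering cells.

Each refined background blob marks the dark core of one ommatidium; nuclei
are assigned to the nearest core using the sorted centroid-distance profile.
A dominant gap in the forward differences of that profile (the "inflection"
between near ring-members and everything else in the field) sets how many
nuclei belong to the ommatidium, capped at 7 — R8 nuclei do not appear in the
imaging planes this workflow targets.  Cells are then numbered 1..k counter-
clockwise about the core centroid; the numbering start is arbitrary (smallest
non-negative angle from image east), only the CCW order is contractual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AssignmentError, GeometryError
from .masking import Blob

log = logging.getLogger("ccrit")

MAX_CELLS = 7


@dataclass
class Ommatidium:
    label: str
    anchor_centroid: tuple[float, float]
    cells: list[tuple[int, Blob]]          # (cell_number 1..k, nucleus blob)


@dataclass
class CellMap:
    """Assignment of nucleus blobs to lettered ommatidia."""

    ommatidia: list[Ommatidium]
    unassigned: list[Blob] = field(default_factory=list)


def ommatidium_label(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA', ... (spreadsheet-style letters)."""
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def distance_profile(anchor: tuple[float, float],
                     nucleus_centroids: list[tuple[float, float]]) -> list[tuple[float, int]]:
    """Euclidean distances from an anchor to every nucleus centroid, sorted
    ascending; ties keep the lower nucleus index first."""
    if not len(nucleus_centroids):
        raise AssignmentError("no nucleus centroids")
    a = np.asarray(anchor, dtype=np.float64)
    pts = np.asarray(nucleus_centroids, dtype=np.float64)
    d = np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1])
    order = np.lexsort((np.arange(len(d)), d))     # stable on ties
    return [(float(d[i]), int(i)) for i in order]


def near_cutoff(sorted_distances, gap_factor: float = 3.0,
                max_cells: int = MAX_CELLS) -> int:
    """Number of "near" nuclei in an ascending distance profile.

    The cutoff is the first local maximum of the forward differences whose
    height dominates the typical spacing — it must exceed ``gap_factor``
    times the median of the *other* differences (an empty median counts as
    0, so a lone gap always qualifies).  Returns the number of distances
    before that gap, capped at ``max_cells``; with no qualifying gap,
    ``min(len, max_cells)``.
    """
    dist = np.asarray(list(sorted_distances), dtype=np.float64)
    if len(dist) < 2:
        return min(len(dist), max_cells)
    diffs = np.diff(dist)
    tiny = 1e-9 * max(float(dist.max()), 1.0)   # numerical fuzz is not a gap
    for i in range(len(diffs)):
        left_ok = i == 0 or diffs[i] > diffs[i - 1]
        right_ok = i == len(diffs) - 1 or diffs[i] >= diffs[i + 1]
        if not (left_ok and right_ok):
            continue
        others = np.delete(diffs, i)
        med = float(np.median(others)) if others.size else 0.0
        if diffs[i] > max(gap_factor * med, tiny):
            return min(i + 1, max_cells)
    return min(len(dist), max_cells)


def number_cells_ccw(anchor: tuple[float, float], cells: list[Blob]) -> list[tuple[int, Blob]]:
    """Number 1..k counter-clockwise about the anchor.

    Angles use ``atan2(-(row-row0), col-col0)`` so that "up" in the image is
    the positive y direction and increasing angle is counter-clockwise on
    screen.  Numbering starts at the smallest non-negative angle from image
    east.
    """
    if not 1 <= len(cells) <= MAX_CELLS:
        raise AssignmentError(f"expected 1..{MAX_CELLS} cells, got {len(cells)}")
    centroids = [c.centroid for c in cells]
    if len({(round(r, 9), round(c, 9)) for r, c in centroids}) != len(centroids):
        raise GeometryError("two cells share a centroid; angular order undefined")
    angles = []
    for blob in cells:
        dr = blob.centroid[0] - anchor[0]
        dc = blob.centroid[1] - anchor[1]
        if dr == 0 and dc == 0:
            raise GeometryError("cell centroid coincides with the anchor")
        angles.append(math.atan2(-dr, dc) % (2 * math.pi))
    order = sorted(range(len(cells)), key=lambda i: angles[i])
    return [(num, cells[i]) for num, i in enumerate(order, start=1)]


def assign_ommatidia(background_blobs: list[Blob], nucleus_blobs: list[Blob],
                     gap_factor: float = 3.0) -> CellMap:
    """Assign nucleus blobs to ommatidia anchored at background-blob centroids.

    Anchors are processed (and lettered A, B, C, ...) in row-major order of
    their centroids.  Each anchor claims its near set from the distance
    profile; a nucleus claimed by several anchors goes to the nearest one
    (ties to the earlier label).  Nuclei claimed by no anchor are reported in
    ``CellMap.unassigned`` and excluded.
    """
    if not background_blobs:
        raise AssignmentError("no background blobs to anchor ommatidia")
    if not nucleus_blobs:
        raise AssignmentError("no nucleus blobs to assign")
    anchors = sorted(background_blobs, key=lambda b: b.centroid)
    centroids = [b.centroid for b in nucleus_blobs]

    # claims[j] = (distance, anchor_order) for nucleus j, best so far
    claims: dict[int, tuple[float, int]] = {}
    for a_idx, anchor in enumerate(anchors):
        profile = distance_profile(anchor.centroid, centroids)
        k = near_cutoff([d for d, _ in profile], gap_factor=gap_factor)
        for dist, j in profile[:k]:
            best = claims.get(j)
            if best is None or (dist, a_idx) < best:
                claims[j] = (dist, a_idx)

    members: dict[int, list[Blob]] = {i: [] for i in range(len(anchors))}
    for j, (_, a_idx) in sorted(claims.items()):
        members[a_idx].append(nucleus_blobs[j])

    ommatidia = []
    for a_idx, anchor in enumerate(anchors):
        if not members[a_idx]:
            continue
        ommatidia.append(Ommatidium(
            label=ommatidium_label(len(ommatidia)),
            anchor_centroid=anchor.centroid,
            cells=number_cells_ccw(anchor.centroid, members[a_idx]),
        ))

    unassigned = [nucleus_blobs[j] for j in range(len(nucleus_blobs)) if j not in claims]
    if unassigned:
        log.warning("%d nucleus blobs claimed by no ommatidium; excluded", len(unassigned))
    return CellMap(ommatidia=ommatidia, unassigned=unassigned)
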