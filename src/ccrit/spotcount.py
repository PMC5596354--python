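"""Automated conventional spot counting (LoG baseline).

The classical transcript-counting route: Laplacian-of-Gaussian filtering to
enhance diffraction-limited spots, a spot-count-versus-threshold curve, an
automatically selected reference intensity from the curve's non-zero plateau
(minimum discrete derivative), and connected-component counting of the
binarized image.  The LoG kernel is negated so bright spots give a positive
response and a single ``>= threshold`` rule suffices.

This is the baseline the integrated-intensity (CCRIT) workflow is contrasted
with: it works well on clean, well-separated spots but degrades on crowded or
noisy signal, which is why the main pipeline forgoes Laplacian filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateInputError, NoPlateauError
from .io import ImageStack, RunConfig

log = logging.getLogger("ccrit")


def log_kernel(hsize: int, sigma: float) -> np.ndarray:
    """Negated, zero-sum Laplacian-of-Gaussian kernel of shape (hsize, hsize).

    Built like the classic ``fspecial('log')`` recipe on a (half-integer for
    even hsize) centered grid, mean-subtracted so a constant image maps to
    zero, then negated so bright blobs respond positively.
    """
    if hsize < 3:
        raise ValueError("hsize must be >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = (hsize - 1) / 2.0
    coords = np.arange(hsize) - half
    x, y = np.meshgrid(coords, coords)
    r2 = x * x + y * y
    g = np.exp(-r2 / (2.0 * sigma**2))
    g /= g.sum()
    kern = g * (r2 - 2.0 * sigma**2) / sigma**4
    kern -= kern.mean()          # exact zero response to a constant image
    return -kern


def log_filter(image: np.ndarray, hsize: int = 8, sigma: float = 0.8) -> np.ndarray:
    """Convolve with the negated LoG kernel, symmetric-reflection borders."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("log_filter expects a 2-D image")
    if hsize > min(image.shape):
        raise ValueError(f"hsize={hsize} exceeds image dimension {min(image.shape)}")
    return ndimage.convolve(image, log_kernel(hsize, sigma), mode="reflect")


@dataclass
class SpotCurve:
    """Spot count as a function of candidate intensity threshold."""

    thresholds: np.ndarray          # strictly increasing, spanning (0, max]
    counts: np.ndarray              # component count at each threshold
    selected_index: int | None = None

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.thresholds.ndim != 1 or self.thresholds.shape != self.counts.shape:
            raise ValueError("thresholds/counts must be matching 1-D arrays")
        if len(self.thresholds) and np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class SpotResult:
    """Outcome of counting spots at one reference intensity."""

    count: int
    threshold: float
    labels: np.ndarray              # labeled image of the counted components


def _label(binary: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    conn = 1 if connectivity == 4 else 2
    labels, n = measure.label(binary, connectivity=conn, return_num=True)
    return labels, n


def spot_curve(filtered: np.ndarray, n_bins: int = 100, connectivity: int = 8) -> SpotCurve:
    """Count components of the super-threshold image at ``n_bins`` equally
    spaced thresholds spanning ``(0, max(filtered)]``.

    Each threshold is evaluated independently; the curve is a pure function
    of the filtered image.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    vmax = float(filtered.max(initial=-np.inf))
    if vmax <= 0:
        raise DegenerateInputError("filtered image has no positive values")
    thresholds = vmax * np.arange(1, n_bins + 1) / n_bins
    counts = np.empty(n_bins, dtype=np.int64)
    for i, t in enumerate(thresholds):
        _, counts[i] = _label(filtered >= t, connectivity)
    return SpotCurve(thresholds=thresholds, counts=counts)


def select_plateau_threshold(curve: SpotCurve, min_run: int = 1) -> float:
    """Pick the reference intensity from the curve's non-zero plateau.

    Within the sub-range where counts are positive, the threshold at the
    minimum |forward difference| of the counts is returned, ties broken
    toward the lowest threshold.  With ``min_run > 1`` only positions lying
    inside a run of at least ``min_run`` consecutive equal counts are
    eligible — a guard that rejects curves whose flat stretches are no wider
    than the accidental equal-count runs produced by pure noise.

    Raises :class:`NoPlateauError` when no eligible position exists.
    """
    nz = np.flatnonzero(curve.counts > 0)
    if len(nz) < 3:
        raise NoPlateauError(f"only {len(nz)} thresholds with nonzero counts")
    counts = curve.counts[nz].astype(np.int64)
    diffs = np.diff(counts)

    # run length of consecutive equal counts covering each position
    run_len = np.empty(len(counts), dtype=np.int64)
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            run_len[start:i] = i - start
            start = i

    eligible = np.flatnonzero(run_len[:-1] >= min_run)   # positions with a forward diff
    if len(eligible) == 0:
        raise NoPlateauError(f"no plateau of >= {min_run} equal counts")
    best = eligible[np.argmin(np.abs(diffs[eligible]))]  # argmin keeps first on ties
    idx = int(nz[best])
    curve.selected_index = idx
    return float(curve.thresholds[idx])


def count_spots(filtered: np.ndarray, threshold: float, connectivity: int = 8) -> SpotResult:
    """Binarize at ``>= threshold`` and count connected components."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    labels, n = _label(np.asarray(filtered) >= threshold, connectivity)
    return SpotResult(count=n, threshold=float(threshold), labels=labels)


def run_spotcount(stack: ImageStack, config: RunConfig | None = None) -> list[SpotResult]:
    """Apply the full baseline per slice: LoG filter, spot curve, automatic
    plateau threshold, component count.

    Slices whose curve is degenerate or has no plateau report 0 spots with a
    logged warning (the expected outcome for transcript-free specimens).
    """
    config = config or RunConfig()
    results: list[SpotResult] = []
    for z, image in enumerate(stack):
        filtered = log_filter(image, hsize=config.log_hsize, sigma=config.log_sigma)
        try:
            curve = spot_curve(filtered, n_bins=config.n_bins,
                               connectivity=config.connectivity)
            threshold = select_plateau_threshold(curve, min_run=config.plateau_min_run)
        except (DegenerateInputError, NoPlateauError) as exc:
            log.warning("slice %d: %s; reporting 0 spots", z, exc)
            results.append(SpotResult(count=0, threshold=float("nan"),
                                      labels=np.zeros(image.shape, dtype=np.int32)))
            continue
        results.append(count_spots(filtered, threshold, connectivity=config.connectivity))
    return results
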