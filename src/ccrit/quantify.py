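"""Digital noise subtraction, masking, smoothing and per-cell integration.

The relative transcript measure of a cell is the sum of its noise-subtracted,
nucleus-masked (optionally Gaussian-smoothed) pixel intensities — integrated
intensity scales directly with the number of bound single-molecule probes, so
relative expression can be compared across cells and specimens even when
individual transcripts are not resolvable.

Per-slice integrated intensities are summarized per cell in three modes:
``ALL`` (every slice), ``CENTRAL80`` (symmetric 10% trim from each end of the
stack) and ``MAX`` (the slice with the largest whole-frame processed signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .assign import CellMap, assign_ommatidia
from .errors import EmptyMaskError, StageError
from .io import SUMMARY_COLUMNS, CellIntensityTable, ImageStack, RunConfig
from .masking import MaskPair, build_masks, label_blobs

log = logging.getLogger("ccrit")


def filter_anchor_blobs(background_blobs, config: RunConfig | None = None):
    """Drop background blobs far smaller than the largest one.

    Ommatidium cores have comparable areas; refined-mask debris well below
    that scale would otherwise seed spurious ommatidia.  Disabled when
    ``anchor_min_area_fraction`` is 0.
    """
    config = config or RunConfig()
    if not background_blobs or config.anchor_min_area_fraction == 0:
        return background_blobs
    cutoff = config.anchor_min_area_fraction * max(b.area for b in background_blobs)
    kept = [b for b in background_blobs if b.area >= cutoff]
    if len(kept) < len(background_blobs):
        log.info("dropped %d undersized anchor blobs",
                 len(background_blobs) - len(kept))
    return kept


def estimate_noise(image: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean intensity of the image over the background-mask pixels."""
    mask = np.asarray(background_mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("background mask is empty; cannot estimate noise")
    return float(np.asarray(image, dtype=np.float64)[mask].mean())


def subtract_noise(image: np.ndarray, noise: float) -> np.ndarray:
    """Subtract the scalar noise estimate, flooring at zero."""
    if noise < 0:
        raise ValueError("noise must be >= 0")
    return np.maximum(np.asarray(image, dtype=np.float64) - noise, 0.0)


def apply_cell_mask(image: np.ndarray, nucleus_mask: np.ndarray) -> np.ndarray:
    """Dot-multiply with the nucleus mask, zeroing extracellular signal."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(nucleus_mask)
    if image.shape != mask.shape:
        raise StageError("apply_cell_mask",
                         f"shape mismatch {image.shape} vs {mask.shape}")
    return image * mask.astype(np.float64)


def smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian smoothing with reflective borders (intensity-preserving
    away from borders)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(np.asarray(image, dtype=np.float64),
                                   sigma=sigma, mode="reflect")


def integrate_cells(image: np.ndarray, cell_map: CellMap) -> list[tuple[str, int, float]]:
    """Sum the processed image over each assigned cell's nucleus-blob pixels.

    Returns (ommatidium_label, cell_number, integrated_intensity) triples.
    """
    image = np.asarray(image, dtype=np.float64)
    out = []
    for omm in cell_map.ommatidia:
        for number, blob in omm.cells:
            px = blob.pixels
            total = float(image[px[:, 0], px[:, 1]].sum()) if len(px) else 0.0
            out.append((omm.label, number, total))
    return out


def central80_slice_range(n_slices: int) -> tuple[int, int]:
    """[start, stop) slice-index range of the central 80% of the stack."""
    start = int(np.floor(0.1 * n_slices))
    stop = int(np.ceil(0.9 * n_slices))
    return start, stop


def summarize(rows: pd.DataFrame, mode: str, n_slices: int,
              max_slice: int | None = None) -> pd.DataFrame:
    """Per-cell mean/sd of integrated intensity under one reporting mode.

    ``ALL``: every slice.  ``CENTRAL80``: symmetric 10% trim from each end
    (falls back to ALL with a warning when the stack has fewer than two
    slices).  ``MAX``: values from ``max_slice`` only (sd reported as 0).
    Sample standard deviation (ddof=1); defined as 0 for a single value.
    """
    if mode == "CENTRAL80" and n_slices < 2:
        log.warning("CENTRAL80 requested for %d-slice stack; using ALL", n_slices)
        mode = "CENTRAL80"  # label kept; selection identical to ALL below
        sel = rows
    elif mode == "CENTRAL80":
        start, stop = central80_slice_range(n_slices)
        sel = rows[(rows["slice_index"] >= start) & (rows["slice_index"] < stop)]
    elif mode == "MAX":
        if max_slice is None:
            raise ValueError("MAX mode needs the max-intensity slice index")
        sel = rows[rows["slice_index"] == max_slice]
    elif mode == "ALL":
        sel = rows
    else:
        raise ValueError(f"unknown summary mode {mode!r}")

    grouped = sel.groupby(["ommatidium_label", "cell_number"])["integrated_intensity"]
    stats = grouped.agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
    stats = stats.reset_index()
    stats.insert(2, "mode", mode)
    return stats[SUMMARY_COLUMNS]


@dataclass
class CCRITResult:
    """Full output of one pipeline run."""

    table: CellIntensityTable
    masks: MaskPair
    cell_map: CellMap
    noise_per_slice: list[float] = field(default_factory=list)
    max_slice: int = 0


def run_ccrit(nucleus_stack: ImageStack, fish_stack: ImageStack,
              config: RunConfig | None = None) -> CCRITResult:
    """The seven-step workflow: MIP, intensity binning, nucleus mask,
    background mask + cell assignment, mask application to the FISH stack,
    optional Gaussian smoothing, and per-cell integrated-intensity report.

    A pure, deterministic function of (stacks, config).
    """
    config = config or RunConfig()
    if nucleus_stack.data.shape != fish_stack.data.shape:
        raise StageError("input", f"stack geometries differ: "
                         f"{nucleus_stack.data.shape} vs {fish_stack.data.shape}")

    try:
        masks = build_masks(nucleus_stack, config)
    except Exception as exc:
        raise StageError("masking", str(exc)) from exc
    if not masks.background_mask.any():
        raise StageError("masking", "refined background mask is empty; "
                         "check refinement parameters against this specimen")

    try:
        nucleus_blobs = label_blobs(masks.nucleus_mask, config.connectivity)
        background_blobs = label_blobs(masks.background_mask, config.connectivity)
        background_blobs = filter_anchor_blobs(background_blobs, config)
        cell_map = assign_ommatidia(background_blobs, nucleus_blobs,
                                    gap_factor=config.gap_factor)
    except Exception as exc:
        raise StageError("assign", str(exc)) from exc

    records = []
    noise_per_slice = []
    slice_totals = []
    for z, image in enumerate(fish_stack):
        noise = estimate_noise(image, masks.background_mask)
        processed = subtract_noise(image, noise)
        processed = apply_cell_mask(processed, masks.nucleus_mask)
        if config.smooth_enabled:
            processed = smooth(processed, config.smooth_sigma)
        noise_per_slice.append(noise)
        slice_totals.append(float(processed.sum()))
        for label, number, total in integrate_cells(processed, cell_map):
            records.append((label, number, z, total))

    rows = pd.DataFrame(records, columns=["ommatidium_label", "cell_number",
                                          "slice_index", "integrated_intensity"])
    max_slice = int(np.argmax(slice_totals))
    if config.per_cell_max:
        # alternative MAX reading: each cell's own best slice
        max_rows = rows.loc[rows.groupby(["ommatidium_label", "cell_number"])
                            ["integrated_intensity"].idxmax()]
        max_summary = max_rows[["ommatidium_label", "cell_number"]].copy()
        max_summary["mode"] = "MAX"
        max_summary["mean"] = max_rows["integrated_intensity"].to_numpy()
        max_summary["sd"] = 0.0
        summaries = pd.concat([
            summarize(rows, "ALL", fish_stack.n_slices),
            summarize(rows, "CENTRAL80", fish_stack.n_slices),
            max_summary[SUMMARY_COLUMNS],
        ], ignore_index=True)
    else:
        summaries = pd.concat([
            summarize(rows, mode, fish_stack.n_slices, max_slice=max_slice)
            for mode in ("ALL", "CENTRAL80", "MAX")
        ], ignore_index=True)

    table = CellIntensityTable(rows=rows, summaries=summaries)
    return CCRITResult(table=table, masks=masks, cell_map=cell_map,
                       noise_per_slice=noise_per_slice, max_slice=max_slice)
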