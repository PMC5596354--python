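"""Stack and table I/O, run configuration, logging.

Image stacks are z-ordered sets of equally shaped 2-D intensity images for a
single channel.  The canonical on-disk form is a multi-page grayscale TIFF; a
directory of single-page TIFFs in lexical z-order is accepted as a common
confocal export dialect.  Channels (nuclear stain vs. FISH signal) are supplied
as two separate stacks.  Pixel coordinates are 0-based ``(row, col)`` with the
origin at the top-left; intensities are raw arbitrary units (integer inputs are
promoted to float64 without rescaling).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError

log = logging.getLogger("ccrit")

PER_SLICE_COLUMNS = ["ommatidium_label", "cell_number", "slice_index", "integrated_intensity"]
SUMMARY_COLUMNS = ["ommatidium_label", "cell_number", "mode", "mean", "sd"]

SUMMARY_MODES = ("ALL", "CENTRAL80", "MAX")


class ChannelRole(enum.Enum):
    NUCLEUS = "nucleus"
    FISH = "fish"


@dataclass
class ImageStack:
    """A z-ordered stack of 2-D non-negative intensity images for one channel.

    ``data`` has shape ``(n_slices, height, width)``; ``z_step`` and
    ``pixel_size`` are optional acquisition metadata in micrometres (e.g.
    0.65 µm slices over a 20 µm depth for the retina stacks this pipeline
    was designed around).
    """

    data: np.ndarray
    channel_role: ChannelRole = ChannelRole.FISH
    z_step: float | None = None
    pixel_size: float | None = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[np.newaxis, ...]
        if arr.ndim != 3:
            raise FormatError(f"stack must be 2-D or 3-D, got ndim={arr.ndim}")
        if arr.shape[0] < 1:
            raise FormatError("stack needs at least one slice")
        arr = arr.astype(np.float64, copy=False)
        if not np.isfinite(arr).all():
            raise FormatError("stack contains non-finite values")
        if (arr < 0).any():
            raise FormatError("stack contains negative intensities")
        self.data = arr

    @classmethod
    def from_slices(cls, slices: Sequence[np.ndarray], **kw) -> "ImageStack":
        shapes = {np.asarray(s).shape for s in slices}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent slice shapes: {sorted(shapes)}")
        return cls(np.stack([np.asarray(s) for s in slices]), **kw)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def __iter__(self):
        return iter(self.data)


@dataclass
class RunConfig:
    """Tunable parameters of the full workflow.

    Defaults follow the reference protocol for photoreceptor-neuron stacks:
    100 intensity bins, LoG kernel ``hsize=8, sigma=0.8``, background-mask
    refinement with opening (disk radius 5, minimum surviving area 50 px²),
    erosion (disk radius 10) and infill of holes up to 1500 px².
    """

    n_bins: int = 100
    log_hsize: int = 8
    log_sigma: float = 0.8
    open_min_area: int = 50
    erosion_radius: int = 10
    infill_max_hole: int = 1500
    open_disk_radius: int = 5
    smooth_sigma: float = 0.8
    smooth_enabled: bool = True
    connectivity: int = 8
    summary_mode: str = "ALL"
    gap_factor: float = 3.0
    plateau_min_run: int = 20
    anchor_min_area_fraction: float = 0.25
    per_cell_max: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        for name in ("log_hsize", "log_sigma", "open_min_area", "erosion_radius",
                     "infill_max_hole", "open_disk_radius", "smooth_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.summary_mode not in SUMMARY_MODES:
            raise ValueError(f"summary_mode must be one of {SUMMARY_MODES}")
        if self.plateau_min_run < 1:
            raise ValueError("plateau_min_run must be >= 1")
        if not 0.0 <= self.anchor_min_area_fraction < 1.0:
            raise ValueError("anchor_min_area_fraction must be in [0, 1)")

    @property
    def skimage_connectivity(self) -> int:
        # skimage encodes 4-connectivity as 1 and 8-connectivity as 2
        return 1 if self.connectivity == 4 else 2


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key/value YAML file mirroring :class:`RunConfig` fields."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise FormatError("config file must be a flat key/value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))


def load_stack(path: str | Path, channel_role: ChannelRole = ChannelRole.FISH,
               **metadata) -> ImageStack:
    """Load a multi-page TIFF (or a directory of per-slice TIFFs in lexical
    z-order) into an :class:`ImageStack`.

    Integer pixel types are promoted to float64 without rescaling.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF files in directory {path}")
        slices = [tifffile.imread(f) for f in files]
        for f, s in zip(files, slices):
            if s.ndim != 2:
                raise FormatError(f"{f} is not a single-page 2-D TIFF")
        return ImageStack.from_slices(slices, channel_role=channel_role, **metadata)
    arr = tifffile.imread(path)
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: expected a 2-D or multi-page grayscale TIFF, "
                          f"got shape {arr.shape}")
    return ImageStack(arr, channel_role=channel_role, **metadata)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page float TIFF (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float64), photometric="minisblack")
    return path


@dataclass
class CellIntensityTable:
    """Per-slice, per-cell integrated intensities plus stack-level summaries.

    ``rows`` columns: ommatidium_label, cell_number, slice_index,
    integrated_intensity.  ``summaries`` columns: ommatidium_label,
    cell_number, mode, mean, sd.
    """

    rows: pd.DataFrame
    summaries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SUMMARY_COLUMNS))

    def __post_init__(self):
        missing = set(PER_SLICE_COLUMNS) - set(self.rows.columns)
        if missing:
            raise FormatError(f"per-slice table missing columns: {sorted(missing)}")
        if len(self.rows) and (self.rows["integrated_intensity"] < 0).any():
            raise FormatError("integrated intensities must be non-negative")


def write_cell_table(table: CellIntensityTable, path: str | Path) -> tuple[Path, Path]:
    """Write the per-slice CSV at ``path`` and a summary CSV alongside it.

    For ``cells.csv`` the summary lands in ``cells_summary.csv``.  Floats are
    written with full repr precision so a re-read is value-exact.
    """
    if not len(table.rows):
        raise FormatError("refusing to write an empty cell table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary_path = path.with_name(path.stem + "_summary.csv")
    table.rows.to_csv(path, index=False, columns=PER_SLICE_COLUMNS)
    table.summaries.to_csv(summary_path, index=False, columns=SUMMARY_COLUMNS)
    return path, summary_path


def read_cell_table(path: str | Path) -> CellIntensityTable:
    path = Path(path)
    summary_path = path.with_name(path.stem + "_summary.csv")
    rows = pd.read_csv(path)
    if summary_path.exists():
        summaries = pd.read_csv(summary_path)
    else:
        summaries = pd.DataFrame(columns=SUMMARY_COLUMNS)
    return CellIntensityTable(rows=rows, summaries=summaries)
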