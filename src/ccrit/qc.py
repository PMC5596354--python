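"""Optional QC image outputs (false-color MIP, masks, labeled-cell overlay)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .assign import CellMap
from .masking import MaskPair


def _save(fig, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    import matplotlib.pyplot as plt
    plt.close(fig)
    return path


def save_mip_png(mip: np.ndarray, path: str | Path) -> Path:
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mip, cmap="viridis")
    ax.set_axis_off()
    return _save(fig, Path(path))


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.asarray(mask, dtype=float), cmap="gray", vmin=0, vmax=1)
    ax.set_axis_off()
    return _save(fig, Path(path))


def save_cell_overlay_png(masks: MaskPair, cell_map: CellMap, path: str | Path) -> Path:
    """Letter+number annotation of every assigned cell on the MIP."""
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.imshow(masks.mip, cmap="viridis")
    for omm in cell_map.ommatidia:
        ar, ac = omm.anchor_centroid
        ax.plot(ac, ar, "w+", markersize=10)
        for number, blob in omm.cells:
            r, c = blob.centroid
            ax.text(c, r, f"{omm.label}{number}", color="white", fontsize=7,
                    ha="center", va="center")
    ax.set_axis_off()
    return _save(fig, Path(path))


def save_spot_overlay_png(labels: np.ndarray, path: str | Path) -> Path:
    """Binary counted-spot image: counted spots in white on black."""
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(labels > 0, cmap="gray", vmin=0, vmax=1)
    ax.set_axis_off()
    return _save(fig, Path(path))
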