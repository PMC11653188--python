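"""Reading binary mask images and segmenting them into single cells.

The pipeline consumes 8-bit single-channel TIFF/PNG masks produced by an
upstream thresholding step (e.g. ImageJ).  Each connected component of
foreground is one candidate microglial cell.  For quality control, every
image gets a gallery directory of per-cell crops plus a manifest CSV so a
human can audit what was segmented.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio
from skimage import measure


@dataclass
class MaskImage:
    """A binarized photomicrograph plus its provenance metadata."""

    pixels: np.ndarray  # 2-D uint8 array of {0,1}
    image_id: str
    group: str | None = None
    lateral_mm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"mask must be single-channel 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("mask has zero extent")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask pixels must be strictly binary {0,1}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CellRecord:
    """One segmented cell, cropped to its bounding box.

    ``bbox`` is half-open ``(row0, col0, row1, col1)`` in parent-image
    coordinates (0-based, origin top-left); ``centroid`` is in the same
    frame.  ``image_shape`` is the parent canvas, kept so Sholl maximum
    distance can be measured against the image corners.
    """

    cell_id: str
    mask: np.ndarray  # bool, cropped to bbox
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    image_id: str
    group: str | None = None
    lateral_mm: float | None = None
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"cell {self.cell_id}: empty mask")
        r0, c0, r1, c1 = self.bbox
        if self.mask.shape != (r1 - r0, c1 - c0):
            raise ValueError(f"cell {self.cell_id}: mask shape does not match bbox")
        cr, cc = self.centroid
        if not (r0 <= cr < r1 and c0 <= cc < c1):
            raise ValueError(f"cell {self.cell_id}: centroid outside bbox")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def load_mask(
    path: str | Path,
    binarize_threshold: int = 127,
    *,
    image_id: str | None = None,
    group: str | None = None,
    lateral_mm: float | None = None,
) -> MaskImage:
    """Load a single-channel raster and binarize it (``value > threshold`` → 1).

    Raises ``OSError`` for unreadable files and ``ValueError`` for
    multi-channel images (naming the channel count).
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"mask file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except Exception as exc:  # decoder failures surface as I/O errors
        raise OSError(f"could not decode mask image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3:
        # tolerate a grayscale image stored with a redundant channel axis
        if raw.shape[2] == 1:
            raw = raw[:, :, 0]
        else:
            raise ValueError(
                f"{path}: expected single-channel mask, got {raw.shape[2]} channels"
            )
    elif raw.ndim != 2:
        raise ValueError(f"{path}: expected 2-D raster, got shape {raw.shape}")
    pixels = (raw > binarize_threshold).astype(np.uint8)
    return MaskImage(
        pixels=pixels,
        image_id=image_id if image_id is not None else path.stem,
        group=group,
        lateral_mm=lateral_mm,
    )


def read_metadata(csv_path: str | Path) -> pd.DataFrame:
    """Read the sidecar metadata table (``image_id,group,lateral_mm``)."""
    meta = pd.read_csv(csv_path, dtype={"image_id": str})
    required = {"image_id", "group", "lateral_mm"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return meta.set_index("image_id")


def load_masks(
    mask_dir: str | Path,
    metadata_csv: str | Path | None = None,
    binarize_threshold: int = 127,
) -> list[MaskImage]:
    """Load every TIFF/PNG mask in a directory, joining sidecar metadata."""
    mask_dir = Path(mask_dir)
    meta = read_metadata(metadata_csv) if metadata_csv is not None else None
    images = []
    paths = sorted(
        p for p in mask_dir.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    for p in paths:
        group = lateral = None
        if meta is not None and p.stem in meta.index:
            row = meta.loc[p.stem]
            group = None if pd.isna(row["group"]) else str(row["group"])
            lateral = None if pd.isna(row["lateral_mm"]) else float(row["lateral_mm"])
        images.append(
            load_mask(p, binarize_threshold, image_id=p.stem, group=group,
                      lateral_mm=lateral)
        )
    return images


def segment_cells(
    img: MaskImage,
    min_area: int = 60,
    connectivity: int = 8,
    border_policy: str = "keep",
) -> list[CellRecord]:
    """Split a binary image into per-cell records (connected components).

    Components smaller than ``min_area`` are discarded as debris; with
    ``border_policy='drop'`` components touching the canvas border are
    discarded too (truncated cells).  Cell ids are deterministic: components
    are ordered by their bounding-box top-left corner.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if border_policy not in ("keep", "drop"):
        raise ValueError("border_policy must be 'keep' or 'drop'")
    lab = measure.label(img.pixels, connectivity=1 if connectivity == 4 else 2)
    props = measure.regionprops(lab)
    h, w = img.pixels.shape
    kept = []
    for p in props:
        if p.area < min_area:
            continue
        r0, c0, r1, c1 = p.bbox
        if border_policy == "drop" and (r0 == 0 or c0 == 0 or r1 == h or c1 == w):
            continue
        kept.append(p)
    kept.sort(key=lambda p: (p.bbox[0], p.bbox[1]))
    cells = []
    for i, p in enumerate(kept):
        r0, c0, r1, c1 = p.bbox
        cells.append(
            CellRecord(
                cell_id=f"{img.image_id}_c{i:04d}",
                mask=lab[r0:r1, c0:c1] == p.label,
                bbox=(r0, c0, r1, c1),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                image_id=img.image_id,
                group=img.group,
                lateral_mm=img.lateral_mm,
                image_shape=(h, w),
            )
        )
    return cells


def write_cell_gallery(cells: list[CellRecord], out_dir: str | Path) -> Path:
    """Write one PNG crop per cell plus a ``manifest.csv`` for QC audit.

    Returns the manifest path.  Crops are 0/255 single-channel PNGs; reloading
    a crop with :func:`load_cell_crop` reproduces the boolean mask exactly.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = out_dir / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["cell_id", "file", "image_id", "row0", "col0", "row1",
                         "col1", "area"])
            for cell in cells:
                fname = f"{cell.cell_id}.png"
                iio.imwrite(out_dir / fname,
                            (cell.mask.astype(np.uint8) * 255))
                wr.writerow([cell.cell_id, fname, cell.image_id, *cell.bbox,
                             cell.area])
    except PermissionError as exc:
        raise OSError(f"gallery directory not writable: {out_dir}") from exc
    return manifest


def load_cell_crop(path: str | Path) -> np.ndarray:
    """Reload a gallery crop as a boolean mask."""
    return np.asarray(iio.imread(path)) > 127
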