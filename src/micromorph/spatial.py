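"""Spatial mapping of clustered cells back onto the tissue image.

Cells are painted in their cluster color over the source canvas, counted
per anatomical layer (polygon annotations, e.g. CA1 strata SO/SPyr/SR) and
per lateral-coordinate bin along the slice series, so cluster composition
can be compared across anatomy and not just in the embedding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .mask_io import CellRecord, MaskImage

logger = logging.getLogger(__name__)

#: Okabe-Ito colorblind-safe palette (RGB), cluster id -> color
PALETTE: tuple[tuple[int, int, int], ...] = (
    (230, 159, 0),    # orange
    (86, 180, 233),   # sky blue
    (0, 158, 115),    # bluish green
    (240, 228, 66),   # yellow
    (0, 114, 178),    # blue
    (213, 94, 0),     # vermillion
    (204, 121, 167),  # reddish purple
)
#: reserved color for noise cells (HDBSCAN label -1)
NOISE_COLOR: tuple[int, int, int] = (128, 128, 128)


@dataclass
class LayerAnnotation:
    """Named simple polygons (vertices as (row, col)) for one image."""

    image_id: str
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        polys = {}
        for name, verts in self.layers.items():
            arr = np.asarray(verts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
                raise ValueError(f"layer '{name}': need >= 3 (row,col) vertices")
            poly = Polygon(arr)
            if not poly.is_valid:
                raise ValueError(f"layer '{name}': polygon is self-intersecting")
            polys[name] = arr
        self.layers = polys

    def polygons(self) -> dict[str, Polygon]:
        return {name: Polygon(v) for name, v in self.layers.items()}


def load_annotations(path) -> dict[str, LayerAnnotation]:
    """Read layer polygons from JSON: image_id -> {layer: [[row,col],...]}."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        image_id: LayerAnnotation(image_id=image_id, layers=layers)
        for image_id, layers in raw.items()
    }


def _color_for(label: int, palette) -> tuple[int, int, int]:
    if label < 0:
        return NOISE_COLOR
    return tuple(palette[label % len(palette)])


def paint_clusters(
    img: MaskImage,
    cells: list[CellRecord],
    labels: pd.Series,
    palette=PALETTE,
) -> np.ndarray:
    """RGB overlay: each cell's foreground in its cluster color.

    Noise cells get the reserved gray; background stays black.  Every cell
    must have a label, otherwise a ``KeyError`` naming the cell is raised.
    """
    canvas = np.zeros((img.height, img.width, 3), dtype=np.uint8)
    for cell in cells:
        if cell.cell_id not in labels.index:
            raise KeyError(f"no cluster label for cell '{cell.cell_id}'")
        color = _color_for(int(labels.loc[cell.cell_id]), palette)
        r0, c0, r1, c1 = cell.bbox
        region = canvas[r0:r1, c0:c1]
        region[cell.mask] = color
    return canvas


_COUNT_COLUMNS = ["group", "image_id", "unit_type", "unit_name", "cluster",
                  "count", "rel_freq"]


def count_by_layer(
    cells: list[CellRecord],
    labels: pd.Series,
    ann: LayerAnnotation,
) -> pd.DataFrame:
    """Cluster census per anatomical layer of one image.

    A cell belongs to the first listed layer whose polygon covers its
    centroid (boundary counts as inside); cells outside every layer are
    tallied under ``unassigned``.  Noise cells are excluded.  Relative
    frequency normalizes within each layer; empty layers emit a zero-count
    row per cluster with missing frequency.
    """
    polys = ann.polygons()
    # overlap warning: any pairwise polygon intersection with interior area
    names = list(polys)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if polys[a].intersection(polys[b]).area > 0:
                logger.warning(
                    "layers '%s' and '%s' overlap; cells assigned to the "
                    "first-listed layer", a, b)
                break
    assigned: dict[str, list[int]] = {name: [] for name in names}
    assigned["unassigned"] = []
    for cell in cells:
        label = int(labels.loc[cell.cell_id])
        if label < 0:
            continue
        pt = Point(cell.centroid)
        for name in names:
            if polys[name].covers(pt):
                assigned[name].append(label)
                break
        else:
            assigned["unassigned"].append(label)
    clusters = sorted({lab for labs in assigned.values() for lab in labs})
    group = cells[0].group if cells else None
    image_id = ann.image_id
    rows = []
    for name, labs in assigned.items():
        total = len(labs)
        for k in clusters:
            count = labs.count(k)
            rows.append({
                "group": group,
                "image_id": image_id,
                "unit_type": "layer",
                "unit_name": name,
                "cluster": k,
                "count": count,
                "rel_freq": count / total if total else np.nan,
            })
    return pd.DataFrame(rows, columns=_COUNT_COLUMNS)


def count_by_lateral_bin(
    cells: list[CellRecord],
    labels: pd.Series,
    bin_start: float = 0.48,
    bin_width: float = 0.24,
) -> pd.DataFrame:
    """Mean per-image cluster counts in half-open lateral-coordinate bins.

    Bins are [start + k*width, start + (k+1)*width) in mm along the
    lateral axis of the slice series.  Within each bin the per-cluster cell
    count is first tallied per image, then averaged over the images falling
    in that bin.  Cells without ``lateral_mm`` are excluded (logged).
    ``rel_freq`` is the bin-level share of each cluster's mean count.
    """
    records = []
    n_missing = 0
    for cell in cells:
        label = int(labels.loc[cell.cell_id])
        if label < 0:
            continue
        if cell.lateral_mm is None:
            n_missing += 1
            continue
        k = int(np.floor((cell.lateral_mm - bin_start) / bin_width))
        records.append({
            "group": cell.group,
            "image_id": cell.image_id,
            "bin_index": k,
            "cluster": label,
        })
    if n_missing:
        logger.warning("%d cells lacked lateral_mm and were excluded", n_missing)
    if not records:
        return pd.DataFrame(columns=_COUNT_COLUMNS)
    df = pd.DataFrame(records)
    per_image = (
        df.groupby(["group", "bin_index", "image_id", "cluster"])
        .size()
        .rename("count")
        .reset_index()
    )
    # images contribute zero counts for clusters they lack within their bin
    full = (
        per_image.pivot_table(index=["group", "bin_index", "image_id"],
                              columns="cluster", values="count", fill_value=0)
        .stack()
        .rename("count")
        .reset_index()
    )
    mean_counts = (
        full.groupby(["group", "bin_index", "cluster"])["count"]
        .mean()
        .reset_index()
    )
    rows = []
    for (group, k), sub in mean_counts.groupby(["group", "bin_index"]):
        total = sub["count"].sum()
        lo = bin_start + k * bin_width
        hi = lo + bin_width
        name = f"[{lo:.2f},{hi:.2f})"
        for _, rec in sub.iterrows():
            rows.append({
                "group": group,
                "image_id": None,
                "unit_type": "lateral_bin",
                "unit_name": name,
                "cluster": int(rec["cluster"]),
                "count": float(rec["count"]),
                "rel_freq": rec["count"] / total if total else np.nan,
            })
    return pd.DataFrame(rows, columns=_COUNT_COLUMNS)
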