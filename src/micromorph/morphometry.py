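"""Morphometric feature extraction for single microglial cells.

Thirty-two features per cell, in five families:

* ``Sk_`` skeleton (4): total branch length, initial points (processes
  leaving the soma), junction points, endpoints.
* ``So_`` soma (8): shape descriptors of the detected cell body.
* ``C_`` cell (8): the same descriptors on the whole silhouette.
* ``F_`` fractal / convex hull (9): the descriptors on the convex hull plus
  the box-counting fractal dimension of the silhouette.
* ``Sh_`` Sholl (3): number of concentric circles reached, total process
  crossings, and the maximum centroid-to-image-corner distance.

All coordinates are (row, col), 0-based, origin top-left.  Lengths are in
pixels, angles in degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .mask_io import CellRecord

logger = logging.getLogger(__name__)

SHAPE_FIELDS = (
    "area",
    "perimeter",
    "circularity",
    "feret_diameter",
    "compactness",
    "aspect_ratio",
    "orientation",
    "eccentricity",
)

#: canonical ordered names of the 32 features
FEATURE_NAMES: tuple[str, ...] = (
    ("Sk_branch_length", "Sk_initial_points", "Sk_junctions", "Sk_endpoints")
    + tuple(f"So_{f}" for f in SHAPE_FIELDS)
    + tuple(f"C_{f}" for f in SHAPE_FIELDS)
    + tuple(f"F_{f}" for f in SHAPE_FIELDS)
    + ("F_fractal_dimension",)
    + ("Sh_circles", "Sh_crossings", "Sh_max_distance")
)

META_COLUMNS = ("cell_id", "image_id", "group", "lateral_mm",
                "centroid_row", "centroid_col")


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable parameters of the feature extraction stage.

    ``soma_opening_radius`` is the disk radius (px) of the morphological
    opening used to isolate the cell body; 6 px suits 40x magnification.
    ``sholl_step`` is the radius increment (px) between consecutive Sholl
    circles.  ``diagonal_weight`` sets the length contributed by a diagonal
    skeleton step when summing branch length (1.0 counts pixels, sqrt(2)
    counts Euclidean step length).
    """

    soma_opening_radius: int = 6
    sholl_step: float = 10.0
    diagonal_weight: float = 1.0


@dataclass(frozen=True)
class ShapeMetrics:
    area: float
    perimeter: float
    circularity: float
    feret_diameter: float
    compactness: float
    aspect_ratio: float
    orientation: float
    eccentricity: float


@dataclass(frozen=True)
class SkeletonMetrics:
    branch_length: float
    n_initial_points: int
    n_junctions: int
    n_endpoints: int


@dataclass(frozen=True)
class ShollMetrics:
    n_circles: int
    n_crossings: int
    max_distance: float


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """Longest marching-squares contour of the padded mask (sub-pixel)."""
    padded = np.pad(mask, 1).astype(float)
    # high connectivity keeps 8-connected 1-px processes on one boundary
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    return max(contours, key=lambda c: c.shape[0])


def _polygon_length(poly: np.ndarray) -> float:
    d = np.diff(poly, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _moments_ellipse(mask: np.ndarray) -> tuple[float, float, float]:
    """(major, minor, orientation_deg) of the best-fit ellipse.

    Second central moments with a +1/12 per-axis term for the unit-square
    pixel extent, so single pixels and 1-px lines stay non-degenerate.
    Orientation is the major-axis angle from the positive column axis,
    reported in [0, 180).
    """
    coords = np.argwhere(mask).astype(float)
    mu = coords.mean(axis=0)
    centered = coords - mu
    cov = centered.T @ centered / len(coords) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    minor, major = 4.0 * np.sqrt(evals[0]), 4.0 * np.sqrt(evals[1])
    v = evecs[:, 1]  # (row, col) components of the major axis
    theta = math.degrees(math.atan2(v[0], v[1])) % 180.0
    return major, minor, theta


def shape_metrics(mask: np.ndarray) -> ShapeMetrics:
    """Eight shape descriptors of a binary silhouette.

    Perimeter is the length of the Douglas-Peucker-simplified (1 px
    tolerance) marching-squares boundary polygon; circularity is
    4*pi*A/P^2 (1 for a perfect circle); compactness is the equivalent
    circular diameter over the Feret diameter; aspect ratio is bounding-box
    width/height; eccentricity is major/minor ellipse axis (>= 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape_metrics: empty mask")
    area = float(mask.sum())
    contour = _outer_contour(mask)
    poly = measure.approximate_polygon(contour, tolerance=1.0)
    perimeter = _polygon_length(poly)
    if perimeter <= 1.0:  # DP degenerates on very small contours
        perimeter = _polygon_length(contour)
    circularity = 4.0 * math.pi * area / perimeter**2

    # Feret: max pairwise distance over convex-hull vertices of the contour
    hull_pts = contour[_convex_hull_vertex_ids(contour)]
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    feret = float(np.sqrt((diffs**2).sum(-1)).max())

    compactness = math.sqrt(4.0 * area / math.pi) / feret
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    bbox_h = float(rows[-1] - rows[0] + 1)
    bbox_w = float(cols[-1] - cols[0] + 1)
    major, minor, orientation = _moments_ellipse(mask)
    return ShapeMetrics(
        area=area,
        perimeter=perimeter,
        circularity=circularity,
        feret_diameter=feret,
        compactness=compactness,
        aspect_ratio=bbox_w / bbox_h,
        orientation=orientation,
        eccentricity=major / minor,
    )


def _convex_hull_vertex_ids(points: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull, QhullError

    if len(points) < 3:
        return np.arange(len(points))
    try:
        return ConvexHull(points).vertices
    except QhullError:  # collinear points
        return np.arange(len(points))


def detect_soma(mask: np.ndarray, opening_radius: int = 6) -> np.ndarray:
    """Isolate the cell body as the largest blob surviving a disk opening.

    Structures thinner than the disk element (processes) are erased by the
    opening; the largest surviving component is the soma.  If the whole cell
    is thinner than the element, fall back to the maximal inscribed disk
    (distance-transform peak), guaranteeing a non-empty soma.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("detect_soma: empty mask")
    opened = morphology.opening(mask, morphology.disk(opening_radius))
    if opened.any():
        lab = measure.label(opened, connectivity=2)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        return lab == largest
    # fallback: maximal inscribed disk
    edt = ndimage.distance_transform_edt(mask)
    peak = np.unravel_index(np.argmax(edt), edt.shape)
    radius = float(edt[peak])
    rr, cc = np.indices(mask.shape)
    disk = (rr - peak[0]) ** 2 + (cc - peak[1]) ** 2 <= radius**2
    soma = mask & disk
    if not soma.any():  # radius < 1: keep the peak pixel itself
        soma = np.zeros_like(mask)
        soma[peak] = True
    return soma


def skeletonize_cell(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving 1-px skeleton of the cell silhouette."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("skeletonize_cell: empty mask")
    return morphology.skeletonize(mask)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skeleton.astype(int), _NEIGHBOR_KERNEL,
                            mode="constant")


def skeleton_metrics(
    skeleton: np.ndarray,
    soma: np.ndarray | None = None,
    diagonal_weight: float = 1.0,
) -> SkeletonMetrics:
    """Branch-structure counts on a 1-px skeleton.

    Endpoints have exactly one 8-connected skeleton neighbor; junction
    pixels have three or more, with touching junction pixels merged into a
    single junction.  Initial points are skeleton pixels outside the soma
    that touch it (the roots of processes).  Branch length sums skeleton
    pixels outside the soma; with ``diagonal_weight=sqrt(2)`` diagonal steps
    count their Euclidean length instead of 1.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        return SkeletonMetrics(0.0, 0, 0, 0)
    if soma is None:
        soma = np.zeros_like(skeleton)
    soma = np.asarray(soma, dtype=bool)
    nbrs = _neighbor_counts(skeleton)
    endpoints = skeleton & (nbrs == 1)
    junction_px = skeleton & (nbrs >= 3)
    n_junctions = int(measure.label(junction_px, connectivity=2).max())
    outside = skeleton & ~soma
    touching = ndimage.binary_dilation(soma, structure=np.ones((3, 3)))
    initial = outside & touching
    if diagonal_weight == 1.0:
        branch_length = float(outside.sum())
    else:
        branch_length = _weighted_length(outside, diagonal_weight)
    return SkeletonMetrics(
        branch_length=branch_length,
        n_initial_points=int(initial.sum()),
        n_junctions=n_junctions,
        n_endpoints=int(endpoints.sum()),
    )


def _weighted_length(skel: np.ndarray, diagonal_weight: float) -> float:
    """Pixel count with diagonal-only connections up-weighted.

    A pixel whose link to the structure is purely diagonal contributes
    ``diagonal_weight`` instead of 1.
    """
    ortho = ndimage.convolve(
        skel.astype(int), np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]),
        mode="constant")
    diag_only = skel & (ortho == 0)
    return float(skel.sum() - diag_only.sum() + diagonal_weight * diag_only.sum())


def fractal_dimension(
    mask: np.ndarray, box_sizes: list[int] | None = None
) -> float:
    """Box-counting fractal dimension of the filled silhouette.

    Counts occupied boxes N(s) on grids of dyadic side s anchored at the
    top-left corner and returns minus the least-squares slope of
    log N(s) vs log s, clipped to [0, 2].  Default sizes are
    {2, 4, ..., max(h, w)/2}.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("fractal_dimension: empty mask")
    h, w = mask.shape
    if box_sizes is None:
        box_sizes = []
        s = 2
        while s <= max(h, w) // 2:
            box_sizes.append(s)
            s *= 2
    if len(box_sizes) < 2:
        raise ValueError("fractal_dimension: need at least 2 box sizes")
    counts = []
    for s in box_sizes:
        ph = (-h) % s
        pw = (-w) % s
        m = np.pad(mask, ((0, ph), (0, pw)))
        blocks = m.reshape(m.shape[0] // s, s, m.shape[1] // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    counts = np.asarray(counts, dtype=float)
    if np.all(counts == counts[0]):
        raise ValueError("fractal_dimension: degenerate fit (all box counts equal)")
    slope = np.polyfit(np.log(np.asarray(box_sizes, float)), np.log(counts), 1)[0]
    return float(np.clip(-slope, 0.0, 2.0))


def convex_hull_mask(mask: np.ndarray) -> np.ndarray:
    """Filled convex hull of the foreground pixels (superset of the mask)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("convex_hull_mask: empty mask")
    return morphology.convex_hull_image(mask)


def sholl_metrics(
    skeleton: np.ndarray,
    soma_centroid: tuple[float, float],
    image_shape: tuple[int, int],
    step: float = 10.0,
    origin: tuple[int, int] = (0, 0),
) -> ShollMetrics:
    """Concentric-circle crossing counts around the soma centroid.

    Circles of radius step, 2*step, ... are drawn up to the largest circle
    that still reaches a skeleton pixel.  A crossing is one connected run of
    skeleton pixels inside a circle's 1-px annulus (thick intersections are
    not double-counted); ``n_crossings`` sums runs over all circles.
    ``max_distance`` is the largest Euclidean distance from the centroid (in
    image coordinates, i.e. offset by ``origin``) to the four image corners.

    ``skeleton`` and ``soma_centroid`` share a local frame; ``origin`` is
    that frame's offset inside the parent image.
    """
    if step <= 0:
        raise ValueError("sholl step must be positive")
    skeleton = np.asarray(skeleton, dtype=bool)
    h, w = image_shape
    gr = soma_centroid[0] + origin[0]
    gc = soma_centroid[1] + origin[1]
    corners = [(0.0, 0.0), (0.0, float(w)), (float(h), 0.0), (float(h), float(w))]
    max_distance = max(math.hypot(gr - r, gc - c) for r, c in corners)
    if not skeleton.any():
        return ShollMetrics(0, 0, max_distance)
    rr, cc = np.indices(skeleton.shape)
    dist = np.hypot(rr - soma_centroid[0], cc - soma_centroid[1])
    reach = float(dist[skeleton].max())
    n_circles = int(reach // step)
    n_crossings = 0
    for k in range(1, n_circles + 1):
        annulus = skeleton & (np.abs(dist - k * step) <= 0.5)
        n_crossings += int(measure.label(annulus, connectivity=2).max())
    return ShollMetrics(n_circles, n_crossings, max_distance)


class FeatureExtractionError(RuntimeError):
    """A cell whose features could not be computed."""


def extract_features(
    cell: CellRecord, config: MorphometryConfig = MorphometryConfig()
) -> dict[str, float]:
    """Compute the full 32-feature vector for one cell.

    Returns an ordered mapping following :data:`FEATURE_NAMES`; raises
    :class:`FeatureExtractionError` if any family fails (e.g. degenerate
    fractal fit on a tiny mask), so callers can flag and exclude the cell.
    """
    try:
        mask = cell.mask
        soma = detect_soma(mask, config.soma_opening_radius)
        skeleton = skeletonize_cell(mask)
        hull = convex_hull_mask(mask)

        sk = skeleton_metrics(skeleton, soma, config.diagonal_weight)
        so = shape_metrics(soma)
        ce = shape_metrics(mask)
        fr = shape_metrics(hull)
        fd = fractal_dimension(mask)
        soma_centroid = tuple(np.argwhere(soma).mean(axis=0))
        if cell.image_shape is not None:
            image_shape = cell.image_shape
            origin = (cell.bbox[0], cell.bbox[1])
        else:
            image_shape = mask.shape
            origin = (0, 0)
        sh = sholl_metrics(skeleton, soma_centroid, image_shape,
                           config.sholl_step, origin)
    except ValueError as exc:
        raise FeatureExtractionError(f"cell {cell.cell_id}: {exc}") from exc

    values: dict[str, float] = {
        "Sk_branch_length": sk.branch_length,
        "Sk_initial_points": float(sk.n_initial_points),
        "Sk_junctions": float(sk.n_junctions),
        "Sk_endpoints": float(sk.n_endpoints),
    }
    for prefix, metrics in (("So", so), ("C", ce), ("F", fr)):
        for field_name, value in asdict(metrics).items():
            values[f"{prefix}_{field_name}"] = float(value)
    values["F_fractal_dimension"] = fd
    values["Sh_circles"] = float(sh.n_circles)
    values["Sh_crossings"] = float(sh.n_crossings)
    values["Sh_max_distance"] = sh.max_distance

    assert tuple(values) == FEATURE_NAMES
    if not all(math.isfinite(v) for v in values.values()):
        raise FeatureExtractionError(f"cell {cell.cell_id}: non-finite feature")
    return values


def features_table(
    cells: list[CellRecord],
    config: MorphometryConfig = MorphometryConfig(),
):
    """Feature matrix for a list of cells.

    Returns ``(table, failures)`` where ``table`` is a DataFrame with the
    metadata columns followed by the 32 features, and ``failures`` lists
    ``(cell_id, reason)`` for cells that were flagged and excluded.
    """
    import pandas as pd

    rows = []
    failures: list[tuple[str, str]] = []
    for cell in cells:
        try:
            feats = extract_features(cell, config)
        except FeatureExtractionError as exc:
            logger.warning("excluding cell: %s", exc)
            failures.append((cell.cell_id, str(exc)))
            continue
        row = {
            "cell_id": cell.cell_id,
            "image_id": cell.image_id,
            "group": cell.group,
            "lateral_mm": cell.lateral_mm,
            "centroid_row": cell.centroid[0],
            "centroid_col": cell.centroid[1],
        }
        row.update(feats)
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))
    return table, failures
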