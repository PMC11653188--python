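"""Synthetic microglia-like mask generator with known ground truth.

Real microglial silhouettes span a continuum from compact, near-circular
(amoeboid) cells to small-bodied cells with long, tortuous, branched
processes (ramified/homeostatic).  This module draws parametric cartoons of
that spectrum — a disk soma plus random-walk processes that may branch — so
every pipeline stage can be exercised against a known archetype label,
soma mask and process count.  The cartoons make no claim of biological
fidelity; they reproduce the *ordering* of morphometric features along the
spectrum (circularity falls, endpoints rise, from amoeboid to ramified).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw, morphology

from .mask_io import MaskImage


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parametric description of one morphology archetype.

    Tuple parameters are (mean, sd) of a normal draw per cell.
    ``branch_prob`` is the probability that a process segment spawns one
    side branch at a uniformly random point along it (applied recursively to
    sub-branches, depth-capped).  ``tortuosity`` is the sd (radians) of the
    per-step heading noise of the random walk.  ``process_width`` is the
    drawn thickness of processes in px.
    """

    name: str
    soma_radius: tuple[float, float]
    n_processes: tuple[float, float]
    process_length: tuple[float, float]
    branch_prob: float
    tortuosity: float
    process_width: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0,1]")
        if self.soma_radius[0] <= 0 or self.process_length[0] <= 0:
            raise ValueError("means must be positive")


#: compact phagocytic-like cells: big soma, fully retracted processes
AMOEBOID = ArchetypeSpec(
    name="amoeboid",
    soma_radius=(12.0, 1.5),
    n_processes=(0.0, 0.0),
    process_length=(5.0, 1.0),
    branch_prob=0.0,
    tortuosity=0.2,
    process_width=4,
)

#: activated-like cells: medium soma, few short thick processes
REACTIVE = ArchetypeSpec(
    name="reactive",
    soma_radius=(9.0, 1.0),
    n_processes=(3.0, 0.8),
    process_length=(35.0, 8.0),
    branch_prob=0.15,
    tortuosity=0.3,
    process_width=3,
)

#: homeostatic-like cells: small soma, many long thin branched processes
RAMIFIED = ArchetypeSpec(
    name="ramified",
    soma_radius=(7.0, 0.8),
    n_processes=(6.0, 1.0),
    process_length=(80.0, 12.0),
    branch_prob=0.3,
    tortuosity=0.1,
    process_width=1,
)

ARCHETYPES: dict[str, ArchetypeSpec] = {
    a.name: a for a in (AMOEBOID, REACTIVE, RAMIFIED)
}

_MAX_BRANCH_DEPTH = 3


@dataclass
class CellTruth:
    """A generated cell and its ground truth."""

    mask: np.ndarray  # bool canvas
    soma_mask: np.ndarray
    archetype: str
    n_processes: int


def _walk(
    start: tuple[float, float],
    heading: float,
    length: int,
    spec: ArchetypeSpec,
    rng: np.random.Generator,
    points: list[tuple[int, int]],
    depth: int,
) -> None:
    """Trace one process segment, recording visited pixels; maybe branch."""
    branch_at = -1
    if depth < _MAX_BRANCH_DEPTH and length > 8 and rng.random() < spec.branch_prob:
        branch_at = int(rng.integers(4, length - 2))
    r, c = start
    for i in range(length):
        heading += rng.normal(0.0, spec.tortuosity)
        r += -np.cos(heading)  # heading 0 points "up" (decreasing row)
        c += np.sin(heading)
        points.append((int(round(r)), int(round(c))))
        if i == branch_at:
            side = heading + rng.choice((-1.0, 1.0)) * rng.uniform(0.5, 1.1)
            _walk((r, c), side, int((length - i) * 0.7), spec, rng,
                  points, depth + 1)


def make_cell(
    spec: ArchetypeSpec,
    rng: np.random.Generator,
    canvas: tuple[int, int] | None = None,
) -> CellTruth:
    """Draw one cell of the given archetype on its own canvas.

    The canvas defaults to a square comfortably containing the soma plus
    the 3-sigma process reach.  Deterministic given the generator state.
    Raises ``ValueError`` if an explicit canvas cannot hold the cell.
    """
    soma_r = max(2.0, rng.normal(*spec.soma_radius))
    n_proc = max(0, int(round(rng.normal(*spec.n_processes))))
    reach = int(soma_r + spec.process_length[0] + 3 * spec.process_length[1]) + 4
    side = 2 * reach + 1
    if canvas is None:
        canvas = (side, side)
    if canvas[0] < side or canvas[1] < side:
        raise ValueError(
            f"canvas {canvas} too small for archetype '{spec.name}' "
            f"(needs {side}x{side})"
        )
    center = (canvas[0] // 2, canvas[1] // 2)
    soma = np.zeros(canvas, dtype=bool)
    # elliptical soma: real cell bodies are elongated to varying degrees
    elong = rng.uniform(1.0, 1.5)
    theta = rng.uniform(0.0, np.pi)
    rr, cc = draw.ellipse(center[0], center[1],
                          soma_r * np.sqrt(elong), soma_r / np.sqrt(elong),
                          shape=canvas, rotation=theta)
    soma[rr, cc] = True

    points: list[tuple[int, int]] = []
    base = rng.uniform(0.0, 2.0 * np.pi)
    anchor_r = max(1.0, soma_r / np.sqrt(elong) - 1)  # inside at any angle
    for k in range(n_proc):
        angle = base + 2.0 * np.pi * k / max(n_proc, 1) + rng.normal(0.0, 0.2)
        start = (center[0] - anchor_r * np.cos(angle),
                 center[1] + anchor_r * np.sin(angle))
        length = max(5, int(round(rng.normal(*spec.process_length))))
        _walk(start, angle, length, spec, rng, points, depth=0)

    procs = np.zeros(canvas, dtype=bool)
    if points:
        pts = np.asarray(points)
        keep = ((pts[:, 0] >= 0) & (pts[:, 0] < canvas[0])
                & (pts[:, 1] >= 0) & (pts[:, 1] < canvas[1]))
        pts = pts[keep]
        procs[pts[:, 0], pts[:, 1]] = True
        if spec.process_width > 1:
            procs = morphology.dilation(
                procs, morphology.disk(spec.process_width // 2))
    mask = soma | procs
    return CellTruth(mask=mask, soma_mask=soma, archetype=spec.name,
                     n_processes=n_proc)


@dataclass
class SceneSpec:
    """Layout of one synthetic image: canvas, census and provenance."""

    n_cells: dict[str, int]  # archetype name -> count
    canvas: tuple[int, int] = (768, 768)
    min_separation: float = 40.0
    seed: int = 0
    image_id: str = "scene_0"
    group: str = "G0"
    lateral_mm: float | None = None


_MAX_TRIES = 1000


def make_scene(
    spec: SceneSpec,
    archetypes: dict[str, ArchetypeSpec] = ARCHETYPES,
) -> tuple[MaskImage, pd.DataFrame]:
    """Compose non-overlapping cells onto one canvas by rejection sampling.

    Returns the composite binary image plus a ground-truth table with one
    row per placed cell (archetype, canvas position, process count).
    Raises ``RuntimeError`` when a cell cannot be placed within the try
    budget — use a larger canvas or fewer cells.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros(spec.canvas, dtype=bool)
    occupied = np.zeros(spec.canvas, dtype=bool)  # foreground + margin
    centers: list[tuple[float, float]] = []
    truth_rows = []
    order = [name for name in sorted(spec.n_cells) for _ in range(spec.n_cells[name])]
    rng.shuffle(order)
    for name in order:
        cell = make_cell(archetypes[name], rng)
        ch, cw = cell.mask.shape
        placed = False
        for _ in range(_MAX_TRIES):
            r0 = int(rng.integers(0, spec.canvas[0] - ch + 1))
            c0 = int(rng.integers(0, spec.canvas[1] - cw + 1))
            center = (r0 + ch / 2.0, c0 + cw / 2.0)
            if any(
                np.hypot(center[0] - r, center[1] - c) < spec.min_separation
                for r, c in centers
            ):
                continue
            region = occupied[r0:r0 + ch, c0:c0 + cw]
            if (region & cell.mask).any():
                continue
            canvas[r0:r0 + ch, c0:c0 + cw] |= cell.mask
            # 2-px exclusion margin keeps neighboring cells disconnected
            grown = morphology.dilation(cell.mask, morphology.disk(2))
            occupied[r0:r0 + ch, c0:c0 + cw] |= grown
            centers.append(center)
            coords = np.argwhere(cell.mask)
            truth_rows.append(
                {
                    "image_id": spec.image_id,
                    "archetype": name,
                    "row0": r0,
                    "col0": c0,
                    "centroid_row": float(coords[:, 0].mean() + r0),
                    "centroid_col": float(coords[:, 1].mean() + c0),
                    "n_processes": cell.n_processes,
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a '{name}' cell after {_MAX_TRIES} tries; "
                "reduce n_cells or enlarge the canvas"
            )
    img = MaskImage(
        pixels=canvas.astype(np.uint8),
        image_id=spec.image_id,
        group=spec.group,
        lateral_mm=spec.lateral_mm,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["image_id", "archetype", "row0", "col0",
                 "centroid_row", "centroid_col", "n_processes"],
    )
    return img, truth


def archetype_feature_table(
    n_per_archetype: int = 25,
    n_scenes: int = 4,
    seed: int = 0,
    canvas: tuple[int, int] = (1024, 1024),
    groups: tuple[str, ...] = ("G0", "G1"),
) -> pd.DataFrame:
    """Morphometric feature table for scenes of all three archetypes.

    Distributes ``n_per_archetype`` cells of each archetype across
    ``n_scenes`` scenes (scene group labels cycle through ``groups``),
    segments the composites back out and extracts the 32 features.  The
    returned table carries an extra ``archetype`` ground-truth column —
    the basis of end-to-end recovery checks.
    """
    from . import mask_io, morphometry

    per_scene = [n_per_archetype // n_scenes] * n_scenes
    for i in range(n_per_archetype % n_scenes):
        per_scene[i] += 1
    cells, archs = [], []
    for s in range(n_scenes):
        spec = SceneSpec(
            n_cells={name: per_scene[s] for name in ARCHETYPES},
            canvas=canvas,
            seed=seed * 1000 + s,
            image_id=f"scene_{seed}_{s}",
            group=groups[s % len(groups)],
            lateral_mm=0.48 + 0.24 * (s % 6),
        )
        img, truth = make_scene(spec)
        scene_cells = mask_io.segment_cells(img)
        cells.extend(scene_cells)
        archs.extend(match_cells_to_truth(scene_cells, truth))
    table, _ = morphometry.features_table(cells)
    table["archetype"] = archs
    return table


def grouped_feature_table(
    groups: tuple[str, ...] = ("SS-CA1", "SCOP-CA1", "SS-Hilus", "SCOP-Hilus"),
    cells_per_group: int = 50,
    seed: int = 0,
    canvas: tuple[int, int] = (1280, 1280),
) -> pd.DataFrame:
    """Labeled feature table with a group-dependent archetype mix.

    Each study group gets ``cells_per_group`` cells whose archetype
    proportions rotate with the group index (so groups differ in
    morphology, giving supervised feature selection a real signal),
    mirroring a saline-vs-treatment design.
    """
    from . import mask_io, morphometry

    names = list(ARCHETYPES)
    base = np.array([0.5, 0.3, 0.2])
    frames = []
    for gi, group in enumerate(groups):
        w = np.roll(base, gi % len(names))
        counts = np.floor(w * cells_per_group).astype(int)
        counts[np.argmax(w)] += cells_per_group - counts.sum()
        census = {name: int(c) for name, c in zip(names, counts) if c > 0}
        # split a group's census across two scenes to keep placement easy
        halves = [{k: v // 2 for k, v in census.items()},
                  {k: v - v // 2 for k, v in census.items()}]
        for s, half in enumerate(halves):
            half = {k: v for k, v in half.items() if v > 0}
            if not half:
                continue
            spec = SceneSpec(
                n_cells=half,
                canvas=canvas,
                seed=seed * 1000 + gi * 10 + s,
                image_id=f"{group}_s{s}",
                group=group,
                lateral_mm=0.48 + 0.24 * s,
            )
            img, _ = make_scene(spec)
            cells = mask_io.segment_cells(img)
            tab, _ = morphometry.features_table(cells)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def match_cells_to_truth(cells, truth: pd.DataFrame) -> list[str]:
    """Archetype label per segmented cell, by nearest ground-truth centroid."""
    labels = []
    tr = truth[["centroid_row", "centroid_col"]].to_numpy()
    for cell in cells:
        d = np.hypot(tr[:, 0] - cell.centroid[0], tr[:, 1] - cell.centroid[1])
        labels.append(str(truth["archetype"].iloc[int(np.argmin(d))]))
    return labels
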