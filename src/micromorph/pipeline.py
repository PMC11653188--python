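"""Five-stage pipeline orchestration with resumable per-stage artifacts.

Stage order: (1) morphometry — segment masks and extract the 32 features;
(2) feature selection — RFE keeps the discriminative half; (3) embedding —
UMAP to 2-D; (4) clustering — HDBSCAN with noise; (5) spatial — painted
overlays, per-layer and per-lateral-bin counts, and the statistics reports.
Each stage writes a CSV that the next stage can be resumed from.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio

from . import mask_io, morphometry, pipeline_ml, spatial, stats
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("features", "select", "embed", "cluster", "spatial")


class DataError(RuntimeError):
    """A stage failed on the input data; message names the stage."""


def _load_and_segment(cfg: PipelineConfig) -> tuple[list, list]:
    images = mask_io.load_masks(
        cfg.io.masks_dir, cfg.io.metadata_csv,
        cfg.segmentation.binarize_threshold,
    )
    if not images:
        raise DataError("features: no mask images found in "
                        f"{cfg.io.masks_dir}")
    cells = []
    for img in images:
        cells.extend(mask_io.segment_cells(
            img, cfg.segmentation.min_area, cfg.segmentation.connectivity,
            cfg.segmentation.border_policy,
        ))
    return images, cells


def stage_features(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    images, cells = _load_and_segment(cfg)
    logger.info("segmented %d cells from %d images", len(cells), len(images))
    if cfg.segmentation.gallery:
        for img in images:
            img_cells = [c for c in cells if c.image_id == img.image_id]
            mask_io.write_cell_gallery(img_cells, out / "gallery" / img.image_id)
    mcfg = morphometry.MorphometryConfig(
        soma_opening_radius=cfg.morphometry.soma_opening_radius,
        sholl_step=cfg.morphometry.sholl_step,
        diagonal_weight=cfg.morphometry.diagonal_weight,
    )
    table, failures = morphometry.features_table(cells, mcfg)
    if table.empty:
        raise DataError("features: no cell produced a feature vector")
    logger.info("extracted features for %d cells (%d excluded)",
                len(table), len(failures))
    table.to_csv(out / "features.csv", index=False)
    if failures:
        pd.DataFrame(failures, columns=["cell_id", "reason"]).to_csv(
            out / "excluded_cells.csv", index=False)
    return table


def stage_select(cfg: PipelineConfig, out: Path,
                 table: pd.DataFrame) -> list[str]:
    if table["group"].nunique() < 2:
        raise DataError("select: need >= 2 groups for supervised selection")
    sel = pipeline_ml.select_features(
        table, target="group", n_keep=cfg.rfe.n_keep, seed=cfg.rfe.seed)
    sel.report().to_csv(out / "selection.csv", index=False)
    logger.info("selected %d / %d features", len(sel.selected_features),
                len(pipeline_ml.feature_columns(table)))
    return sel.selected_features


def stage_embed(cfg: PipelineConfig, out: Path, table: pd.DataFrame,
                selected: list[str]) -> pipeline_ml.Embedding:
    emb = pipeline_ml.embed(
        table, selected,
        n_neighbors=cfg.umap.n_neighbors, min_dist=cfg.umap.min_dist,
        n_components=cfg.umap.n_components, seed=cfg.umap.seed,
        scale=cfg.umap.scale,
    )
    emb.frame().to_csv(out / "embedding.csv", index=False)
    return emb


def stage_cluster(cfg: PipelineConfig, out: Path,
                  emb: pipeline_ml.Embedding) -> pd.Series:
    labels = pipeline_ml.cluster(
        emb, cfg.hdbscan.min_cluster_size, cfg.hdbscan.min_samples)
    labels.reset_index().to_csv(out / "clusters.csv", index=False)
    n_noise = int((labels < 0).sum())
    logger.info("%d clusters, %d noise cells of %d",
                labels[labels >= 0].nunique(), n_noise, len(labels))
    return labels


def stage_spatial(cfg: PipelineConfig, out: Path, table: pd.DataFrame,
                  labels: pd.Series) -> None:
    images, cells = _load_and_segment(cfg)
    featured = set(table["cell_id"])
    cells = [c for c in cells if c.cell_id in featured]
    paint_dir = out / "painted"
    paint_dir.mkdir(exist_ok=True)
    for img in images:
        img_cells = [c for c in cells if c.image_id == img.image_id]
        if not img_cells:
            continue
        rgb = spatial.paint_clusters(img, img_cells, labels)
        iio.imwrite(paint_dir / f"{img.image_id}.png", rgb)
    counts_frames = []
    if cfg.io.annotations_json:
        anns = spatial.load_annotations(cfg.io.annotations_json)
        for img in images:
            if img.image_id not in anns:
                continue
            img_cells = [c for c in cells if c.image_id == img.image_id]
            counts_frames.append(
                spatial.count_by_layer(img_cells, labels, anns[img.image_id]))
    if any(c.lateral_mm is not None for c in cells):
        counts_frames.append(spatial.count_by_lateral_bin(
            cells, labels, cfg.spatial.bin_start, cfg.spatial.bin_width))
    if counts_frames:
        pd.concat(counts_frames, ignore_index=True).to_csv(
            out / "spatial_counts.csv", index=False)

    _write_stats(out, table, labels)


def _write_stats(out: Path, table: pd.DataFrame, labels: pd.Series) -> None:
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    aligned = labels.loc[table["cell_id"]].to_numpy()
    groups = table["group"]
    try:
        ct = stats.contingency(pd.Series(aligned), groups)
    except ValueError as exc:
        logger.warning("association test skipped: %s", exc)
        ct = None
    if ct is not None:
        res = stats.chi_square(ct)
        ct.to_csv(stats_dir / "contingency.csv")
        res.std_residuals.to_csv(stats_dir / "std_residuals.csv")
        res.adjusted_residuals.to_csv(stats_dir / "adjusted_residuals.csv")
        with open(stats_dir / "chi_square.json", "w") as fh:
            json.dump({"statistic": res.statistic, "df": res.df,
                       "p_value": res.p_value}, fh, indent=2)
    for key_name, keys in (("cluster", aligned), ("group", groups)):
        mask = np.asarray(aligned) >= 0
        sub = table.loc[mask]
        hm, bv = stats.cluster_heatmap(sub, np.asarray(keys)[mask])
        hm.to_csv(stats_dir / f"heatmap_by_{key_name}.csv")
        _render_heatmap(hm, stats_dir / f"heatmap_by_{key_name}.png")


def _render_heatmap(hm: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(6, 0.3 * hm.shape[1]), max(3, 0.5 * hm.shape[0])))
    im = ax.imshow(hm.to_numpy(), cmap="coolwarm", aspect="auto",
                   vmin=-2, vmax=2)
    ax.set_xticks(range(hm.shape[1]), hm.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(hm.shape[0]), [str(i) for i in hm.index])
    fig.colorbar(im, ax=ax, label="mean z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig, from_stage: str = "features") -> Path:
    """Execute the pipeline, resuming from ``from_stage`` if its inputs exist.

    Returns the run directory.  Earlier stages' CSV outputs are reloaded
    when resuming; every run rewrites the resolved config and appends to
    ``run.log``.
    """
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage '{from_stage}' (choose from {STAGES})")
    out = Path(cfg.io.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_resolved.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("micromorph")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    start = STAGES.index(from_stage)
    try:
        if start <= STAGES.index("features"):
            table = stage_features(cfg, out)
        else:
            table = pd.read_csv(out / "features.csv")
        if start <= STAGES.index("select"):
            selected = stage_select(cfg, out, table)
        else:
            rep = pd.read_csv(out / "selection.csv")
            selected = rep.loc[rep["selected"], "feature"].tolist()
        if start <= STAGES.index("embed"):
            emb = stage_embed(cfg, out, table, selected)
        else:
            edf = pd.read_csv(out / "embedding.csv")
            coord_cols = [c for c in edf.columns if c.startswith("umap")]
            emb = pipeline_ml.Embedding(
                coords=edf[coord_cols].to_numpy(),
                cell_ids=edf["cell_id"].astype(str).tolist(),
            )
        if start <= STAGES.index("cluster"):
            labels = stage_cluster(cfg, out, emb)
        else:
            cdf = pd.read_csv(out / "clusters.csv")
            labels = cdf.set_index("cell_id")["cluster"]
        stage_spatial(cfg, out, table, labels)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
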