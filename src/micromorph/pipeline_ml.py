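"""Feature selection, embedding and clustering of the morphometric table.

The machine-learning backbone of the pipeline: recursive feature
elimination with a random-forest importance engine keeps the half of the
morphometric features that best separates the study groups; UMAP projects
the selected (z-scored) features to 2-D; HDBSCAN clusters the embedding,
labelling low-density cells as noise (-1).  Noise cells are excluded from
all downstream statistics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.preprocessing import StandardScaler

from .morphometry import FEATURE_NAMES, META_COLUMNS

logger = logging.getLogger(__name__)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table = numeric columns that are not metadata."""
    return [
        c for c in table.columns
        if c not in META_COLUMNS
        and pd.api.types.is_numeric_dtype(table[c])
    ]


@dataclass
class SelectionResult:
    selected_features: list[str]
    importances: pd.Series  # importance per input feature (selected subset fit)
    ranking: pd.Series      # RFE rank per input feature (1 = kept)
    seed: int

    def report(self) -> pd.DataFrame:
        """Selection report: feature, importance, selected flag."""
        return pd.DataFrame(
            {
                "feature": self.importances.index,
                "importance": self.importances.to_numpy(),
                "rank": self.ranking.to_numpy(),
                "selected": [f in self.selected_features
                             for f in self.importances.index],
            }
        )


def select_features(
    table: pd.DataFrame,
    target: str = "group",
    n_keep: int | None = None,
    seed: int = 0,
    n_estimators: int = 100,
) -> SelectionResult:
    """Recursive feature elimination with a random-forest engine.

    Drops the least-important feature one at a time until ``n_keep``
    (default: half of the inputs, rounded up) remain.  Supervised by the
    ``target`` metadata column; deterministic given ``seed``.
    """
    feats = [c for c in feature_columns(table) if c != target]
    if n_keep is None:
        n_keep = math.ceil(len(feats) / 2)
    if n_keep > len(feats):
        raise ValueError(f"n_keep={n_keep} exceeds {len(feats)} features")
    y = table[target].to_numpy()
    levels, counts = np.unique(y, return_counts=True)
    if len(levels) < 2:
        raise ValueError("feature selection is supervised: need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("each group needs >= 2 cells")
    X = table[feats].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rfe = RFE(forest, n_features_to_select=n_keep, step=1)
    rfe.fit(X, y)
    selected = [f for f, kept in zip(feats, rfe.support_) if kept]
    # importances of the final forest, refit on the kept subset by RFE
    imp = np.full(len(feats), np.nan)
    imp[rfe.support_] = rfe.estimator_.feature_importances_
    return SelectionResult(
        selected_features=selected,
        importances=pd.Series(imp, index=feats, name="importance"),
        ranking=pd.Series(rfe.ranking_, index=feats, name="rank"),
        seed=seed,
    )


@dataclass
class Embedding:
    coords: np.ndarray  # (n_cells, n_components)
    cell_ids: list[str]
    params: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        cols = {f"umap{i + 1}": self.coords[:, i]
                for i in range(self.coords.shape[1])}
        return pd.DataFrame({"cell_id": self.cell_ids, **cols})


def embed(
    table: pd.DataFrame,
    features: list[str] | None = None,
    n_neighbors: int = 10,
    min_dist: float = 0.1,
    n_components: int = 2,
    seed: int = 0,
    scale: bool = True,
) -> Embedding:
    """UMAP embedding of the (z-scored) selected features.

    Features are standardized before embedding because they mix units
    (px, degrees, dimensionless ratios); pass ``scale=False`` to skip.
    Fixing ``seed`` forces single-threaded layout, making the coordinates
    bit-for-bit reproducible.
    """
    import umap  # deferred: numba JIT import is slow

    if features is None:
        features = feature_columns(table)
    X = table[features].to_numpy(dtype=float)
    if n_neighbors >= len(X):
        raise ValueError(
            f"n_neighbors={n_neighbors} must be < n_rows={len(X)}"
        )
    if scale:
        X = StandardScaler().fit_transform(X)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs.*random_state.*")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_components=n_components,
            random_state=seed,
            n_jobs=1,
        )
        coords = reducer.fit_transform(X)
    cell_ids = (table["cell_id"].astype(str).tolist()
                if "cell_id" in table.columns else
                [str(i) for i in range(len(X))])
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        cell_ids=cell_ids,
        params={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "n_components": n_components,
            "seed": seed,
            "scaled": scale,
        },
    )


def cluster(
    emb: Embedding,
    min_cluster_size: int = 20,
    min_samples: int = 10,
) -> pd.Series:
    """HDBSCAN clustering of the embedding; noise labelled -1.

    The cluster count is emergent.  Cluster ids are renumbered by
    descending size so cluster 0 is always the largest, keeping reports
    stable across runs.  With fewer points than ``min_cluster_size`` every
    point is noise (a warning is logged).
    """
    n = emb.coords.shape[0]
    if n < min_cluster_size:
        logger.warning(
            "only %d points < min_cluster_size=%d: all labelled noise",
            n, min_cluster_size,
        )
        labels = np.full(n, -1)
    else:
        model = HDBSCAN(min_cluster_size=min_cluster_size,
                        min_samples=min_samples, copy=True)
        labels = model.fit_predict(emb.coords)
        labels = _renumber_by_size(labels)
    return pd.Series(labels, index=pd.Index(emb.cell_ids, name="cell_id"),
                     name="cluster")


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Map cluster ids to 0..K-1 by descending member count (noise fixed)."""
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    if len(ids) == 0:
        return labels.copy()
    # primary key: size descending; tie-break: original id ascending
    order = ids[np.lexsort((ids, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    out = labels.copy()
    for old, new in mapping.items():
        out[labels == old] = new
    return out
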