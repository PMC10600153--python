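"""Per-type cell clustering: sampling, preprocessing, Leiden, extrapolation.

The workflow mirrors the standard single-cell recipe: sample a fraction of
cells per slide, log1p-transform and scale each feature to unit variance,
project onto principal components, build a k-nearest-neighbor graph in the
reduced space and partition it with the Leiden algorithm.  A fitted
:class:`ClusterModel` stores everything needed to extend the clustering to
new cohorts with the reference memberships held fixed, so every new cell
receives one of the existing cluster labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import joblib
import leidenalg as la
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.005        # discovery-cohort per-slide sampling fraction
DEFAULT_EXTRAP_FRACTION = 0.10  # validation-cohort sampling fraction
DEFAULT_RESOLUTION = 1.0
DEFAULT_N_PCS = 50
DEFAULT_N_NEIGHBORS = 15

#: inflammatory clusters summed into the aggregated inflammatory cell score
AIC_CLUSTERS = ("INF0", "INF1", "INF6", "INF7")


def sample_cells(tables: dict[str, pd.DataFrame], fraction: float,
                 seed: int) -> pd.DataFrame:
    """Uniform without-replacement sample of cells per slide, pooled.

    ``tables`` maps slide id -> per-cell feature table.  Every nonempty slide
    contributes at least one cell.  The result carries a ``slide_id`` column
    and a unique (slide, cell) index.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    parts = []
    for slide_id in sorted(tables):
        tab = tables[slide_id]
        if len(tab) == 0:
            continue
        n = max(1, int(round(len(tab) * fraction)))
        take = np.sort(rng.choice(len(tab), size=min(n, len(tab)), replace=False))
        sub = tab.iloc[take].copy()
        sub.insert(0, "slide_id", slide_id)
        sub.index = pd.Index([f"{slide_id}::{i}" for i in sub.index], name="cell_id")
        parts.append(sub)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, axis=0)


@dataclass
class Preprocessor:
    """Stored log1p/scale/PCA parameters, reusable on new data."""

    feature_names: list[str]
    means: np.ndarray
    stds: np.ndarray
    pca: PCA | None
    log_transform: bool = True

    def transform_scaled(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in matrix.columns]
        if missing:
            raise ValueError(f"feature schema mismatch, missing: {missing[:5]}")
        x = matrix[self.feature_names].to_numpy(dtype=float)
        if self.log_transform:
            x = np.log1p(np.clip(x, a_min=-0.999999, a_max=None))
        return (x - self.means) / self.stds

    def transform(self, matrix: pd.DataFrame) -> np.ndarray:
        if self.pca is None:  # fully degenerate input: no informative feature
            return np.zeros((len(matrix), 1))
        return self.pca.transform(self.transform_scaled(matrix))


def preprocess(matrix: pd.DataFrame, n_pcs: int = DEFAULT_N_PCS,
               log_transform: bool = True,
               random_state: int = 0) -> tuple[np.ndarray, Preprocessor]:
    """log1p + per-feature unit-variance scaling + PCA.

    Zero-variance features are dropped with a warning.  Returns the reduced
    matrix and the fitted :class:`Preprocessor`.
    """
    numeric = matrix.select_dtypes(include=[np.number])
    x = numeric.to_numpy(dtype=float)
    if log_transform:
        x = np.log1p(np.clip(x, a_min=-0.999999, a_max=None))
    means = x.mean(axis=0)
    stds = x.std(axis=0)
    keep = stds > 1e-12
    if not keep.all():
        dropped = list(numeric.columns[~keep])
        warnings.warn(f"dropping zero-variance features: {dropped[:10]}")
    features = list(numeric.columns[keep])
    means, stds = means[keep], stds[keep]
    if not features:
        pp = Preprocessor(feature_names=[], means=means, stds=stds, pca=None,
                          log_transform=log_transform)
        return np.zeros((len(matrix), 1)), pp
    scaled = (x[:, keep] - means) / stds
    n_comp = min(n_pcs, scaled.shape[1] - 1 if scaled.shape[1] > 1 else 1,
                 scaled.shape[0])
    pca = PCA(n_components=n_comp, random_state=random_state)
    reduced = pca.fit_transform(scaled)
    pp = Preprocessor(feature_names=features, means=means, stds=stds, pca=pca,
                      log_transform=log_transform)
    return reduced, pp


def _knn_igraph(reduced: np.ndarray, n_neighbors: int) -> ig.Graph:
    """Undirected kNN similarity graph of rows of the reduced matrix."""
    n = reduced.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(reduced)
    _, idx = nn.kneighbors(reduced)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n)
    g.add_edges(sorted(edges))
    return g


@dataclass
class ClusterModel:
    """A fitted per-type clustering: reference data, parameters and labels."""

    cell_type: str
    reference: pd.DataFrame          # raw feature matrix of the reference cells
    preprocessor: Preprocessor
    reduced: np.ndarray              # reference cells in PCA space
    labels: np.ndarray               # per-reference-cell cluster id (int)
    resolution: float
    n_neighbors: int
    seed: int
    label_prefix: str = ""
    slide_ids: pd.Series | None = field(default=None)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cluster_names(self) -> list[str]:
        prefix = self.label_prefix or self.cell_type[:3].upper()
        return [f"{prefix}{i}" for i in range(self.n_clusters)]

    def label_name(self, label: int) -> str:
        prefix = self.label_prefix or self.cell_type[:3].upper()
        return f"{prefix}{int(label)}"

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        return joblib.load(path)


def leiden_cluster(matrix: pd.DataFrame, cell_type: str = "cell",
                   resolution: float = DEFAULT_RESOLUTION,
                   n_pcs: int = DEFAULT_N_PCS,
                   n_neighbors: int = DEFAULT_N_NEIGHBORS,
                   seed: int = 0,
                   label_prefix: str = "") -> ClusterModel:
    """Cluster a pooled per-cell feature matrix; deterministic given seed."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 cells to cluster")
    slide_ids = matrix["slide_id"] if "slide_id" in matrix.columns else None
    feats = matrix.drop(columns=["slide_id", "x", "y"], errors="ignore")
    reduced, pp = preprocess(feats, n_pcs=n_pcs, random_state=seed)
    if np.ptp(reduced) < 1e-12:  # all cells identical: one cluster
        labels = np.zeros(len(feats), dtype=int)
    else:
        g = _knn_igraph(reduced, n_neighbors)
        part = la.find_partition(
            g, la.RBConfigurationVertexPartition,
            resolution_parameter=resolution, seed=seed, n_iterations=-1,
        )
        labels = np.asarray(part.membership, dtype=int)
    logger.info("%s: %d cells -> %d clusters", cell_type, len(matrix),
                labels.max() + 1)
    return ClusterModel(
        cell_type=cell_type, reference=feats, preprocessor=pp, reduced=reduced,
        labels=labels, resolution=resolution, n_neighbors=n_neighbors,
        seed=seed, label_prefix=label_prefix, slide_ids=slide_ids,
    )


def extrapolate_clusters(model: ClusterModel, new_cells: pd.DataFrame,
                         seed: int = 0,
                         use_reference_scaling: bool = False) -> np.ndarray:
    """Assign model clusters to new cells with reference memberships fixed.

    Reference and new cells are concatenated, the reduced space is recomputed
    on the joint matrix, and Leiden runs with the reference labels frozen; new
    cells start from random initial clusters.  Any new cell that ends in a
    community containing no reference cell is reassigned to the cluster with
    the nearest centroid in the joint reduced space, so the returned labels
    are always drawn from the model's clusters.

    With ``use_reference_scaling`` the new cohort is scaled with the
    reference cohort's stored parameters instead of its own statistics.
    """
    feats_new = new_cells.drop(columns=["slide_id", "x", "y"], errors="ignore")
    missing = [f for f in model.preprocessor.feature_names
               if f not in feats_new.columns]
    if missing:
        raise ValueError(f"feature schema mismatch, missing: {missing[:5]}")
    if len(feats_new) == 0:
        return np.empty(0, dtype=int)

    ref_scaled = model.preprocessor.transform_scaled(model.reference)
    if use_reference_scaling:
        new_scaled = model.preprocessor.transform_scaled(feats_new)
    else:
        x = feats_new[model.preprocessor.feature_names].to_numpy(dtype=float)
        if model.preprocessor.log_transform:
            x = np.log1p(np.clip(x, a_min=-0.999999, a_max=None))
        stds = x.std(axis=0)
        stds[stds <= 1e-12] = 1.0
        new_scaled = (x - x.mean(axis=0)) / stds
    joint = np.vstack([ref_scaled, new_scaled])
    n_comp = model.preprocessor.pca.n_components_
    pca = PCA(n_components=min(n_comp, joint.shape[1], joint.shape[0]),
              random_state=seed)
    joint_reduced = pca.fit_transform(joint)

    n_ref = len(model.reference)
    if np.ptp(joint_reduced) < 1e-12 or model.n_clusters == 1:
        return np.zeros(len(feats_new), dtype=int)
    g = _knn_igraph(joint_reduced, model.n_neighbors)
    rng = np.random.default_rng(seed)
    init = np.concatenate([
        model.labels,
        rng.integers(0, model.n_clusters, size=len(feats_new)),
    ]).tolist()
    part = la.RBConfigurationVertexPartition(
        g, initial_membership=init, resolution_parameter=model.resolution)
    opt = la.Optimiser()
    opt.set_rng_seed(seed)
    is_fixed = [True] * n_ref + [False] * len(feats_new)
    opt.optimise_partition(part, is_membership_fixed=is_fixed, n_iterations=-1)
    labels = np.asarray(part.membership[n_ref:], dtype=int)

    # fall back to nearest reference-cluster centroid for any novel community
    novel = labels >= model.n_clusters
    if novel.any():
        centroids = np.vstack([
            joint_reduced[:n_ref][model.labels == c].mean(axis=0)
            for c in range(model.n_clusters)
        ])
        pts = joint_reduced[n_ref:][novel]
        d = np.linalg.norm(pts[:, None, :] - centroids[None, :, :], axis=2)
        labels[novel] = d.argmin(axis=1)
        logger.info("reassigned %d cells from novel communities", int(novel.sum()))
    return labels


def cluster_abundance(labels: pd.Series, sample_ids: pd.Series,
                      cluster_names: list[str] | None = None) -> pd.DataFrame:
    """Within-type fractional cluster abundance per sample (rows sum to 1)."""
    df = pd.DataFrame({"sample": sample_ids.values, "cluster": labels.values})
    counts = df.groupby(["sample", "cluster"]).size().unstack(fill_value=0)
    if cluster_names is not None:
        counts = counts.reindex(columns=cluster_names, fill_value=0)
    totals = counts.sum(axis=1)
    abundance = counts.div(totals, axis=0)
    abundance[totals == 0] = np.nan
    return abundance


def aic_score(abundance: pd.DataFrame | pd.Series,
              clusters: tuple[str, ...] = AIC_CLUSTERS) -> pd.Series | float:
    """Aggregated inflammatory cell abundance score.

    The sum of the abundances of the locally aggregated inflammatory-cell
    clusters (by default INF0 + INF1 + INF6 + INF7).  Missing clusters
    contribute 0; a sample with undefined abundances yields NaN.
    """
    if isinstance(abundance, pd.Series):
        return float(sum(abundance.get(c, 0.0) for c in clusters))
    present = [c for c in clusters if c in abundance.columns]
    score = abundance[present].sum(axis=1, min_count=1) if present else pd.Series(
        0.0, index=abundance.index)
    score.name = "AIC"
    return score
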