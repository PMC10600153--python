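"""Spot tessellation, spatial correlation, micro-ecological modules, Moran's I.

A slide is tessellated into non-overlapping square spots (default side
200 um), each characterized by its per-cluster cell counts.  Pairwise
colocalization of cell clusters is measured with a multivariate extension
of Moran's autocorrelation:

    C = (N_s / W) * sum_ij w_ij (x_i - xbar)(y_j - ybar)
        / ( sqrt(sum (x - xbar)^2) * sqrt(sum (y - ybar)^2) )

with binary rook-adjacency weights (a spot's up-to-four orthogonal grid
neighbors).  Micro-ecological modules (MEMs) are groups of clusters found
by Ward hierarchical clustering of the cohort-mean correlation matrix.
Per-spot module scores are cell fractions; spots are assigned to their
argmax module, with empty spots labelled Module0_NC.  The univariate
special case (x = y) is Moran's I, used to characterize each module's
spatial pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .nuclei_io import NucleusSet

DEFAULT_SPOT_UM = 200.0
DEFAULT_N_MODULES = 8
MODULE0 = "Module0_NC"


@dataclass
class SpotMatrix:
    """Spot-grid x cell-cluster count matrix of one slide.

    ``counts`` is indexed by (row, col) grid coordinates; columns are
    cluster names.  ``spot_px`` is the spot side length in pixels.
    """

    slide_id: str
    counts: pd.DataFrame
    spot_px: float
    mpp: float

    @property
    def n_spots(self) -> int:
        return len(self.counts)

    @property
    def clusters(self) -> list[str]:
        return list(self.counts.columns)

    def spot_centers(self) -> np.ndarray:
        """(n, 2) array of spot center (x, y) in pixels."""
        rc = np.asarray(list(self.counts.index), dtype=float)
        return np.column_stack([
            (rc[:, 1] + 0.5) * self.spot_px,  # col -> x
            (rc[:, 0] + 0.5) * self.spot_px,  # row -> y
        ])


def tessellate(ns: NucleusSet, cluster_labels: pd.Series,
               spot_um: float = DEFAULT_SPOT_UM,
               clusters: list[str] | None = None) -> SpotMatrix:
    """Assign every labelled cell to a square spot and tally cluster counts.

    A cell at pixel (x, y) falls in spot (floor(y/s), floor(x/s)) with
    s = spot_um / mpp; intervals are half-open, so a cell exactly on a
    boundary belongs to the higher-index spot.  Only spots containing at
    least one cell get a row; the full occupied bounding grid (including
    empty spots) is materialized by :func:`occupied_grid`.
    """
    if spot_um <= 0:
        raise ValueError("spot_um must be > 0")
    s = spot_um / ns.mpp
    labels = cluster_labels
    missing = [i for i in ns.ids if i not in labels.index]
    if missing:
        raise ValueError(f"cells without cluster label: {missing[:5]}")
    xy = ns.centroids
    rows = np.floor(xy[:, 1] / s).astype(int)
    cols = np.floor(xy[:, 0] / s).astype(int)
    df = pd.DataFrame({
        "row": rows, "col": cols,
        "cluster": [labels[i] for i in ns.ids],
    })
    counts = df.groupby(["row", "col"])["cluster"].value_counts().unstack(fill_value=0)
    if clusters is not None:
        counts = counts.reindex(columns=clusters, fill_value=0)
    return SpotMatrix(slide_id=ns.slide_id, counts=counts, spot_px=s, mpp=ns.mpp)


def occupied_grid(sm: SpotMatrix) -> pd.DataFrame:
    """Counts on the full bounding grid of occupied spots (empty rows zero)."""
    if sm.n_spots == 0:
        return sm.counts
    rows = [r for r, _ in sm.counts.index]
    cols = [c for _, c in sm.counts.index]
    full = pd.MultiIndex.from_product(
        [range(min(rows), max(rows) + 1), range(min(cols), max(cols) + 1)],
        names=["row", "col"])
    return sm.counts.reindex(full, fill_value=0)


@dataclass
class SpatialWeights:
    """Binary spot-pair weights; rook adjacency on the grid by default."""

    matrix: np.ndarray  # (n, n) 0/1, zero diagonal
    scheme: str = "rook"

    @property
    def total(self) -> float:
        return float(self.matrix.sum())


def rook_weights(index: pd.MultiIndex) -> SpatialWeights:
    """w_ij = 1 iff spots i, j are orthogonal grid neighbors (rook scheme)."""
    pos = {rc: i for i, rc in enumerate(index)}
    n = len(index)
    w = np.zeros((n, n))
    for (r, c), i in pos.items():
        for dr, dc in ((0, 1), (1, 0)):
            j = pos.get((r + dr, c + dc))
            if j is not None:
                w[i, j] = w[j, i] = 1.0
    return SpatialWeights(matrix=w, scheme="rook")


def knn_weights(centers: np.ndarray, k: int = 4) -> SpatialWeights:
    """w_ij = 1 iff spot j is among the k nearest spot centers of spot i."""
    from scipy.spatial import cKDTree
    n = len(centers)
    w = np.zeros((n, n))
    if n > 1:
        tree = cKDTree(centers)
        _, idx = tree.query(centers, k=min(k + 1, n))
        for i in range(n):
            for j in np.atleast_1d(idx[i])[1:]:
                w[i, int(j)] = 1.0
    return SpatialWeights(matrix=w, scheme=f"knn{k}")


def spatial_correlation(x: np.ndarray, y: np.ndarray,
                        w: SpatialWeights) -> tuple[float, bool]:
    """Multivariate spatial correlation between two spot fields.

    Returns (C, degenerate): C is 0 and the flag True when either field has
    zero variance or the weights sum to zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 2 or w.total == 0:
        return 0.0, True
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx ** 2).sum())
    sy = np.sqrt((dy ** 2).sum())
    if sx <= 1e-300 or sy <= 1e-300:
        return 0.0, True
    num = float(dx @ w.matrix @ dy)
    return (n / w.total) * num / (sx * sy), False


def morans_i(x: np.ndarray, w: SpatialWeights) -> tuple[float, bool]:
    """Univariate Moran's I of a spot field; (0, True) when degenerate."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or w.total == 0:
        return 0.0, True
    dx = x - x.mean()
    s2 = float((dx ** 2).sum())
    if s2 <= 1e-300:
        return 0.0, True
    return (n / w.total) * float(dx @ w.matrix @ dx) / s2, False


def correlation_matrix(sm: SpotMatrix, weights: SpatialWeights | None = None,
                       include_empty: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x cluster spatial correlation matrix of one slide.

    Returns (C, degenerate_flags).  By default the field includes the empty
    spots of the occupied bounding grid, so absence of cells is informative.
    """
    counts = occupied_grid(sm) if include_empty else sm.counts
    if weights is None:
        weights = rook_weights(counts.index)
    clusters = list(counts.columns)
    k = len(clusters)
    C = np.zeros((k, k))
    flags = np.zeros((k, k), dtype=bool)
    fields = {c: counts[c].to_numpy(dtype=float) for c in clusters}
    for a in range(k):
        for b in range(k):
            C[a, b], flags[a, b] = spatial_correlation(
                fields[clusters[a]], fields[clusters[b]], weights)
    return (pd.DataFrame(C, index=clusters, columns=clusters),
            pd.DataFrame(flags, index=clusters, columns=clusters))


@dataclass
class MEMModel:
    """Fitted cluster -> micro-ecological-module map."""

    mean_correlation: pd.DataFrame
    linkage_matrix: np.ndarray
    module_of: dict[str, str]        # cluster name -> module name
    n_modules: int
    module_names: list[str] = field(default_factory=list)

    @property
    def clusters(self) -> list[str]:
        return list(self.mean_correlation.index)

    def module_clusters(self, module: str) -> list[str]:
        return [c for c, m in self.module_of.items() if m == module]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "MEMModel":
        return joblib.load(path)


def build_mem_model(matrices: list[tuple[pd.DataFrame, pd.DataFrame]],
                    n_modules: int = DEFAULT_N_MODULES) -> MEMModel:
    """Ward-cluster the cohort-mean spatial correlation matrix into modules.

    ``matrices`` holds per-sample (correlation, degenerate-flag) pairs;
    degenerate entries are ignored in the mean.  The mean matrix is
    symmetrized and clustered on its rows (Ward linkage); the tree is cut
    into ``n_modules`` groups named Module1..ModuleN, ordered by first
    cluster appearance.
    """
    if not matrices:
        raise ValueError("need at least one per-sample correlation matrix")
    clusters = list(matrices[0][0].index)
    stack = np.stack([m.to_numpy(dtype=float) for m, _ in matrices])
    valid = ~np.stack([f.to_numpy(dtype=bool) for _, f in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(valid, stack, np.nan)
        mean = np.nanmean(mean, axis=0)
    bad = np.argwhere(~np.isfinite(mean))
    if len(bad):
        pairs = [(clusters[i], clusters[j]) for i, j in bad[:5]]
        raise ValueError(f"all samples degenerate for cluster pairs: {pairs}")
    mean = (mean + mean.T) / 2.0
    n_modules = min(n_modules, len(clusters))
    Z = linkage(mean, method="ward")
    cut = fcluster(Z, t=n_modules, criterion="maxclust")
    # stable module names: Module1 = module of the first cluster, etc.
    seen: dict[int, str] = {}
    module_of = {}
    for cl, g in zip(clusters, cut):
        if g not in seen:
            seen[g] = f"Module{len(seen) + 1}"
        module_of[cl] = seen[g]
    mean_df = pd.DataFrame(mean, index=clusters, columns=clusters)
    return MEMModel(mean_correlation=mean_df, linkage_matrix=Z,
                    module_of=module_of, n_modules=len(seen),
                    module_names=sorted(set(module_of.values()),
                                        key=lambda m: int(m.removeprefix("Module"))))


def score_spots(sm: SpotMatrix, mm: MEMModel,
                include_empty: bool = True) -> pd.DataFrame:
    """Per-spot module scores and argmax module assignment.

    The score of a module is the fraction of the spot's cells whose cluster
    belongs to it (scores over modules sum to 1 for nonempty spots).
    Zero-cell spots are assigned Module0_NC.  Ties at the argmax break
    toward the lower module index.
    """
    unknown = [c for c in sm.clusters if c not in mm.module_of]
    if unknown:
        raise ValueError(f"spot clusters not in MEM model: {unknown[:5]}")
    counts = occupied_grid(sm) if include_empty else sm.counts
    totals = counts.sum(axis=1)
    scores = pd.DataFrame(0.0, index=counts.index, columns=mm.module_names)
    for mod in mm.module_names:
        cols = [c for c in mm.module_clusters(mod) if c in counts.columns]
        if cols:
            scores[mod] = counts[cols].sum(axis=1) / totals.replace(0, np.nan)
    scores = scores.fillna(0.0)
    assignment = scores.idxmax(axis=1)
    assignment[totals == 0] = MODULE0
    out = scores.copy()
    out["n_cells"] = totals
    out["module"] = assignment
    return out


def module_morans_i(scored: pd.DataFrame, mm: MEMModel,
                    weights: SpatialWeights | None = None) -> pd.Series:
    """Moran's I of each module-score field over the spot grid."""
    if weights is None:
        weights = rook_weights(scored.index)
    out = {}
    for mod in mm.module_names:
        value, degenerate = morans_i(scored[mod].to_numpy(dtype=float), weights)
        out[mod] = np.nan if degenerate else value
    return pd.Series(out, name="morans_i")


def mem_variation(assignments: pd.Series,
                  proportions: pd.DataFrame) -> pd.DataFrame:
    """Intra- and inter-module variation of per-spot cell-type proportions.

    Intra = mean over modules of the population SD of a cell type's spot
    proportion within the module; inter = population SD over modules of the
    within-module mean proportion.  Module0_NC spots are excluded; modules
    with a single spot contribute SD 0 with a warning.
    """
    keep = assignments != MODULE0
    assignments = assignments[keep]
    proportions = proportions.loc[assignments.index]
    modules = sorted(assignments.unique())
    if not modules:
        raise ValueError("no classified spots")
    rows = {}
    for ctype in proportions.columns:
        intra_parts, means = [], []
        for mod in modules:
            vals = proportions.loc[assignments == mod, ctype].to_numpy(dtype=float)
            if len(vals) < 2:
                warnings.warn(f"module {mod}: fewer than 2 spots, SD set to 0")
                intra_parts.append(0.0)
            else:
                intra_parts.append(float(vals.std(ddof=0)))
            means.append(float(vals.mean()))
        rows[ctype] = {
            "intra": float(np.mean(intra_parts)),
            "inter": float(np.std(means, ddof=0)),
        }
    return pd.DataFrame(rows).T
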