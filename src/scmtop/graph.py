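"""Multilevel pairwise cell graphs and per-cell topological features.

For each ordered pair of profiled cell types (tumor, inflammatory, stroma),
a k-nearest-neighbor graph is built: every cell of one type is connected to
its k nearest cells of the partner type (within-type kNN when the types
coincide), edges longer than a pixel threshold are deleted, and the result
is undirected-deduplicated.  Defaults follow the standard construction:
k = 5 and threshold = 100 px (25 um at 0.25 um/px); the distance test is
strict (an edge of exactly the threshold length is deleted).

Topological features are computed per graph and concatenated with a graph
label prefix (e.g. ``T-I_Degrees``).  Isolated cells carry the sentinel
conventions: Min/MeanEdgeLength = threshold, Closeness = 0,
ClusteringCoefficient = 0.  Heterotypic graphs carry no
ClusteringCoefficient column (it is uninformative there by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .nuclei_io import CellType, NucleusSet, PROFILED_TYPES

DEFAULT_K = 5
DEFAULT_THRESHOLD_PX = 100.0

_TYPE_LETTER = {CellType.TUMOR: "T", CellType.INFLAMMATORY: "I", CellType.STROMA: "S"}

#: the six graph labels in canonical order
GRAPH_LABELS = ("T-T", "I-I", "S-S", "T-I", "T-S", "I-S")
#: graph label -> (type1, type2)
GRAPH_TYPES = {
    "T-T": (CellType.TUMOR, CellType.TUMOR),
    "I-I": (CellType.INFLAMMATORY, CellType.INFLAMMATORY),
    "S-S": (CellType.STROMA, CellType.STROMA),
    "T-I": (CellType.TUMOR, CellType.INFLAMMATORY),
    "T-S": (CellType.TUMOR, CellType.STROMA),
    "I-S": (CellType.INFLAMMATORY, CellType.STROMA),
}

TOPO_FEATURE_NAMES = [
    "Nsubgraph", "MinEdgeLength", "MeanEdgeLength", "Degrees", "Coreness",
    "Eccentricity", "Eccentricity_normed", "HarmonicCentrality", "Closeness",
    "Betweenness", "Betweenness_normed", "ClusteringCoefficient",
]


@dataclass
class EdgeSet:
    """One pairwise cell graph: typed, undirected, length-annotated edges."""

    graph_label: str
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    k: int = DEFAULT_K
    threshold_px: float = DEFAULT_THRESHOLD_PX

    @property
    def is_homotypic(self) -> bool:
        c1, c2 = GRAPH_TYPES[self.graph_label]
        return c1 == c2

    def __len__(self) -> int:
        return len(self.edges)


def graph_label(c1: CellType, c2: CellType) -> str:
    return f"{_TYPE_LETTER[c1]}-{_TYPE_LETTER[c2]}"


def _knn_candidates(src_xy: np.ndarray, src_ids: list[str],
                    dst_xy: np.ndarray, dst_ids: list[str],
                    k: int, same: bool) -> set[tuple[str, str, float]]:
    """Directed kNN edges src -> dst; ties broken by destination id order."""
    out: set[tuple[str, str, float]] = set()
    if len(dst_ids) == 0 or len(src_ids) == 0:
        return out
    n_query = k + 1 if same else k
    n_query = min(n_query, len(dst_ids))
    tree = cKDTree(dst_xy)
    dists, idxs = tree.query(src_xy, k=n_query)
    dists = np.atleast_2d(dists)
    idxs = np.atleast_2d(idxs)
    for si, sid in enumerate(src_ids):
        cands = []
        for d, j in zip(dists[si], idxs[si]):
            did = dst_ids[int(j)]
            if same and did == sid:
                continue
            cands.append((float(d), did))
        cands.sort(key=lambda t: (t[0], t[1]))
        for d, did in cands[:k]:
            out.add((sid, did, d))
    return out


def build_pairwise_graph(ns: NucleusSet, c1: CellType | str, c2: CellType | str,
                         k: int = DEFAULT_K,
                         threshold_px: float = DEFAULT_THRESHOLD_PX) -> EdgeSet:
    """Build the undirected kNN graph between cell types c1 and c2.

    Directed candidates run both ways (each cell of one type to its k nearest
    of the partner type), are filtered at ``distance < threshold_px``, then
    deduplicated as unordered pairs.
    """
    c1 = CellType(c1)
    c2 = CellType(c2)
    for c in (c1, c2):
        if c not in PROFILED_TYPES:
            raise ValueError(f"cell type {c} is not profiled in graphs")
    if k < 1:
        raise ValueError("k must be >= 1")
    if threshold_px <= 0:
        raise ValueError("threshold_px must be > 0")
    label = graph_label(c1, c2)

    set1 = ns.subset([c1])
    ids1, xy1 = set1.ids, set1.centroids
    if c1 == c2:
        directed = _knn_candidates(xy1, ids1, xy1, ids1, k, same=True)
    else:
        set2 = ns.subset([c2])
        ids2, xy2 = set2.ids, set2.centroids
        directed = _knn_candidates(xy1, ids1, xy2, ids2, k, same=False)
        directed |= {(b, a, d) for a, b, d in
                     _knn_candidates(xy2, ids2, xy1, ids1, k, same=False)}

    undirected: dict[tuple[str, str], float] = {}
    for a, b, d in directed:
        if d < threshold_px:
            key = (a, b) if a <= b else (b, a)
            undirected[key] = d
    edges = sorted((a, b, d) for (a, b), d in undirected.items())
    return EdgeSet(graph_label=label, edges=edges, k=k, threshold_px=threshold_px)


def build_all_graphs(ns: NucleusSet, k: int = DEFAULT_K,
                     threshold_px: float = DEFAULT_THRESHOLD_PX) -> dict[str, EdgeSet]:
    """All six pairwise graphs of a slide, keyed by graph label."""
    return {
        lab: build_pairwise_graph(ns, *GRAPH_TYPES[lab], k=k, threshold_px=threshold_px)
        for lab in GRAPH_LABELS
    }


def compute_topology(es: EdgeSet, ns: NucleusSet) -> pd.DataFrame:
    """Per-cell topological features for one graph.

    Rows cover every cell of the graph's type(s), including isolated ones.
    Columns are unprefixed feature names; :func:`assemble_cell_features`
    applies the graph-label prefix.
    """
    c1, c2 = GRAPH_TYPES[es.graph_label]
    members = ns.subset([c1] if c1 == c2 else [c1, c2])
    ids = members.ids
    idx = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)

    g = ig.Graph(n=n)
    if es.edges:
        g.add_edges([(idx[a], idx[b]) for a, b, _ in es.edges])
    lengths_by_vertex: list[list[float]] = [[] for _ in range(n)]
    for a, b, d in es.edges:
        lengths_by_vertex[idx[a]].append(d)
        lengths_by_vertex[idx[b]].append(d)

    comps = g.connected_components()
    membership = comps.membership
    comp_sizes = [len(c) for c in comps]
    degrees = g.degree()
    coreness = g.coreness()
    betweenness = g.betweenness()
    transitivity = g.transitivity_local_undirected(mode="zero")

    # component-wise eccentricity / diameter / closeness / harmonic
    ecc = np.zeros(n)
    ecc_normed = np.zeros(n)
    closeness = np.zeros(n)
    harmonic = np.zeros(n)
    for comp in comps:
        nc = len(comp)
        if nc == 1:
            continue
        sub = g.induced_subgraph(comp)
        d = np.asarray(sub.distances(), dtype=float)
        e = d.max(axis=1)
        diam = float(e.max())
        for local, vertex in enumerate(comp):
            ecc[vertex] = e[local]
            ecc_normed[vertex] = e[local] / diam if diam > 0 else 0.0
            row = np.delete(d[local], local)
            closeness[vertex] = (nc - 1) / row.sum()
            harmonic[vertex] = float((1.0 / row).sum()) / (nc - 1)

    rows = {}
    for nid, i in idx.items():
        nc = comp_sizes[membership[i]]
        incident = lengths_by_vertex[i]
        if incident:
            min_len, mean_len = float(np.min(incident)), float(np.mean(incident))
        else:
            min_len = mean_len = es.threshold_px  # isolated-cell sentinel
        b_norm = betweenness[i] / ((nc - 1) * (nc - 2) / 2.0) if nc >= 3 else 0.0
        row = {
            "Nsubgraph": nc,
            "MinEdgeLength": min_len,
            "MeanEdgeLength": mean_len,
            "Degrees": degrees[i],
            "Coreness": coreness[i],
            "Eccentricity": float(ecc[i]),
            "Eccentricity_normed": float(ecc_normed[i]),
            "HarmonicCentrality": float(harmonic[i]),
            "Closeness": float(closeness[i]),
            "Betweenness": float(betweenness[i]),
            "Betweenness_normed": float(b_norm),
        }
        if es.is_homotypic:
            row["ClusteringCoefficient"] = float(transitivity[i])
        rows[nid] = row
    columns = [c for c in TOPO_FEATURE_NAMES
               if es.is_homotypic or c != "ClusteringCoefficient"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


@dataclass
class StromaBlockerConfig:
    """Parameters of the stromal-barrier feature (a configurable reconstruction).

    For each inflammatory cell, the straight segments to its ``k_tumor``
    nearest tumor cells within ``radius_px`` are examined; the feature is the
    mean number of stroma centroids within ``corridor_halfwidth_px`` of a
    segment (0 when no tumor cell is in range).
    """

    k_tumor: int = 5
    radius_px: float = 300.0
    corridor_halfwidth_px: float = 15.0


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def compute_stroma_blocker(ns: NucleusSet,
                           config: StromaBlockerConfig | None = None) -> pd.Series:
    """StromaBlocker value for every inflammatory cell of the slide."""
    cfg = config or StromaBlockerConfig()
    inf = ns.subset([CellType.INFLAMMATORY])
    tum = ns.subset([CellType.TUMOR])
    str_xy = ns.subset([CellType.STROMA]).centroids
    values = pd.Series(0.0, index=pd.Index(inf.ids, name="cell_id"), name="StromaBlocker")
    if len(inf) == 0 or len(tum) == 0:
        return values
    tree = cKDTree(tum.centroids)
    kq = min(cfg.k_tumor, len(tum))
    dists, idxs = tree.query(inf.centroids, k=kq)
    dists = np.atleast_2d(dists)
    idxs = np.atleast_2d(idxs)
    for i, nid in enumerate(inf.ids):
        a = inf.centroids[i]
        counts = []
        for d, j in zip(dists[i], idxs[i]):
            if d > cfg.radius_px:
                continue
            if len(str_xy) == 0:
                counts.append(0)
                continue
            b = tum.centroids[int(j)]
            near = _point_segment_distance(str_xy, a, b) <= cfg.corridor_halfwidth_px
            counts.append(int(near.sum()))
        values[nid] = float(np.mean(counts)) if counts else 0.0
    return values


#: graphs each profiled type appears in
TYPE_GRAPHS = {
    CellType.TUMOR: ("T-T", "T-I", "T-S"),
    CellType.INFLAMMATORY: ("I-I", "T-I", "I-S"),
    CellType.STROMA: ("S-S", "T-S", "I-S"),
}


def assemble_cell_features(ns: NucleusSet, edge_sets: dict[str, EdgeSet],
                           morphology: pd.DataFrame,
                           texture: pd.DataFrame | None = None,
                           blocker_config: StromaBlockerConfig | None = None,
                           ) -> dict[str, pd.DataFrame]:
    """Concatenate morphology, texture and graph-prefixed topology per cell.

    Returns one table per profiled type ("tumor"/"inflammatory"/"stroma").
    Each cell carries the topology of the three graphs its type appears in
    (tumor: T-T/T-I/T-S; inflammatory: I-I/T-I/I-S; stroma: S-S/T-S/I-S);
    inflammatory cells additionally carry StromaBlocker.
    """
    unknown = [i for i in morphology.index if i not in ns]
    if unknown:
        raise ValueError(f"morphology rows reference unknown nuclei: {unknown[:5]}")
    topo_by_label = {}
    for lab in GRAPH_LABELS:
        topo = compute_topology(edge_sets[lab], ns)
        topo.columns = [f"{lab}_{c}" for c in topo.columns]
        topo_by_label[lab] = topo
    out: dict[str, pd.DataFrame] = {}
    for ctype in PROFILED_TYPES:
        ids = ns.subset([ctype]).ids
        parts = [morphology.loc[[i for i in ids if i in morphology.index]]]
        if texture is not None:
            parts.append(texture.reindex(parts[0].index))
        for lab in TYPE_GRAPHS[ctype]:
            parts.append(topo_by_label[lab].reindex(parts[0].index))
        table = pd.concat(parts, axis=1)
        if ctype is CellType.INFLAMMATORY:
            blocker = compute_stroma_blocker(ns, blocker_config)
            table["StromaBlocker"] = blocker.reindex(table.index)
        table.index.name = "cell_id"
        out[ctype.value] = table
    return out
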