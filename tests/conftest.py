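"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from scmtop.nuclei_io import CellType, Nucleus, NucleusSet


def make_nucleus(nid: str, x: float, y: float, cell_type: CellType,
                 r: float = 3.0) -> Nucleus:
    """A small triangular nucleus centred at (x, y)."""
    contour = ((x - r, y - r), (x + r, y - r), (x, y + r))
    return Nucleus(id=nid, centroid=(x, y), contour=contour,
                   bbox=(x - r, y - r, x + r, y + r), cell_type=cell_type)


def random_nucleus_set(rng: np.random.Generator, n: int, size_px: float = 1000.0,
                       types=(CellType.TUMOR, CellType.INFLAMMATORY, CellType.STROMA),
                       slide_id: str = "rand") -> NucleusSet:
    """n nuclei with uniform centroids and uniform-random profiled types."""
    xy = rng.uniform(4, size_px - 4, size=(n, 2))
    tcodes = rng.integers(0, len(types), size=n)
    nuclei = [make_nucleus(str(i), float(xy[i, 0]), float(xy[i, 1]),
                           types[tcodes[i]]) for i in range(n)]
    return NucleusSet(slide_id, nuclei)


def brute_force_pairwise_edges(ns: NucleusSet, c1: CellType, c2: CellType,
                               k: int, threshold: float) -> set[tuple[str, str]]:
    """O(n^2) oracle for the typed kNN graph: exhaustive distance sort,
    k nearest partner-type cells per cell in both directions, strict
    threshold filter, undirected dedup."""
    cells1 = [n for n in ns if n.cell_type == c1]
    cells2 = [n for n in ns if n.cell_type == c2]

    def knn_edges(src, dst):
        out = set()
        for a in src:
            cands = []
            for b in dst:
                if b.id == a.id:
                    continue
                d = float(np.hypot(a.centroid[0] - b.centroid[0],
                                   a.centroid[1] - b.centroid[1]))
                cands.append((d, b.id))
            cands.sort()
            for d, bid in cands[:k]:
                if d < threshold:
                    out.add(tuple(sorted((a.id, bid))))
        return out

    return knn_edges(cells1, cells2) | knn_edges(cells2, cells1)


def brute_force_glcm(patch: np.ndarray, mask: np.ndarray, levels: int,
                     offset: tuple[int, int]) -> np.ndarray:
    """Exhaustive pair-counting co-occurrence tabulation (symmetric,
    normalized), restricted to pairs with both pixels inside the mask."""
    q = (patch.astype(np.int64) * levels) // 256
    q = np.clip(q, 0, levels - 1)
    h, w = patch.shape
    dy, dx = offset
    m = np.zeros((levels, levels))
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                m[q[y, x], q[y2, x2]] += 1
    m = m + m.T
    return m / m.sum() if m.sum() else m


def brute_force_morans_i(x: np.ndarray, w: np.ndarray) -> float:
    """Double-loop evaluation of Moran's I."""
    n = len(x)
    xbar = x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
    den = float(((x - xbar) ** 2).sum())
    return (n / w.sum()) * num / den


def brute_force_spatial_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Double-loop evaluation of the multivariate spatial correlation."""
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (y[j] - ybar)
    den = np.sqrt(((x - xbar) ** 2).sum()) * np.sqrt(((y - ybar) ** 2).sum())
    return (n / w.sum()) * num / den


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
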