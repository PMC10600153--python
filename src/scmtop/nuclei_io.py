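"""Data model for segmented nuclei and slide-level I/O.

The input dialect is the per-nucleus JSON record map emitted by nuclear
segmentation networks such as HoVer-Net: each record carries a bounding box,
a centroid, a contour polygon and an integer type code.  Type codes follow
the PanNuke five-class taxonomy:

    1 -> tumor (neoplastic)       2 -> inflammatory
    3 -> stroma (connective)      4 -> dead (necrotic)
    5 -> normal (non-neoplastic epithelial)
    0 -> unlabelled, dropped with a warning

Coordinates are 0-based pixels, x rightward, y downward; all distances are
Euclidean in pixels.  The default resolution is 0.25 micron/pixel so that
100 px corresponds to 25 um.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DEFAULT_MPP = 0.25


class CellType(str, Enum):
    """Five-class nuclear taxonomy."""

    TUMOR = "tumor"
    INFLAMMATORY = "inflammatory"
    STROMA = "stroma"
    NORMAL = "normal"
    DEAD = "dead"

    def __str__(self) -> str:  # keep table cells plain
        return self.value


#: PanNuke integer code -> cell type (0 = unlabelled, dropped).
TYPE_CODE_MAP = {
    1: CellType.TUMOR,
    2: CellType.INFLAMMATORY,
    3: CellType.STROMA,
    4: CellType.DEAD,
    5: CellType.NORMAL,
}
TYPE_TO_CODE = {v: k for k, v in TYPE_CODE_MAP.items()}

#: Types that enter graphs and feature profiling.
PROFILED_TYPES = (CellType.TUMOR, CellType.INFLAMMATORY, CellType.STROMA)
#: Types retained in composition summaries (dead excluded).
COMPOSITION_TYPES = PROFILED_TYPES + (CellType.NORMAL,)


class SegmentationError(ValueError):
    """Raised for malformed or inconsistent segmentation records."""


@dataclass(frozen=True)
class Nucleus:
    """One segmented nucleus."""

    id: str
    centroid: tuple[float, float]
    contour: tuple[tuple[float, float], ...]
    bbox: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    cell_type: CellType

    def __post_init__(self) -> None:
        if len(self.contour) < 3:
            raise SegmentationError(
                f"nucleus {self.id!r}: contour needs >= 3 vertices, got {len(self.contour)}"
            )
        xmin, ymin, xmax, ymax = self.bbox
        xs = [p[0] for p in self.contour]
        ys = [p[1] for p in self.contour]
        if min(xs) < xmin or max(xs) > xmax or min(ys) < ymin or max(ys) > ymax:
            raise SegmentationError(f"nucleus {self.id!r}: bbox does not contain contour")
        cx, cy = self.centroid
        if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
            raise SegmentationError(f"nucleus {self.id!r}: centroid outside bbox")


class NucleusSet:
    """All nuclei of one slide plus slide metadata.

    Provides vectorized access to centroids/types and exact k-nearest-neighbor
    queries by Euclidean centroid distance (KD-tree backed; results match an
    exhaustive distance sort, ties broken by insertion order of ids).
    """

    def __init__(self, slide_id: str, nuclei: Iterable[Nucleus], mpp: float = DEFAULT_MPP):
        if mpp <= 0:
            raise ValueError(f"mpp must be > 0, got {mpp}")
        self.slide_id = slide_id
        self.mpp = float(mpp)
        self.nuclei: list[Nucleus] = list(nuclei)
        ids = [n.id for n in self.nuclei]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise SegmentationError(
                f"duplicate nucleus ids in slide {slide_id!r}: "
                f"{list(dup[dup > 1].index[:5])}"
            )
        self._index = {nid: i for i, nid in enumerate(ids)}
        self._tree: cKDTree | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.nuclei)

    def __iter__(self) -> Iterator[Nucleus]:
        return iter(self.nuclei)

    def __getitem__(self, nucleus_id: str) -> Nucleus:
        return self.nuclei[self._index[nucleus_id]]

    def __contains__(self, nucleus_id: str) -> bool:
        return nucleus_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NucleusSet):
            return NotImplemented
        return (
            self.slide_id == other.slide_id
            and self.mpp == other.mpp
            and self.nuclei == other.nuclei
        )

    # -- vectorized views ----------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [n.id for n in self.nuclei]

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) float array of centroid (x, y)."""
        if not self.nuclei:
            return np.empty((0, 2))
        return np.asarray([n.centroid for n in self.nuclei], dtype=float)

    @property
    def types(self) -> np.ndarray:
        return np.asarray([n.cell_type.value for n in self.nuclei], dtype=object)

    def subset(self, types: Sequence[CellType | str]) -> "NucleusSet":
        wanted = {CellType(t) for t in types}
        return NucleusSet(
            self.slide_id, [n for n in self.nuclei if n.cell_type in wanted], self.mpp
        )

    def query_neighbors(self, xy: Sequence[float], k: int) -> list[tuple[str, float]]:
        """k nearest nuclei to a point, as (id, distance), nearest first."""
        if not self.nuclei:
            return []
        if self._tree is None:
            self._tree = cKDTree(self.centroids)
        k = min(k, len(self.nuclei))
        dist, idx = self._tree.query(np.asarray(xy, dtype=float), k=k)
        dist = np.atleast_1d(dist)
        idx = np.atleast_1d(idx)
        return [(self.nuclei[i].id, float(d)) for d, i in zip(dist, idx)]


@dataclass
class CompositionSummary:
    """Per-type cell counts and percentages over the non-necrotic total.

    ``percentages`` is None when the slide holds no non-necrotic cell.
    """

    counts: dict[CellType, int]
    total: int
    percentages: dict[CellType, float] | None = field(default=None)

    @property
    def defined(self) -> bool:
        return self.percentages is not None


# ---------------------------------------------------------------------------
# segmentation dialect I/O
# ---------------------------------------------------------------------------

def _parse_record(nid: str, rec: dict) -> Nucleus | None:
    try:
        code = int(rec["type"])
    except (KeyError, TypeError, ValueError) as exc:
        raise SegmentationError(f"nucleus {nid!r}: missing or bad type field") from exc
    if code == 0:
        return None
    if code not in TYPE_CODE_MAP:
        raise SegmentationError(f"nucleus {nid!r}: unknown type code {code}")
    try:
        centroid = tuple(float(v) for v in rec["centroid"])
        contour = tuple((float(x), float(y)) for x, y in rec["contour"])
        bbox = tuple(float(v) for v in rec["bbox"])
        if len(centroid) != 2 or len(bbox) != 4:
            raise ValueError("bad centroid/bbox arity")
    except (KeyError, TypeError, ValueError) as exc:
        raise SegmentationError(f"nucleus {nid!r}: malformed record ({exc})") from exc
    return Nucleus(id=str(nid), centroid=centroid, contour=contour, bbox=bbox,
                   cell_type=TYPE_CODE_MAP[code])


def read_segmentation(path: str | Path, mpp: float = DEFAULT_MPP,
                      slide_id: str | None = None) -> NucleusSet:
    """Read a per-nucleus JSON record map into a :class:`NucleusSet`.

    Accepts either a flat map ``{id: record}`` or the same map nested under a
    top-level ``"nuc"`` key (the HoVer-Net file layout).  Unlabelled records
    (type code 0) are dropped with a logged count.
    """
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    if "nuc" in payload and isinstance(payload["nuc"], dict):
        records = payload["nuc"]
        mpp = float(payload.get("mpp", mpp))
    else:
        records = payload
    nuclei = []
    n_dropped = 0
    for nid, rec in records.items():
        nucleus = _parse_record(nid, rec)
        if nucleus is None:
            n_dropped += 1
        else:
            nuclei.append(nucleus)
    if n_dropped:
        logger.warning("%s: dropped %d unlabelled (type 0) nuclei", path.name, n_dropped)
    return NucleusSet(slide_id or path.stem, nuclei, mpp=mpp)


def write_segmentation(ns: NucleusSet, path: str | Path) -> None:
    """Write a NucleusSet back to the JSON record-map dialect (lossless)."""
    records = {
        n.id: {
            "bbox": list(n.bbox),
            "centroid": list(n.centroid),
            "contour": [list(p) for p in n.contour],
            "type": TYPE_TO_CODE[n.cell_type],
        }
        for n in ns
    }
    with open(path, "w") as fh:
        json.dump({"mpp": ns.mpp, "nuc": records}, fh)


# ---------------------------------------------------------------------------
# filtering and composition
# ---------------------------------------------------------------------------

def filter_non_necrotic(ns: NucleusSet) -> NucleusSet:
    """Remove dead (necrotic) nuclei; other nuclei unchanged, order stable."""
    return NucleusSet(
        ns.slide_id, [n for n in ns if n.cell_type is not CellType.DEAD], ns.mpp
    )


def compute_composition(ns: NucleusSet) -> CompositionSummary:
    """Counts and percentages of tumor/inflammatory/stroma/normal cells.

    Percentages are taken over the non-necrotic total; dead cells, if still
    present, are excluded from counts and totals.
    """
    counts = {t: 0 for t in COMPOSITION_TYPES}
    for n in ns:
        if n.cell_type in counts:
            counts[n.cell_type] += 1
    total = sum(counts.values())
    if total == 0:
        return CompositionSummary(counts=counts, total=0, percentages=None)
    percentages = {t: 100.0 * c / total for t, c in counts.items()}
    return CompositionSummary(counts=counts, total=total, percentages=percentages)


# ---------------------------------------------------------------------------
# feature/edge table output ("four dataframes" per slide)
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["source_id", "target_id", "graph_label", "length_px"]


def feature_table_paths(out_dir: str | Path, slide_id: str) -> dict[str, Path]:
    out_dir = Path(out_dir)
    return {
        "tumor": out_dir / f"{slide_id}_tumor.csv",
        "inflammatory": out_dir / f"{slide_id}_inflammatory.csv",
        "stroma": out_dir / f"{slide_id}_stroma.csv",
        "edges": out_dir / f"{slide_id}_edges.csv",
    }


def write_feature_tables(ns: NucleusSet, features: "pd.DataFrame | dict[str, pd.DataFrame]",
                         edges: Iterable, out_dir: str | Path) -> dict[str, Path]:
    """Write the four per-slide tables: tumor/inflammatory/stroma features + edges.

    ``features`` is either a single id-indexed table or a per-type dict of
    them (as returned by :func:`scmtop.graph.assemble_cell_features`); every
    row must reference an existing nucleus.  An ``x``/``y`` centroid pair is
    prepended to each feature row.  ``edges`` is an iterable of EdgeSet
    objects (see :mod:`scmtop.graph`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = feature_table_paths(out_dir, ns.slide_id)

    by_type: dict[str, list[str]] = {t.value: [] for t in PROFILED_TYPES}
    for n in ns:
        if n.cell_type in PROFILED_TYPES:
            by_type[n.cell_type.value].append(n.id)
    for tname in ("tumor", "inflammatory", "stroma"):
        table = features[tname] if isinstance(features, dict) else features
        dangling = [i for i in table.index if i not in ns]
        if dangling:
            raise SegmentationError(
                f"feature rows reference unknown nuclei: {dangling[:5]}")
        ids = [i for i in by_type[tname] if i in table.index]
        sub = table.loc[ids].copy()
        sub.insert(0, "x", [ns[i].centroid[0] for i in ids])
        sub.insert(1, "y", [ns[i].centroid[1] for i in ids])
        sub.to_csv(paths[tname], index_label="cell_id")

    rows = []
    for es in edges:
        for a, b, length in es.edges:
            if a not in ns or b not in ns:
                raise SegmentationError(f"edge ({a}, {b}) references unknown nucleus")
            rows.append((a, b, es.graph_label, length))
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(paths["edges"], index=False)
    return paths


def read_feature_tables(out_dir: str | Path, slide_id: str) -> dict[str, pd.DataFrame]:
    """Read back the four per-slide tables written by :func:`write_feature_tables`."""
    paths = feature_table_paths(out_dir, slide_id)
    out = {}
    for name, p in paths.items():
        if name == "edges":
            out[name] = pd.read_csv(p)
        else:
            out[name] = pd.read_csv(p, index_col="cell_id")
            out[name].index = out[name].index.astype(str)
    return out
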