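"""Seeded synthetic nucleus fields and cohorts with planted structure.

The generator emulates the inputs the pipeline consumes: marked spatial
point patterns (homogeneous Poisson, Thomas cluster, or region-restricted
processes per cell type), polygonal nuclear contours (ellipses with radial
Fourier perturbation whose amplitude dispersion plants a morphological-
heterogeneity ground truth), and 8-bit grayscale patches with controllable
stripe texture.  Cohorts plant region-level cluster colocalization and
sample-level ecotype archetypes so module discovery and ecotype
classification can be validated end to end.

Everything is driven by ``numpy.random.default_rng`` seeds: the same seed
reproduces the same output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclei_io import DEFAULT_MPP, CellType, Nucleus, NucleusSet

UM_PER_MM = 1000.0


# ---------------------------------------------------------------------------
# point processes
# ---------------------------------------------------------------------------

@dataclass
class PoissonProcess:
    """Homogeneous Poisson point process."""

    intensity_per_mm2: float
    region: tuple[float, float, float, float] | None = None  # fractional xmin,ymin,xmax,ymax

    def sample(self, rng: np.random.Generator, size_um: float) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.region or (0.0, 0.0, 1.0, 1.0)
        w = (xmax - xmin) * size_um
        h = (ymax - ymin) * size_um
        lam = self.intensity_per_mm2 * (w / UM_PER_MM) * (h / UM_PER_MM)
        n = rng.poisson(lam)
        pts = rng.uniform(size=(n, 2)) * [w, h] + [xmin * size_um, ymin * size_um]
        return pts


@dataclass
class ThomasProcess:
    """Thomas cluster process: Poisson parents, Gaussian offspring clouds."""

    parent_intensity_per_mm2: float
    mean_offspring: float
    sigma_um: float
    region: tuple[float, float, float, float] | None = None

    @property
    def intensity_per_mm2(self) -> float:
        return self.parent_intensity_per_mm2 * self.mean_offspring

    def sample(self, rng: np.random.Generator, size_um: float,
               return_parents: bool = False):
        xmin, ymin, xmax, ymax = self.region or (0.0, 0.0, 1.0, 1.0)
        w = (xmax - xmin) * size_um
        h = (ymax - ymin) * size_um
        lam = self.parent_intensity_per_mm2 * (w / UM_PER_MM) * (h / UM_PER_MM)
        n_parents = rng.poisson(lam)
        parents = rng.uniform(size=(n_parents, 2)) * [w, h] + [
            xmin * size_um, ymin * size_um]
        pts, parent_of = [], []
        for i, p in enumerate(parents):
            n_off = rng.poisson(self.mean_offspring)
            off = p + rng.normal(scale=self.sigma_um, size=(n_off, 2))
            pts.append(off)
            parent_of.extend([i] * n_off)
        pts = np.vstack(pts) if pts else np.empty((0, 2))
        keep = ((pts[:, 0] >= 0) & (pts[:, 0] < size_um)
                & (pts[:, 1] >= 0) & (pts[:, 1] < size_um))
        pts = pts[keep]
        parent_of = np.asarray(parent_of)[keep] if len(parent_of) else np.empty(0, int)
        if return_parents:
            return pts, parents, parent_of
        return pts


@dataclass
class ShapeModel:
    """Elliptical nuclei with radial Fourier perturbation.

    ``perturbation_dispersion`` spreads the per-nucleus perturbation
    amplitude across nuclei; larger dispersion plants larger morphological
    intratumor heterogeneity.
    """

    mean_radius_um: float = 3.0
    radius_sd_um: float = 0.5
    axis_ratio_range: tuple[float, float] = (1.0, 1.8)
    perturbation_amplitude: float = 0.05
    perturbation_dispersion: float = 0.0
    n_vertices: int = 24


@dataclass
class TextureModel:
    """Gray-level model of nuclear patches."""

    mean_gray: float = 100.0
    sd_gray: float = 10.0
    stripe_period_px: float = 0.0    # 0 disables stripes
    stripe_contrast: float = 0.0
    background_gray: float = 220.0


@dataclass
class FieldConfig:
    """One synthetic slide: per-type processes, shapes, textures, seed."""

    size_um: float = 1000.0
    mpp: float = DEFAULT_MPP
    processes: dict[CellType, object] = field(default_factory=dict)
    shapes: dict[CellType, ShapeModel] = field(default_factory=dict)
    textures: dict[CellType, TextureModel] = field(default_factory=dict)
    seed: int = 0
    slide_id: str = "synthetic"
    make_patches: bool = False


@dataclass
class SimulatedField:
    """Generator output: the nucleus set plus ground truth for tests."""

    nucleus_set: NucleusSet
    patches: dict[str, tuple[np.ndarray, np.ndarray]]   # id -> (patch, mask)
    ground_truth: dict


def _make_contour(rng: np.random.Generator, cx: float, cy: float,
                  shape: ShapeModel, mpp: float) -> np.ndarray:
    r_um = max(0.5, rng.normal(shape.mean_radius_um, shape.radius_sd_um))
    ratio = rng.uniform(*shape.axis_ratio_range)
    a = r_um * np.sqrt(ratio) / mpp
    b = r_um / np.sqrt(ratio) / mpp
    phi = rng.uniform(0, np.pi)
    amp = abs(rng.normal(shape.perturbation_amplitude,
                         shape.perturbation_dispersion))
    theta = np.linspace(0, 2 * np.pi, shape.n_vertices, endpoint=False)
    wobble = np.zeros_like(theta)
    for m in (2, 3, 4, 5):
        wobble += rng.normal(scale=amp / 2) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    scale = 1.0 + np.clip(wobble, -0.6, 0.6)
    ex = a * np.cos(theta) * scale
    ey = b * np.sin(theta) * scale
    x = cx + ex * np.cos(phi) - ey * np.sin(phi)
    y = cy + ex * np.sin(phi) + ey * np.cos(phi)
    return np.column_stack([x, y])


def _make_patch(rng: np.random.Generator, contour: np.ndarray,
                bbox: tuple[float, float, float, float],
                tex: TextureModel) -> tuple[np.ndarray, np.ndarray]:
    from .features import rasterize_contour
    mask, (x0, y0) = rasterize_contour(contour)
    patch = np.full(mask.shape, tex.background_gray, dtype=float)
    noise = rng.normal(tex.mean_gray, tex.sd_gray, size=mask.shape)
    if tex.stripe_period_px > 0 and tex.stripe_contrast > 0:
        xs = np.arange(mask.shape[1]) + x0
        stripes = tex.stripe_contrast * np.sin(2 * np.pi * xs / tex.stripe_period_px)
        noise = noise + stripes[None, :]
    patch[mask] = noise[mask]
    return np.clip(patch, 0, 255).astype(np.uint8), mask


def simulate_field(fc: FieldConfig) -> SimulatedField:
    """Generate one synthetic slide from its configuration (deterministic)."""
    rng = np.random.default_rng(fc.seed)
    size_px = fc.size_um / fc.mpp
    nuclei: list[Nucleus] = []
    patches: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    truth: dict = {"type_points": {}, "parents": {}}
    counter = 0
    for ctype in CellType:  # fixed iteration order for determinism
        proc = fc.processes.get(ctype)
        if proc is None:
            continue
        if isinstance(proc, ThomasProcess):
            pts, parents, parent_of = proc.sample(rng, fc.size_um, return_parents=True)
            truth["parents"][ctype] = (parents / fc.mpp, parent_of)
        else:
            pts = proc.sample(rng, fc.size_um)
        pts_px = pts / fc.mpp
        truth["type_points"][ctype] = pts_px
        shape = fc.shapes.get(ctype, ShapeModel())
        tex = fc.textures.get(ctype, TextureModel())
        for cx, cy in pts_px:
            counter += 1
            nid = str(counter)
            contour = _make_contour(rng, cx, cy, shape, fc.mpp)
            contour[:, 0] = np.clip(contour[:, 0], 0, size_px - 1)
            contour[:, 1] = np.clip(contour[:, 1], 0, size_px - 1)
            xmin, ymin = np.floor(contour.min(axis=0))
            xmax, ymax = np.ceil(contour.max(axis=0))
            centroid = (float(contour[:, 0].mean()), float(contour[:, 1].mean()))
            nucleus = Nucleus(
                id=nid, centroid=centroid,
                contour=tuple(map(tuple, contour.tolist())),
                bbox=(float(xmin), float(ymin), float(xmax), float(ymax)),
                cell_type=ctype,
            )
            nuclei.append(nucleus)
            if fc.make_patches:
                patches[nid] = _make_patch(rng, contour, nucleus.bbox, tex)
    ns = NucleusSet(fc.slide_id, nuclei, mpp=fc.mpp)
    return SimulatedField(nucleus_set=ns, patches=patches, ground_truth=truth)


# ---------------------------------------------------------------------------
# cohorts with planted colocalization regions and ecotype archetypes
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """A cohort of slides with planted region/module/ecotype structure.

    Each slide is tiled into square regions (``region_um`` per side); every
    region draws a region kind from its sample's archetype prior; each kind
    co-places its clusters as Gaussian blobs inside the region.  MEM
    discovery should recover the cluster -> kind partition, and ecotype
    clustering the archetype labels.
    """

    n_samples: int = 40
    size_um: float = 2000.0
    region_um: float = 500.0
    mpp: float = DEFAULT_MPP
    #: region kind -> list of cluster names co-placed in regions of the kind
    region_clusters: dict[str, list[str]] = field(default_factory=lambda: {
        "tumor_rich": ["TUM0", "TUM1"],
        "immune_rich": ["INF0", "INF1"],
        "stroma_rich": ["STR0", "STR1"],
        "mixed": ["TUM2", "STR2"],
    })
    #: archetype name -> region-kind prior (rows of the mixture)
    archetypes: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "E1": {"tumor_rich": 0.70, "immune_rich": 0.10, "stroma_rich": 0.10, "mixed": 0.10},
        "E2": {"tumor_rich": 0.10, "immune_rich": 0.70, "stroma_rich": 0.10, "mixed": 0.10},
        "E3": {"tumor_rich": 0.10, "immune_rich": 0.10, "stroma_rich": 0.70, "mixed": 0.10},
        "E4": {"tumor_rich": 0.10, "immune_rich": 0.10, "stroma_rich": 0.10, "mixed": 0.70},
    })
    cells_per_cluster_per_region: float = 30.0
    blob_sigma_um: float = 80.0
    noise: float = 0.0               # archetype-prior jitter
    seed: int = 0


_CLUSTER_TYPE = {"TUM": CellType.TUMOR, "INF": CellType.INFLAMMATORY,
                 "STR": CellType.STROMA}


def _cluster_cell_type(cluster: str) -> CellType:
    return _CLUSTER_TYPE.get(cluster[:3], CellType.TUMOR)


@dataclass
class SimulatedCohort:
    """Cohort output: per-slide cells + labels, and ground truth."""

    slides: dict[str, NucleusSet]
    cluster_labels: dict[str, pd.Series]       # sample -> per-cell cluster name
    ecotypes: pd.Series                         # sample -> archetype name
    region_maps: dict[str, np.ndarray]          # sample -> region-kind grid
    clusters: list[str]
    cluster_kind: dict[str, str]                # cluster -> planted region kind


def simulate_cohort(cc: CohortConfig) -> SimulatedCohort:
    """Generate a cohort with planted modules and ecotypes (deterministic)."""
    rng = np.random.default_rng(cc.seed)
    archetype_names = list(cc.archetypes)
    kinds = list(cc.region_clusters)
    clusters = [c for k in kinds for c in cc.region_clusters[k]]
    cluster_kind = {c: k for k in kinds for c in cc.region_clusters[k]}
    # balanced archetype allocation, remainder to the earlier archetypes
    per = cc.n_samples // len(archetype_names)
    extra = cc.n_samples % len(archetype_names)
    assignment = []
    for i, a in enumerate(archetype_names):
        assignment.extend([a] * (per + (1 if i < extra else 0)))

    n_tiles = int(np.floor(cc.size_um / cc.region_um))
    shape = ShapeModel()
    slides, labels_by_sample, region_maps = {}, {}, {}
    ecolabels = {}
    for s_idx, arch in enumerate(assignment):
        sample_id = f"S{s_idx:03d}"
        ecolabels[sample_id] = arch
        prior = np.array([cc.archetypes[arch].get(k, 0.0) for k in kinds])
        if cc.noise > 0:
            prior = np.clip(prior + rng.normal(scale=cc.noise, size=len(prior)), 1e-6, None)
        prior = prior / prior.sum()
        region_map = rng.choice(len(kinds), size=(n_tiles, n_tiles), p=prior)
        region_maps[sample_id] = np.array(kinds, dtype=object)[region_map]
        nuclei: list[Nucleus] = []
        labels: dict[str, str] = {}
        counter = 0
        for r in range(n_tiles):
            for c in range(n_tiles):
                kind = kinds[region_map[r, c]]
                ox = c * cc.region_um
                oy = r * cc.region_um
                center = np.array([ox + cc.region_um / 2, oy + cc.region_um / 2])
                for cluster in cc.region_clusters[kind]:
                    n_cells = rng.poisson(cc.cells_per_cluster_per_region)
                    pts = center + rng.normal(scale=cc.blob_sigma_um, size=(n_cells, 2))
                    pts[:, 0] = np.clip(pts[:, 0], ox, ox + cc.region_um - 1e-6)
                    pts[:, 1] = np.clip(pts[:, 1], oy, oy + cc.region_um - 1e-6)
                    ctype = _cluster_cell_type(cluster)
                    for ux, uy in pts / cc.mpp:
                        counter += 1
                        nid = str(counter)
                        contour = _make_contour(rng, ux, uy, shape, cc.mpp)
                        xmin, ymin = np.floor(contour.min(axis=0))
                        xmax, ymax = np.ceil(contour.max(axis=0))
                        nuclei.append(Nucleus(
                            id=nid,
                            centroid=(float(contour[:, 0].mean()),
                                      float(contour[:, 1].mean())),
                            contour=tuple(map(tuple, contour.tolist())),
                            bbox=(float(xmin), float(ymin), float(xmax), float(ymax)),
                            cell_type=ctype,
                        ))
                        labels[nid] = cluster
        slides[sample_id] = NucleusSet(sample_id, nuclei, mpp=cc.mpp)
        labels_by_sample[sample_id] = pd.Series(labels, name="cluster")
    return SimulatedCohort(
        slides=slides, cluster_labels=labels_by_sample,
        ecotypes=pd.Series(ecolabels, name="archetype"),
        region_maps=region_maps, clusters=clusters, cluster_kind=cluster_kind,
    )
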