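"""End-to-end orchestration: extract -> cluster -> MITH -> MEM -> ecotype.

The pipeline consumes a directory of per-slide segmentation JSON files,
writes the four per-slide feature/edge tables, clusters each profiled cell
type, extends the clustering to all cells, computes per-sample MITH, runs
the spot/module analysis, and (with enough samples) the ecotype
classification.  A JSON manifest records parameters, seeds, a parameter
hash and every per-stage output path so runs are auditable and
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, ecotype, graph, heterogeneity, spatial
from .features import compute_morphology, compute_texture
from .nuclei_io import (CellType, NucleusSet, compute_composition,
                        filter_non_necrotic, read_segmentation,
                        write_feature_tables)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run (YAML round-trippable)."""

    input_dir: str = ""
    output_dir: str = "scmtop_out"
    mpp: float = 0.25
    k: int = 5
    edge_threshold_px: float = 100.0
    sampling_fraction: float = 0.005
    leiden_resolution: float = 1.0
    n_pcs: int = 50
    n_neighbors: int = 15
    spot_um: float = 200.0
    n_modules: int = 8
    ecotype_k_min: int = 2
    ecotype_k_max: int = 10
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mpp", "k", "edge_threshold_px", "sampling_fraction",
                     "leiden_resolution", "n_pcs", "n_neighbors", "spot_um",
                     "n_modules", "ecotype_k_min", "ecotype_k_max",
                     "train_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def extract_slide(ns: NucleusSet, k: int = 5, threshold_px: float = 100.0,
                  patches: dict | None = None,
                  out_dir: str | Path | None = None) -> dict:
    """Feature-extract one slide: composition, graphs, per-cell tables."""
    ns = filter_non_necrotic(ns)
    composition = compute_composition(ns)
    morph_rows = {}
    tex_rows = {}
    for n in ns:
        if n.cell_type not in graph.TYPE_GRAPHS:
            continue
        morph_rows[n.id] = compute_morphology(n.contour, n.bbox, nucleus_id=n.id)
        if patches and n.id in patches:
            patch, mask = patches[n.id]
            tex_rows[n.id] = compute_texture(patch, mask)
    morphology = pd.DataFrame.from_dict(morph_rows, orient="index")
    morphology.index.name = "cell_id"
    texture = None
    if tex_rows:
        texture = pd.DataFrame.from_dict(tex_rows, orient="index")
        texture.index.name = "cell_id"
    edge_sets = graph.build_all_graphs(ns, k=k, threshold_px=threshold_px)
    tables = graph.assemble_cell_features(ns, edge_sets, morphology, texture)
    result = {"nucleus_set": ns, "composition": composition,
              "edge_sets": edge_sets, "tables": tables}
    if out_dir is not None:
        result["paths"] = write_feature_tables(ns, tables, edge_sets.values(), out_dir)
    n_edges = sum(len(es) for es in edge_sets.values())
    logger.info("%s: %d cells, %d edges", ns.slide_id, len(ns), n_edges)
    return result


@dataclass
class PipelineResult:
    manifest: dict
    per_slide: dict = field(default_factory=dict)
    cluster_models: dict = field(default_factory=dict)
    cell_labels: dict = field(default_factory=dict)
    mith: pd.DataFrame | None = None
    mem_model: spatial.MEMModel | None = None
    scored_spots: dict = field(default_factory=dict)
    composition: pd.DataFrame | None = None
    ecotype_model: ecotype.EcotypeModel | None = None


_PREFIX = {CellType.TUMOR: "TUM", CellType.INFLAMMATORY: "INF",
           CellType.STROMA: "STR"}


def run_pipeline(config: PipelineConfig,
                 slides: dict[str, NucleusSet] | None = None) -> PipelineResult:
    """Run every stage on a set of slides; returns results + manifest.

    ``slides`` may be given directly (e.g. from the synthetic generator);
    otherwise every ``*.json`` under ``config.input_dir`` is read.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if slides is None:
        input_dir = Path(config.input_dir)
        if not input_dir.is_dir():
            raise FileNotFoundError(f"input directory not found: {input_dir}")
        slides = {}
        for path in sorted(input_dir.glob("*.json")):
            ns = read_segmentation(path, mpp=config.mpp)
            slides[ns.slide_id] = ns
        if not slides:
            raise FileNotFoundError(f"no segmentation JSON files in {input_dir}")

    manifest: dict = {
        "parameters": asdict(config),
        "parameter_hash": config.param_hash(),
        "seed": config.seed,
        "stages": {},
    }
    result = PipelineResult(manifest=manifest)

    # stage 1: per-slide extraction -----------------------------------------
    tables_dir = out_dir / "tables"
    for sid in sorted(slides):
        res = extract_slide(slides[sid], k=config.k,
                            threshold_px=config.edge_threshold_px,
                            out_dir=tables_dir)
        result.per_slide[sid] = res
    manifest["stages"]["extract"] = {
        "n_slides": len(slides),
        "tables_dir": str(tables_dir),
        "total_cells": int(sum(len(r["nucleus_set"]) for r in result.per_slide.values())),
    }

    # stage 2: per-type clustering + extrapolation to all cells -------------
    rng = np.random.default_rng(config.seed)
    for ctype in (CellType.TUMOR, CellType.INFLAMMATORY, CellType.STROMA):
        tname = ctype.value
        per_slide_tables = {sid: r["tables"][tname]
                            for sid, r in result.per_slide.items()}
        pooled = clustering.sample_cells(per_slide_tables,
                                        fraction=config.sampling_fraction,
                                        seed=int(rng.integers(2 ** 31)))
        if len(pooled) < 2:
            continue
        model = clustering.leiden_cluster(
            pooled, cell_type=tname, resolution=config.leiden_resolution,
            n_pcs=config.n_pcs, n_neighbors=config.n_neighbors,
            seed=config.seed, label_prefix=_PREFIX[ctype])
        result.cluster_models[tname] = model
        for sid, tab in per_slide_tables.items():
            if len(tab) == 0:
                continue
            labels = clustering.extrapolate_clusters(model, tab, seed=config.seed)
            names = pd.Series([model.label_name(v) for v in labels],
                              index=tab.index, name="cluster")
            result.cell_labels.setdefault(sid, {})[tname] = names
    manifest["stages"]["cluster"] = {
        t: m.n_clusters for t, m in result.cluster_models.items()}

    # stage 3: MITH ----------------------------------------------------------
    from .features import MORPH_FEATURE_NAMES, TEXTURE_FEATURE_NAMES
    mith_features = MORPH_FEATURE_NAMES + TEXTURE_FEATURE_NAMES
    tumor_parts = []
    for sid, r in result.per_slide.items():
        tab = r["tables"]["tumor"]
        morph = tab[[c for c in tab.columns if c in mith_features]]
        morph = morph.copy()
        morph.insert(0, heterogeneity.SAMPLE_COLUMN, sid)
        tumor_parts.append(morph)
    if tumor_parts:
        pooled_tumor = pd.concat(tumor_parts)
        if len(pooled_tumor) >= 2:
            result.mith = heterogeneity.mith_table(pooled_tumor)
            result.mith.to_csv(out_dir / "mith.csv")
            manifest["stages"]["mith"] = {"path": str(out_dir / "mith.csv"),
                                          "n_samples": len(result.mith)}

    # stage 4: spots, spatial correlation, MEMs ------------------------------
    if result.cell_labels:
        all_clusters = sorted({
            name for m in result.cluster_models.values() for name in m.cluster_names()})
        spot_matrices, corr_matrices = {}, []
        for sid, r in result.per_slide.items():
            labels = pd.concat(result.cell_labels.get(sid, {}).values()) \
                if result.cell_labels.get(sid) else pd.Series(dtype=object)
            ns_prof = r["nucleus_set"].subset(list(graph.TYPE_GRAPHS))
            ns_prof = NucleusSet(sid, [n for n in ns_prof if n.id in labels.index],
                                 ns_prof.mpp)
            if len(ns_prof) == 0:
                continue
            sm = spatial.tessellate(ns_prof, labels, spot_um=config.spot_um,
                                    clusters=all_clusters)
            spot_matrices[sid] = sm
            corr_matrices.append(spatial.correlation_matrix(sm))
        if corr_matrices:
            try:
                result.mem_model = spatial.build_mem_model(
                    corr_matrices, n_modules=config.n_modules)
            except ValueError as exc:
                logger.warning("MEM stage skipped: %s", exc)
                manifest["stages"]["mem"] = {"skipped": str(exc)}
        if result.mem_model is not None:
            result.mem_model.save(out_dir / "mem_model.joblib")
            moran_rows = {}
            for sid, sm in spot_matrices.items():
                scored = spatial.score_spots(sm, result.mem_model)
                result.scored_spots[sid] = scored
                moran_rows[sid] = spatial.module_morans_i(scored, result.mem_model)
            pd.DataFrame(moran_rows).T.to_csv(out_dir / "module_morans_i.csv")
            manifest["stages"]["mem"] = {
                "n_modules": result.mem_model.n_modules,
                "model_path": str(out_dir / "mem_model.joblib"),
                "morans_i_path": str(out_dir / "module_morans_i.csv"),
            }

    # stage 5: ecotypes ------------------------------------------------------
    if result.mem_model is not None and len(result.scored_spots) >= 4:
        assignments = {sid: s["module"] for sid, s in result.scored_spots.items()}
        comp = ecotype.mem_composition(assignments, result.mem_model.module_names)
        result.composition = comp
        try:
            em = ecotype.cluster_ecotypes(
                comp, k_range=range(config.ecotype_k_min, config.ecotype_k_max + 1),
                seed=config.seed)
            em = ecotype.train_ecotype_classifier(
                em, train_fraction=config.train_fraction, seed=config.seed)
            result.ecotype_model = em
            em.save(out_dir / "ecotype_model.joblib")
            table = comp.copy()
            table["ecotype"] = em.labels
            table.to_csv(out_dir / "ecotypes.csv")
            manifest["stages"]["ecotype"] = {
                "k": em.k, "test_weighted_f1": em.test_f1,
                "path": str(out_dir / "ecotypes.csv"),
            }
        except ValueError as exc:
            logger.warning("ecotype stage skipped: %s", exc)
            manifest["stages"]["ecotype"] = {"skipped": str(exc)}

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["path"] = str(manifest_path)
    return result
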