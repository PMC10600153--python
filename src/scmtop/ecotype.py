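"""Sample-level ecotypes from micro-ecological-module composition.

Each sample is summarized by the fraction of its classified spots falling
in each micro-ecological module (MEM).  Ward hierarchical clustering of
these composition vectors defines the ecotypes; the cluster number is
chosen over a search range by Silhouette coefficient with Calinski-Harabasz
as tie-break.  An SVM trained on the compositions (stratified 80/20 split)
lets new samples be classified without re-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import calinski_harabasz_score, f1_score, silhouette_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .spatial import MODULE0

DEFAULT_K_RANGE = range(2, 11)
DEFAULT_TRAIN_FRACTION = 0.8


def mem_composition(assignments: dict[str, pd.Series],
                    module_names: list[str],
                    include_empty: bool = False) -> pd.DataFrame:
    """Per-sample fraction of spots in each module (rows sum to 1).

    ``assignments`` maps sample id -> per-spot module assignment.  By
    default Module0_NC spots are excluded from the denominator; with
    ``include_empty`` they form their own composition column.  Samples with
    zero classified spots get a NaN row.
    """
    columns = list(module_names) + ([MODULE0] if include_empty else [])
    rows = {}
    for sample_id in sorted(assignments):
        a = assignments[sample_id]
        if not include_empty:
            a = a[a != MODULE0]
        counts = a.value_counts().reindex(columns, fill_value=0)
        total = counts.sum()
        rows[sample_id] = counts / total if total > 0 else counts * np.nan
    comp = pd.DataFrame(rows).T
    comp.index.name = "sample_id"
    return comp


@dataclass
class EcotypeModel:
    """Fitted ecotype clustering and (optionally) its SVM classifier."""

    composition: pd.DataFrame
    linkage_matrix: np.ndarray
    k: int
    labels: pd.Series                 # sample id -> ecotype in {1..k}
    seed: int
    selection: pd.DataFrame | None = None   # per-k Silhouette / CH table
    classifier: SVC | None = None
    test_f1: float | None = field(default=None)
    split: dict | None = None

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "EcotypeModel":
        return joblib.load(path)


def cluster_ecotypes(composition: pd.DataFrame,
                     k_range=DEFAULT_K_RANGE, seed: int = 0) -> EcotypeModel:
    """Ward clustering of MEM compositions with automatic k selection.

    k maximizes the Silhouette coefficient over ``k_range``; ties break by
    Calinski-Harabasz index, then by smaller k.
    """
    comp = composition.dropna()
    n = len(comp)
    if n < 4:
        raise ValueError(f"need >= 4 samples, got {n}")
    x = comp.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all compositions identical; ecotypes undefined")
    Z = linkage(x, method="ward")
    records = []
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        records.append({
            "k": k,
            "silhouette": silhouette_score(x, lab),
            "calinski_harabasz": calinski_harabasz_score(x, lab),
        })
    if not records:
        raise ValueError("no valid k in the search range")
    sel = pd.DataFrame(records).set_index("k")
    best_k = int(sel.sort_values(
        ["silhouette", "calinski_harabasz"], ascending=False,
        kind="stable").index[0])
    labels = pd.Series(fcluster(Z, t=best_k, criterion="maxclust"),
                       index=comp.index, name="ecotype")
    return EcotypeModel(composition=comp, linkage_matrix=Z, k=best_k,
                        labels=labels, seed=seed, selection=sel)


def train_ecotype_classifier(em: EcotypeModel,
                             train_fraction: float = DEFAULT_TRAIN_FRACTION,
                             seed: int | None = None,
                             kernel: str = "rbf") -> EcotypeModel:
    """Fit an SVM on the compositions with a stratified train/test split.

    Mutates and returns ``em`` with the fitted classifier, the held-out
    weighted F1, and the split indices recorded.
    """
    seed = em.seed if seed is None else seed
    counts = em.labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(
            f"ecotypes with a single sample cannot be split: "
            f"{list(singletons.index)}; merge or evaluate jointly")
    x = em.composition.to_numpy(dtype=float)
    y = em.labels.to_numpy()
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed)
    clf = SVC(kernel=kernel, random_state=seed)
    clf.fit(x[train_idx], y[train_idx])
    pred = clf.predict(x[test_idx])
    em.classifier = clf
    em.test_f1 = float(f1_score(y[test_idx], pred, average="weighted"))
    em.split = {"train": em.composition.index[train_idx].tolist(),
                "test": em.composition.index[test_idx].tolist()}
    return em


def classify_ecotype(em: EcotypeModel,
                     composition: pd.Series | pd.DataFrame) -> np.ndarray:
    """Predict ecotype labels for composition vectors with the trained SVM."""
    if em.classifier is None:
        raise ValueError("model has no trained classifier; "
                         "run train_ecotype_classifier first")
    if isinstance(composition, pd.Series):
        composition = composition.to_frame().T
    missing = [c for c in em.composition.columns if c not in composition.columns]
    if missing:
        raise ValueError(f"composition schema mismatch, missing: {missing}")
    x = composition[em.composition.columns].to_numpy(dtype=float)
    sums = x.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("composition vectors must sum to ~1")
    return em.classifier.predict(x)
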