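"""Morphological intratumor heterogeneity (MITH) of tumor nuclei.

Each morphological/texture feature is first normalized (z-scored) across
all tumor nuclei of all samples; MITH of one sample is the mean over
features of the population standard deviation of the normalized feature
across that sample's tumor nuclei:

    MITH = (1/N) * sum_i sqrt( sum_j (x_ij - xbar_i)^2 / M )

with N features, M tumor nuclei in the sample, x_ij the normalized value
of feature i for nucleus j and xbar_i the per-sample feature mean.  The
divide-by-M (population) convention is deliberate: MITH is then invariant
under duplicating a sample's nuclei.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

SAMPLE_COLUMN = "sample_id"


def normalize_global(features: pd.DataFrame, method: str = "zscore",
                     sample_column: str = SAMPLE_COLUMN) -> pd.DataFrame:
    """Normalize each feature across all nuclei pooled over samples.

    ``method`` is "zscore" (mean 0, SD 1) or "robust" (median/MAD).
    Zero-dispersion features are dropped with a warning.  Non-numeric
    columns and the sample-id column pass through unchanged.
    """
    numeric = features.select_dtypes(include=[np.number]).columns
    numeric = [c for c in numeric if c != sample_column]
    if len(features) < 2:
        raise ValueError("need >= 2 nuclei to normalize")
    out = features.copy()
    dropped = []
    for col in numeric:
        x = out[col].to_numpy(dtype=float)
        if method == "zscore":
            center, scale = x.mean(), x.std()
        elif method == "robust":
            center = np.median(x)
            scale = 1.4826 * np.median(np.abs(x - center))
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        if scale <= 1e-12:
            dropped.append(col)
            out = out.drop(columns=[col])
        else:
            out[col] = (x - center) / scale
    if dropped:
        warnings.warn(f"dropping zero-dispersion features: {dropped[:10]}")
    return out


def compute_mith(normalized: pd.DataFrame, sample_id: str,
                 sample_column: str = SAMPLE_COLUMN) -> float:
    """MITH of one sample from the globally normalized feature matrix.

    Returns NaN for samples with fewer than 2 tumor nuclei.
    """
    sub = normalized[normalized[sample_column] == sample_id]
    x = sub.drop(columns=[sample_column]).select_dtypes(include=[np.number]).to_numpy(dtype=float)
    if x.shape[0] < 2:
        warnings.warn(f"sample {sample_id!r}: fewer than 2 tumor nuclei, MITH undefined")
        return float("nan")
    return float(x.std(axis=0, ddof=0).mean())


def mith_table(features: pd.DataFrame, sample_column: str = SAMPLE_COLUMN,
               method: str = "zscore") -> pd.DataFrame:
    """Per-sample MITH table (sample_id, MITH, M nuclei, N features)."""
    normalized = normalize_global(features, method=method, sample_column=sample_column)
    n_features = normalized.drop(columns=[sample_column]).select_dtypes(
        include=[np.number]).shape[1]
    rows = []
    for sid, sub in normalized.groupby(sample_column, sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = compute_mith(normalized, sid, sample_column)
        rows.append({"sample_id": sid, "MITH": value, "M": len(sub), "N": n_features})
    return pd.DataFrame(rows).set_index("sample_id")
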