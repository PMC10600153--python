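"""Per-nucleus morphological and texture features.

Morphology (14 features) is computed from the rasterized contour mask:
region-property style descriptors (area, bounding-box area, equal-moment
ellipse axes and eccentricity, extent, solidity, perimeter, circularity,
elongation) plus four contour-curvature statistics.  Texture (9 features)
comes from a gray-level co-occurrence matrix (GLCM) restricted to pixel
pairs inside the nuclear mask, plus intensity statistics over the masked
pixels.

All features are translation invariant; scaling a contour by s scales Area
by ~s^2 and Perimeter by ~s (up to rasterization).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import polygon as draw_polygon
from skimage.measure import regionprops, label as sk_label
from skimage.morphology import convex_hull_image

MORPH_FEATURE_NAMES = [
    "Area", "AreaBbox", "CellEccentricities", "Circularity", "Elongation",
    "Extent", "MajorAxisLength", "MinorAxisLength", "Perimeter", "Solidity",
    "CurvMean", "CurvMax", "CurvMin", "CurvStd",
]

TEXTURE_FEATURE_NAMES = [
    "ASM", "Contrast", "Correlation", "Entropy", "Homogeneity",
    "IntensityMean", "IntensityStd", "IntensityMax", "IntensityMin",
]

#: four symmetric 1-px offsets: 0, 45, 90, 135 degrees, in (dy, dx)
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
GLCM_LEVELS = 32


class DegenerateContourError(ValueError):
    pass


def rasterize_contour(contour: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterize a closed polygon to a binary mask in its own local frame.

    Returns (mask, (x0, y0)) where (x0, y0) is the pixel offset of the mask
    origin in slide coordinates.
    """
    contour = np.asarray(contour, dtype=float)
    x0 = int(np.floor(contour[:, 0].min()))
    y0 = int(np.floor(contour[:, 1].min()))
    cols = contour[:, 0] - x0
    rows = contour[:, 1] - y0
    h = int(np.ceil(rows.max())) + 1
    w = int(np.ceil(cols.max())) + 1
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    return mask, (x0, y0)


def _resample_closed(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n points at uniform arc length."""
    pts = np.asarray(contour, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise DegenerateContourError("zero-perimeter contour")
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    return np.column_stack([x, y])


def contour_curvature(contour: np.ndarray, n_samples: int = 128,
                      sigma: float = 2.0) -> np.ndarray:
    """Signed curvature along the contour, resampled and Gaussian-smoothed.

    kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2), with periodic
    finite differences; sigma is in units of resampled points, smoothing out
    rasterization noise that would otherwise dominate the extrema.
    """
    pts = _resample_closed(contour, n_samples)
    x = gaussian_filter1d(pts[:, 0], sigma, mode="wrap")
    y = gaussian_filter1d(pts[:, 1], sigma, mode="wrap")
    dx = (np.roll(x, -1) - np.roll(x, 1)) / 2.0
    dy = (np.roll(y, -1) - np.roll(y, 1)) / 2.0
    ddx = np.roll(x, -1) - 2 * x + np.roll(x, 1)
    ddy = np.roll(y, -1) - 2 * y + np.roll(y, 1)
    denom = (dx ** 2 + dy ** 2) ** 1.5
    denom = np.where(denom < 1e-12, np.nan, denom)
    kappa = (dx * ddy - dy * ddx) / denom
    return kappa[np.isfinite(kappa)]


def compute_morphology(contour, bbox=None, nucleus_id: str | None = None) -> dict[str, float]:
    """The 14 morphological features of one nucleus.

    ``bbox`` is (xmin, ymin, xmax, ymax); when omitted, the contour's tight
    bounds are used.  Raises :class:`DegenerateContourError` for zero-area
    contours, naming the nucleus when an id is given.
    """
    contour = np.asarray(contour, dtype=float)
    # shoelace area catches collinear/degenerate polygons before rasterizing
    xs, ys = contour[:, 0], contour[:, 1]
    shoelace = 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))
    mask, _ = rasterize_contour(contour)
    area = float(mask.sum())
    if area == 0 or shoelace < 1e-9:
        raise DegenerateContourError(
            f"nucleus {nucleus_id!r}: zero-area contour"
        )
    if bbox is None:
        xmin, ymin = contour.min(axis=0)
        xmax, ymax = contour.max(axis=0)
    else:
        xmin, ymin, xmax, ymax = bbox
    area_bbox = float(max(xmax - xmin, 1.0) * max(ymax - ymin, 1.0))

    props = regionprops(mask.astype(np.uint8))[0]
    # Crofton estimator: less rasterization bias than the chain-code perimeter
    perimeter = float(props.perimeter_crofton)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    ecc = float(props.eccentricity)
    hull_area = float(convex_hull_image(mask).sum())

    circularity = 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
    extent = area / area_bbox
    solidity = area / hull_area if hull_area > 0 else 0.0
    elongation = 1.0 - (minor / major if major > 0 else 1.0)

    kappa = contour_curvature(contour)
    return {
        "Area": area,
        "AreaBbox": area_bbox,
        "CellEccentricities": ecc,
        "Circularity": circularity,
        "Elongation": elongation,
        "Extent": min(extent, 1.0),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Perimeter": perimeter,
        "Solidity": min(solidity, 1.0),
        "CurvMean": float(np.mean(kappa)),
        "CurvMax": float(np.max(kappa)),
        "CurvMin": float(np.min(kappa)),
        "CurvStd": float(np.std(kappa)),
    }


def masked_glcm(patch: np.ndarray, mask: np.ndarray,
                levels: int = GLCM_LEVELS,
                offsets=GLCM_OFFSETS) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrices restricted to the mask.

    The 8-bit patch is quantized to ``levels`` gray levels; for each offset,
    only pixel pairs with both endpoints inside the mask are counted.
    Returns an array of shape (len(offsets), levels, levels); an offset with
    no valid pair yields an all-zero matrix.
    """
    patch = np.asarray(patch)
    mask = np.asarray(mask, dtype=bool)
    if patch.shape != mask.shape:
        raise ValueError(f"patch {patch.shape} and mask {mask.shape} differ in shape")
    if not mask.any():
        raise ValueError("empty mask")
    q = (patch.astype(np.int64) * levels) // 256
    q = np.clip(q, 0, levels - 1)
    h, w = patch.shape
    out = np.zeros((len(offsets), levels, levels), dtype=float)
    for k, (dy, dx) in enumerate(offsets):
        ys0 = slice(max(0, -dy), min(h, h - dy))
        xs0 = slice(max(0, -dx), min(w, w - dx))
        ys1 = slice(max(0, dy), min(h, h + dy))
        xs1 = slice(max(0, dx), min(w, w + dx))
        valid = mask[ys0, xs0] & mask[ys1, xs1]
        a = q[ys0, xs0][valid]
        b = q[ys1, xs1][valid]
        if a.size == 0:
            continue
        m = np.zeros((levels, levels), dtype=float)
        np.add.at(m, (a, b), 1.0)
        m += m.T  # symmetric
        out[k] = m / m.sum()
    return out


def _glcm_features(glcms: np.ndarray) -> dict[str, float]:
    levels = glcms.shape[-1]
    i = np.arange(levels)[:, None].astype(float)
    j = np.arange(levels)[None, :].astype(float)
    feats = {"ASM": [], "Contrast": [], "Correlation": [], "Entropy": [],
             "Homogeneity": []}
    for p in glcms:
        if p.sum() == 0:
            continue
        feats["ASM"].append(float((p ** 2).sum()))
        feats["Contrast"].append(float((p * (i - j) ** 2).sum()))
        mu_i = float((p * i).sum())
        mu_j = float((p * j).sum())
        var_i = float((p * (i - mu_i) ** 2).sum())
        var_j = float((p * (j - mu_j) ** 2).sum())
        if var_i > 1e-12 and var_j > 1e-12:
            corr = float((p * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
        else:
            corr = 0.0  # zero-variance patch: correlation defined as 0
        feats["Correlation"].append(corr)
        nz = p[p > 0]
        feats["Entropy"].append(float(-(nz * np.log(nz)).sum()))
        feats["Homogeneity"].append(float((p / (1.0 + (i - j) ** 2)).sum()))
    if not feats["ASM"]:
        # mask too small for any pair at any offset: single-pixel conventions
        return {"ASM": 1.0, "Contrast": 0.0, "Correlation": 0.0,
                "Entropy": 0.0, "Homogeneity": 1.0}
    return {k: float(np.mean(v)) for k, v in feats.items()}


def compute_texture(patch: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """The 9 texture features of one nucleus from its grayscale bbox patch.

    GLCM features are averaged over the four 1-px offsets (0/45/90/135 deg);
    intensity statistics use masked pixels only (population SD).
    """
    patch = np.asarray(patch)
    mask = np.asarray(mask, dtype=bool)
    if patch.shape != mask.shape:
        raise ValueError(f"patch {patch.shape} and mask {mask.shape} differ in shape")
    if not mask.any():
        raise ValueError("empty mask")
    vals = patch[mask].astype(float)
    out = _glcm_features(masked_glcm(patch, mask))
    out.update({
        "IntensityMean": float(vals.mean()),
        "IntensityStd": float(vals.std()),
        "IntensityMax": float(vals.max()),
        "IntensityMin": float(vals.min()),
    })
    return out
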