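"""2D radiomics on body-composition compartments.

Features are computed on the unfiltered ("original") image after resampling
to a fixed 2 mm grid: first-order intensity statistics, 2D shape descriptors
of the tissue mask, and gray-level size-zone matrix (GLSZM) texture features.
A *zone* is a maximal 8-connected set of pixels sharing one discretized gray
level; ``P(i, j)`` counts zones of level ``i`` and size ``j``.

Gray levels use fixed-width, minimum-anchored bins (default 25 HU).  Feature
names follow ``<REGION>_original_<class>_<feature>`` with REGION in
{SM, VAT, SAT}; the printed aliases ``VATI_``/``SATI_`` seen in some reports
are accepted on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.transform import resize

from .phantom import PhantomSlice

logger = logging.getLogger(__name__)

__all__ = [
    "ResampledROI",
    "DiscretizedROI",
    "GLSZMatrix",
    "resample_to_grid",
    "discretize",
    "build_glszm",
    "glszm_features",
    "small_area_emphasis",
    "firstorder_features",
    "shape2d_features",
    "shape2d_perimeter",
    "extract_features",
    "default_registry",
    "normalize_feature_name",
]

TARGET_SPACING = 2.0  # mm
DEFAULT_BIN_WIDTH = 25.0  # HU


@dataclass
class ResampledROI:
    image: np.ndarray
    mask: np.ndarray
    spacing: tuple


@dataclass
class DiscretizedROI:
    levels: np.ndarray  # 1..n_levels inside mask, 0 outside
    mask: np.ndarray
    bin_width: float
    n_levels: int


@dataclass
class GLSZMatrix:
    P: np.ndarray  # (n_levels, max_zone_size); P[i-1, j-1] zones of level i size j
    n_z: int
    n_p: int


def resample_to_grid(image, mask, spacing, target=TARGET_SPACING) -> ResampledROI:
    """Resample image (bilinear) and mask (nearest) to an isotropic grid.

    Output dimensions are ``ceil(native_extent / target)`` per axis.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    sr, sc = spacing
    if sr <= 0 or sc <= 0:
        raise ValueError("native spacing must be > 0")
    out_shape = (
        int(np.ceil(image.shape[0] * sr / target)),
        int(np.ceil(image.shape[1] * sc / target)),
    )
    if out_shape == image.shape and abs(sr - target) < 1e-12 and abs(sc - target) < 1e-12:
        return ResampledROI(image.copy(), mask.copy(), (target, target))
    img_r = resize(image, out_shape, order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    mask_r = resize(mask.astype(float), out_shape, order=0, mode="edge",
                    anti_aliasing=False, preserve_range=True) > 0.5
    return ResampledROI(img_r, mask_r, (target, target))


def discretize(roi: ResampledROI, bin_width: float = DEFAULT_BIN_WIDTH) -> DiscretizedROI:
    """Fixed-bin-width gray-level discretization anchored at the ROI minimum.

    ``level(x) = floor((x - min_in_mask) / bin_width) + 1`` inside the mask.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not roi.mask.any():
        raise ValueError("cannot discretize an empty mask")
    vals = roi.image[roi.mask]
    levels = np.zeros(roi.image.shape, dtype=np.int64)
    levels[roi.mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return DiscretizedROI(levels=levels, mask=roi.mask.copy(),
                          bin_width=bin_width, n_levels=int(levels.max()))


_STRUCT8 = np.ones((3, 3), dtype=int)


def build_glszm(d: DiscretizedROI) -> GLSZMatrix:
    """Count 8-connected equal-level zones into P(level, size)."""
    if not d.mask.any():
        raise ValueError("empty mask")
    n_p = int(d.mask.sum())
    counts = {}  # (level, size) -> zones
    max_size = 1
    for level in range(1, d.n_levels + 1):
        sel = d.levels == level
        if not sel.any():
            continue
        lab, n_comp = ndimage.label(sel, structure=_STRUCT8)
        if n_comp == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz, cnt in zip(*np.unique(sizes, return_counts=True)):
            counts[(level, int(sz))] = counts.get((level, int(sz)), 0) + int(cnt)
            max_size = max(max_size, int(sz))
    P = np.zeros((d.n_levels, max_size), dtype=np.int64)
    for (i, j), c in counts.items():
        P[i - 1, j - 1] = c
    m = GLSZMatrix(P=P, n_z=int(P.sum()), n_p=n_p)
    # marginal identities, asserted on every construction
    j = np.arange(1, max_size + 1)
    assert int((P * j).sum()) == n_p, "GLSZM size marginal != pixel count"
    return m


def small_area_emphasis(m: GLSZMatrix) -> float:
    """SAE = (1/N_z) Σ_ij P(i,j) / j²; in (0, 1], 1 iff all zones singleton."""
    if m.n_z == 0:
        return np.nan
    j = np.arange(1, m.P.shape[1] + 1, dtype=float)
    return float((m.P / j ** 2).sum() / m.n_z)


def glszm_features(m: GLSZMatrix) -> dict:
    if m.n_z == 0:
        return {}
    P = m.P.astype(float)
    nz, npx = m.n_z, m.n_p
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / nz
    pg = P.sum(axis=1)  # per gray level
    ps = P.sum(axis=0)  # per size
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    ent = p[p > 0]
    out = {
        "SmallAreaEmphasis": float((P / j ** 2).sum() / nz),
        "LargeAreaEmphasis": float((P * j ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / nz ** 2),
        "SizeZoneNonUniformity": float((ps ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps ** 2).sum() / nz ** 2),
        "ZonePercentage": float(nz / npx),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (j - mu_j) ** 2).sum()),
        "ZoneEntropy": float(-(ent * np.log2(ent)).sum()),
        "LowGrayLevelZoneEmphasis": float((P / i ** 2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * i ** 2).sum() / nz),
    }
    return out


def firstorder_features(roi: ResampledROI,
                        bin_width: float = DEFAULT_BIN_WIDTH) -> dict:
    """First-order intensity statistics over the masked pixels.

    Entropy is computed on the fixed-bin-width discretized histogram;
    skewness/kurtosis use population moments (kurtosis not excess-corrected).
    """
    if not roi.mask.any():
        return {}
    x = roi.image[roi.mask].astype(float)
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    if sd > 0:
        m3 = ((x - mean) ** 3).mean()
        m4 = ((x - mean) ** 4).mean()
        skew = m3 / sd ** 3
        kurt = m4 / var ** 2
    else:
        skew, kurt = 0.0, 0.0
    levels = np.floor((x - x.min()) / bin_width).astype(int)
    counts = np.bincount(levels).astype(float)
    pmf = counts[counts > 0] / n
    entropy = float(-(pmf * np.log2(pmf)).sum())
    return {
        "Maximum": float(x.max()),
        "Minimum": float(x.min()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "Range": float(x.max() - x.min()),
        "Variance": float(var),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Energy": float((x ** 2).sum()),
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Entropy": entropy,
    }


def shape2d_perimeter(mask, spacing) -> float:
    """Marching-squares perimeter (mm) of a binary mask.

    Total length of the iso-0.5 contour of the zero-padded mask; multiple
    connected components (and interior holes) all contribute.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.nan
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        diffs = np.diff(contour, axis=0)
        diffs[:, 0] *= spacing[0]
        diffs[:, 1] *= spacing[1]
        total += np.hypot(diffs[:, 0], diffs[:, 1]).sum()
    return float(total)


def shape2d_features(mask, spacing) -> dict:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {}
    area = float(mask.sum() * spacing[0] * spacing[1])  # mm²
    perim = shape2d_perimeter(mask, spacing)
    # principal-axis lengths from the second central moments of pixel centers
    rr, cc = np.nonzero(mask)
    pts = np.stack([rr * spacing[0], cc * spacing[1]], axis=1)
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / pts.shape[0]
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.clip(evals, 0.0, None)
    major = 4.0 * np.sqrt(evals[0])
    minor = 4.0 * np.sqrt(evals[1])
    return {
        "PixelSurface": area,
        "Perimeter": perim,
        "PerimeterSurfaceRatio": perim / area,
        "Sphericity": float(2.0 * np.sqrt(np.pi * area) / perim),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": float(np.sqrt(evals[1] / evals[0])) if evals[0] > 0 else np.nan,
    }


def default_registry() -> dict:
    """Feature classes and their declared feature names (all 2D)."""
    return {
        "firstorder": ["Maximum", "Minimum", "Mean", "Median", "Range",
                       "Variance", "Skewness", "Kurtosis", "Energy",
                       "RootMeanSquared", "Entropy"],
        "shape2D": ["PixelSurface", "Perimeter", "PerimeterSurfaceRatio",
                    "Sphericity", "MajorAxisLength", "MinorAxisLength",
                    "Elongation"],
        "glszm": ["SmallAreaEmphasis", "LargeAreaEmphasis",
                  "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
                  "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized",
                  "ZonePercentage", "GrayLevelVariance", "ZoneVariance",
                  "ZoneEntropy", "LowGrayLevelZoneEmphasis",
                  "HighGrayLevelZoneEmphasis"],
    }


_REGION_ALIASES = {"VATI": "VAT", "SATI": "SAT", "SMI": "SM"}


def normalize_feature_name(name: str) -> str:
    """Map printed aliases (``VATI_...``, ``SATI_...``) to canonical names."""
    region, sep, rest = name.partition("_")
    return f"{_REGION_ALIASES.get(region, region)}{sep}{rest}"


def extract_features(slice_: PhantomSlice, masks: dict | None = None,
                     registry: dict | None = None,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     target_spacing: float = TARGET_SPACING) -> dict:
    """Per-region radiomics: resample → discretize → compute registry classes.

    Returns ``{feature_name: value}``; regions whose mask is empty after
    resampling contribute NaNs (logged), never an exception.
    """
    from .bodycomp import segment_all

    registry = registry or default_registry()
    masks = masks or segment_all(slice_)
    out = {}
    for region in ("SM", "VAT", "SAT"):
        tm = masks[region]
        roi = resample_to_grid(slice_.hu_image, tm.mask, tm.spacing,
                               target=target_spacing)
        empty = not roi.mask.any()
        if empty:
            logger.warning("region %s empty after resampling; features NaN",
                           region)
        feats = {}
        if "firstorder" in registry:
            vals = firstorder_features(roi, bin_width) if not empty else {}
            for f in registry["firstorder"]:
                feats[f"{region}_original_firstorder_{f}"] = vals.get(f, np.nan)
        if "shape2D" in registry:
            vals = shape2d_features(roi.mask, roi.spacing) if not empty else {}
            for f in registry["shape2D"]:
                feats[f"{region}_original_shape2D_{f}"] = vals.get(f, np.nan)
        if "glszm" in registry:
            if not empty:
                vals = glszm_features(build_glszm(discretize(roi, bin_width)))
            else:
                vals = {}
            for f in registry["glszm"]:
                feats[f"{region}_original_glszm_{f}"] = vals.get(f, np.nan)
        out.update(feats)
    return out
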