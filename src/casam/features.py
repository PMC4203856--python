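"""Per-region statistical, textural and morphological image measurements.

A catalogue of 55 measurements is computed from the contrast-equalised
image: first-order histogram statistics, gray-level co-occurrence (GLCM,
Haralick-type) texture descriptors, gradient statistics, region morphology
and a box-counting fractal slope.  Applied across the twelve intra-breast
regions through a fixed region map, they assemble into the 489-element
image feature vector that, together with the 15 header-derived predictors,
feeds the volumetric density model.

The region map is configuration: 39 intensity/texture measurements are
recomputed for each of the 12 regions (468 values), 5 coarser-scale GLCM
measurements for the whole breast and the high-signal core (10), and 11
morphology/global measurements for the whole breast only (11), totalling
489.  Feature names are stable: ``<region>__<measurement>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy import ndimage as ndi

from .segmentation import RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "PER_REGION_MEASUREMENTS",
    "DUAL_REGION_MEASUREMENTS",
    "GLOBAL_MEASUREMENTS",
    "MEASUREMENT_NAMES",
    "FEATURE_NAMES",
    "compute_measurements",
    "assemble_feature_vector",
]

#: Measurements recomputed for every one of the 12 regions.
PER_REGION_MEASUREMENTS = (
    "mean", "sd", "skewness", "kurtosis", "entropy", "energy",
    "min", "max", "range", "median", "p05", "p10", "p25", "p75", "p90", "p95",
    "iqr", "cv", "mad", "trimmed_mean", "rms",
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
    "glcm_dissimilarity", "glcm_entropy",
    "grad_mean", "grad_sd", "grad_median", "grad_p90",
    "area_fraction", "n_components", "mean_component_area",
    "perimeter_total", "compactness", "solidity", "eccentricity",
    "fractal_dim",
)

#: Coarser-scale texture, computed for the whole breast and the core only.
DUAL_REGION_MEASUREMENTS = (
    "glcm_contrast_d2", "glcm_correlation_d2", "glcm_energy_d2",
    "glcm_homogeneity_d2", "glcm_entropy_d2",
)

#: Whole-breast morphology and global shape.
GLOBAL_MEASUREMENTS = (
    "shape_area", "shape_perimeter", "shape_eccentricity", "shape_solidity",
    "shape_extent", "shape_major_axis", "shape_minor_axis",
    "shape_orientation", "centroid_row_rel", "centroid_col_rel",
    "edge_fractal_dim",
)

MEASUREMENT_NAMES = PER_REGION_MEASUREMENTS + DUAL_REGION_MEASUREMENTS + GLOBAL_MEASUREMENTS
assert len(MEASUREMENT_NAMES) == 55

_GLCM_LEVELS = 64
_GLCM_OFFSETS = ((0, 1), (1, 0))


@dataclass
class FeatureVector:
    """Named, ordered 489-element image descriptor."""

    names: list[str]
    values: np.ndarray
    region_map: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _entropy_energy(values: np.ndarray, bins: int = 64) -> tuple[float, float]:
    if np.ptp(values) == 0:
        return 0.0, 1.0
    hist, _ = np.histogram(values, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()), float((p**2).sum())


def _glcm(quant: np.ndarray, inside: np.ndarray, distance: int) -> np.ndarray:
    """Symmetric, offset-averaged co-occurrence matrix restricted to a mask.

    ``quant`` holds levels 0.._GLCM_LEVELS-1; pairs with either pixel
    outside ``inside`` are excluded.
    """
    L = _GLCM_LEVELS
    acc = np.zeros((L, L), float)
    for dr, dc in _GLCM_OFFSETS:
        dr, dc = dr * distance, dc * distance
        a = quant[: quant.shape[0] - dr, : quant.shape[1] - dc]
        b = quant[dr:, dc:]
        ok = inside[: inside.shape[0] - dr, : inside.shape[1] - dc] & inside[dr:, dc:]
        if not ok.any():
            continue
        pair = np.ravel_multi_index((a[ok], b[ok]), (L, L))
        m = np.bincount(pair, minlength=L * L).reshape(L, L).astype(float)
        acc += m + m.T  # symmetric
    total = acc.sum()
    return acc / total if total > 0 else acc


def _glcm_props(P: np.ndarray) -> dict[str, float]:
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    var_i = float(((i - mu_i) ** 2 * P).sum())
    var_j = float(((j - mu_j) ** 2 * P).sum())
    if var_i > 0 and var_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * P).sum()) / np.sqrt(var_i * var_j))
    else:
        corr = 1.0
    asm = float((P**2).sum())
    nz = P[P > 0]
    return {
        "contrast": float((P * diff**2).sum()),
        "correlation": corr,
        "energy": float(np.sqrt(asm)),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
        "dissimilarity": float((P * np.abs(diff)).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0,
    }


def _box_count_dim(mask: np.ndarray) -> float:
    """Box-counting fractal slope of a binary mask (Minkowski dimension)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return 0.0
    n = 2 ** int(np.floor(np.log2(min(mask.shape))))
    if n < 4:
        return 0.0
    m = mask[:n, :n]
    sizes, counts = [], []
    size = n
    while size >= 2:
        view = m.reshape(n // size, size, n // size, size)
        occupied = view.any(axis=(1, 3)).sum()
        if occupied > 0:
            sizes.append(size)
            counts.append(occupied)
        size //= 2
    if len(sizes) < 2:
        return 0.0
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)
    return float(slope)


def _shape_props(region: np.ndarray) -> dict[str, float]:
    from skimage import measure

    lab = measure.label(region, connectivity=2)
    props = measure.regionprops(lab)
    if not props:
        return {k: np.nan for k in (
            "n_components", "mean_component_area", "perimeter_total",
            "compactness", "solidity", "eccentricity", "area", "extent",
            "major_axis", "minor_axis", "orientation",
            "centroid_row_rel", "centroid_col_rel",
        )}
    areas = np.array([p.area for p in props], float)
    perim = float(sum(p.perimeter for p in props))
    big = props[int(np.argmax(areas))]
    total_area = float(areas.sum())
    h, w = region.shape
    return {
        "n_components": float(len(props)),
        "mean_component_area": float(areas.mean()),
        "perimeter_total": perim,
        "compactness": 4.0 * np.pi * total_area / perim**2 if perim > 0 else 1.0,
        "solidity": float(big.solidity),
        "eccentricity": float(big.eccentricity),
        "area": total_area,
        "extent": float(big.extent),
        "major_axis": float(big.axis_major_length),
        "minor_axis": float(big.axis_minor_length),
        "orientation": float(big.orientation),
        "centroid_row_rel": float(big.centroid[0] / h),
        "centroid_col_rel": float(big.centroid[1] / w),
    }


def compute_measurements(
    matrix: np.ndarray,
    region: np.ndarray,
    breast_area: int | None = None,
    intensity_range: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Compute the full 55-measurement catalogue for one region.

    ``intensity_range`` fixes the gray-level quantisation window for the
    co-occurrence features (normally the whole-breast range, so levels are
    comparable across regions).  An empty region returns all-NaN values.
    """
    region = np.asarray(region, bool)
    m = np.asarray(matrix, float)
    out: dict[str, float] = {}
    values = m[region]
    if values.size == 0:
        logger.warning("empty region: measurements flagged missing")
        return {k: np.nan for k in MEASUREMENT_NAMES}

    # --- first-order statistics
    sd = float(values.std())
    mean = float(values.mean())
    ent, ene = _entropy_energy(values)
    q = np.percentile(values, [5, 10, 25, 50, 75, 90, 95])
    out.update(
        mean=mean, sd=sd,
        skewness=float(sps.skew(values)) if sd > 0 else 0.0,
        kurtosis=float(sps.kurtosis(values)) if sd > 0 else 0.0,
        entropy=ent, energy=ene,
        min=float(values.min()), max=float(values.max()),
        range=float(np.ptp(values)), median=float(q[3]),
        p05=float(q[0]), p10=float(q[1]), p25=float(q[2]),
        p75=float(q[4]), p90=float(q[5]), p95=float(q[6]),
        iqr=float(q[4] - q[2]),
        cv=sd / mean if mean != 0 else 0.0,
        mad=float(np.median(np.abs(values - q[3]))),
        trimmed_mean=float(sps.trim_mean(values, 0.1)),
        rms=float(np.sqrt(np.mean(values**2))),
    )

    # --- co-occurrence texture
    lo, hi = intensity_range if intensity_range is not None else (values.min(), values.max())
    span = hi - lo if hi > lo else 1.0
    quant = np.clip(((m - lo) / span) * (_GLCM_LEVELS - 1), 0, _GLCM_LEVELS - 1)
    quant = quant.astype(np.intp)
    for dist, suffix in ((1, ""), (2, "_d2")):
        props = _glcm_props(_glcm(quant, region, dist))
        if suffix:
            for k in ("contrast", "correlation", "energy", "homogeneity", "entropy"):
                out[f"glcm_{k}{suffix}"] = props[k]
        else:
            for k in ("contrast", "correlation", "energy", "homogeneity",
                      "dissimilarity", "entropy"):
                out[f"glcm_{k}"] = props[k]

    # --- gradient statistics (on the region-masked image, so the values do
    # not depend on pixels outside the region)
    gm = np.hypot(ndi.sobel(m * region, axis=0), ndi.sobel(m * region, axis=1))
    gv = gm[region]
    out.update(
        grad_mean=float(gv.mean()), grad_sd=float(gv.std()),
        grad_median=float(np.median(gv)), grad_p90=float(np.percentile(gv, 90)),
    )

    # --- morphology
    shp = _shape_props(region)
    denom = float(breast_area) if breast_area else float(region.size)
    out.update(
        area_fraction=float(region.sum()) / denom,
        n_components=shp["n_components"],
        mean_component_area=shp["mean_component_area"],
        perimeter_total=shp["perimeter_total"],
        compactness=shp["compactness"],
        solidity=shp["solidity"],
        eccentricity=shp["eccentricity"],
        fractal_dim=_box_count_dim(region),
        shape_area=shp["area"],
        shape_perimeter=shp["perimeter_total"],
        shape_eccentricity=shp["eccentricity"],
        shape_solidity=shp["solidity"],
        shape_extent=shp["extent"],
        shape_major_axis=shp["major_axis"],
        shape_minor_axis=shp["minor_axis"],
        shape_orientation=shp["orientation"],
        centroid_row_rel=shp["centroid_row_rel"],
        centroid_col_rel=shp["centroid_col_rel"],
        edge_fractal_dim=_box_count_dim(region ^ ndi.binary_erosion(region)),
    )
    assert set(out) == set(MEASUREMENT_NAMES)
    return out


def _build_names() -> tuple[list[str], dict[str, tuple[str, ...]]]:
    from .config import DEFAULT_REGION_LABELS

    names: list[str] = []
    region_map: dict[str, tuple[str, ...]] = {}
    for label in DEFAULT_REGION_LABELS:
        names.extend(f"{label}__{m}" for m in PER_REGION_MEASUREMENTS)
    region_map.update({m: DEFAULT_REGION_LABELS for m in PER_REGION_MEASUREMENTS})
    for label in ("breast", "core"):
        names.extend(f"{label}__{m}" for m in DUAL_REGION_MEASUREMENTS)
    region_map.update({m: ("breast", "core") for m in DUAL_REGION_MEASUREMENTS})
    names.extend(f"breast__{m}" for m in GLOBAL_MEASUREMENTS)
    region_map.update({m: ("breast",) for m in GLOBAL_MEASUREMENTS})
    return names, region_map


#: The stable 489-name ordering of the image feature vector.
FEATURE_NAMES, _REGION_MAP = _build_names()
assert len(FEATURE_NAMES) == 489


def assemble_feature_vector(matrix: np.ndarray, regions: RegionSet) -> FeatureVector:
    """Assemble the 489-element feature vector for one mammogram.

    ``matrix`` is the contrast-equalised image; measurements for an empty
    region are imputed with the whole-breast values (and logged), so the
    vector is always finite and model-ready.
    """
    breast = regions["breast"]
    breast_area = int(breast.sum())
    vals = np.asarray(matrix, float)[breast]
    intensity_range = (float(vals.min()), float(vals.max())) if vals.size else (0.0, 1.0)

    per_region: dict[str, dict[str, float]] = {}
    for label, region in zip(regions.labels, regions.regions):
        per_region[label] = compute_measurements(
            matrix, region, breast_area=breast_area, intensity_range=intensity_range
        )
    fallback = per_region["breast"]
    for label, meas in per_region.items():
        if label != "breast" and not np.isfinite(list(meas.values())).all():
            logger.info("region %s empty; imputing with whole-breast measurements", label)
            per_region[label] = {
                k: (v if np.isfinite(v) else fallback[k]) for k, v in meas.items()
            }

    values = []
    for name in FEATURE_NAMES:
        label, meas = name.split("__", 1)
        values.append(per_region[label][meas])
    return FeatureVector(names=list(FEATURE_NAMES), values=np.asarray(values), region_map=dict(_REGION_MAP))
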