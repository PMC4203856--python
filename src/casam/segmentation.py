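"""Breast segmentation and the area-based percent-density statistic.

The chain mirrors a fully automated area-density workflow for processed
mammograms: empty-margin cropping, pseudo-colour breast masking, pectoral
muscle removal (MLO views), contrast limited adaptive histogram
equalisation (CLAHE), morphological background subtraction, a catalogue of
seven intra-breast thresholding methods yielding twelve analysis regions,
and finally the square-root area percent-density statistic

    PD_area = sqrt(100 * |dense| / |breast|)

where |dense| and |breast| are pixel counts of the segmented dense-tissue
and whole-breast regions.  The square root symmetrises the right-skewed
percent-density distribution; the statistic lives in [0, 10].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import exposure, filters, morphology, measure

from .config import SegmentationConfig, DEFAULT_SEGMENTATION
from .io import ProcessedMammogram, normalize_orientation

logger = logging.getLogger(__name__)

__all__ = [
    "BreastMask",
    "RegionSet",
    "SegmentationResult",
    "crop_borders",
    "compute_breast_mask",
    "remove_pectoral",
    "apply_clahe",
    "background_subtract",
    "compute_cutoffs",
    "define_regions",
    "segment_dense",
    "casam_area",
    "segment_mammogram",
]


@dataclass
class BreastMask:
    """Binary breast mask with the pectoral muscle split out."""

    mask: np.ndarray
    pectoral_mask: np.ndarray
    convexity_applied: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        self.pectoral_mask = np.asarray(self.pectoral_mask, bool)
        if self.mask.shape != self.pectoral_mask.shape:
            raise ValueError("mask and pectoral_mask shapes differ")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionSet:
    """Twelve intra-breast analysis regions derived from seven cut-offs."""

    cutoffs: np.ndarray          # 7 values, sorted ascending
    regions: list[np.ndarray]    # 12 binary matrices
    labels: tuple[str, ...]      # 12 names

    def __post_init__(self) -> None:
        self.cutoffs = np.sort(np.asarray(self.cutoffs, float))
        if self.cutoffs.size != 7:
            raise ValueError("exactly 7 cut-offs required")
        if len(self.regions) != 12 or len(self.labels) != 12:
            raise ValueError("exactly 12 regions/labels required")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.regions[self.labels.index(label)]


@dataclass
class SegmentationResult:
    """Everything the segmentation chain produces for one mammogram.

    All matrices are on the oriented, uncropped image grid; ``crop`` records
    the row/column slices that bounded the analysis window.
    """

    image: ProcessedMammogram
    breast: BreastMask
    dense_mask: np.ndarray
    regions: RegionSet
    clahe_image: np.ndarray
    bg_subtracted: np.ndarray
    crop: tuple[slice, slice]

    @property
    def dense_fraction(self) -> float:
        return float(self.dense_mask.sum()) / float(self.breast.mask.sum())

    @property
    def casam_area(self) -> float:
        return casam_area(self.dense_mask, self.breast.mask)


# ---------------------------------------------------------------------------
# cropping


def crop_borders(
    img: ProcessedMammogram, config: SegmentationConfig = DEFAULT_SEGMENTATION
) -> tuple[ProcessedMammogram, tuple[slice, slice]]:
    """Trim empty (air-only) margin rows and columns.

    A row/column is empty when essentially none of its pixels rise above a
    small fraction of the intensity range.  If trimming would discard more
    than half of the non-background pixels the input is returned unchanged
    with a warning (the heuristic has clearly misfired).
    """
    px = img.pixels
    thr = config.crop_background_fraction * img.max_value
    signal = px > thr
    col_keep = signal.mean(axis=0) > 0.002
    row_keep = signal.mean(axis=1) > 0.002
    if not col_keep.any() or not row_keep.any():
        return img, (slice(0, px.shape[0]), slice(0, px.shape[1]))
    r0, r1 = np.flatnonzero(row_keep)[[0, -1]]
    c0, c1 = np.flatnonzero(col_keep)[[0, -1]]
    rows, cols = slice(int(r0), int(r1) + 1), slice(int(c0), int(c1) + 1)
    kept = signal[rows, cols].sum()
    if kept < 0.5 * signal.sum():
        warnings.warn("cropping would remove most of the signal; skipped")
        return img, (slice(0, px.shape[0]), slice(0, px.shape[1]))
    if rows == slice(0, px.shape[0]) and cols == slice(0, px.shape[1]):
        return img, (rows, cols)
    return replace(img, pixels=px[rows, cols].copy()), (rows, cols)


# ---------------------------------------------------------------------------
# breast mask


def _q_channel(rgb: np.ndarray) -> np.ndarray:
    # NTSC YIQ chroma: positive Q for reddish colours
    return 0.211456 * rgb[..., 0] - 0.522591 * rgb[..., 1] + 0.311135 * rgb[..., 2]


def compute_breast_mask(
    img: ProcessedMammogram, config: SegmentationConfig = DEFAULT_SEGMENTATION
) -> BreastMask:
    """Extract the breast from the air background.

    The grayscale image is mapped through a pseudo-colour map chosen so that
    tissue renders reddish while air does not; thresholding the NTSC Q
    (chroma) channel at Q > 0 separates tissue from background.  The result
    is cleaned up (small objects and holes removed), reduced to the single
    connected component touching the chest-wall (left) edge and regularised
    with its convex hull, which smooths the skin line.
    """
    from matplotlib import colormaps

    px = img.pixels
    if px.max() == 0:
        raise ValueError("no breast found: image is empty")
    norm = px.astype(float) / img.max_value
    rgb = np.asarray(colormaps[config.pseudo_colormap](norm))[..., :3]
    q = _q_channel(rgb)
    raw = (q > 0) & (norm > config.crop_background_fraction)
    if not raw.any():
        raise ValueError("no breast found: pseudo-colour chroma signal empty")

    raw = morphology.remove_small_objects(raw, max_size=max(64, raw.size // 2000))
    raw = binary_fill_holes(raw)
    lab = measure.label(raw, connectivity=2)
    touching = np.unique(lab[:, 0])
    touching = touching[touching > 0]
    if touching.size == 0:
        # fall back to the largest component
        sizes = np.bincount(lab.ravel())[1:]
        if sizes.size == 0:
            raise ValueError("no breast found")
        comp = lab == (1 + int(np.argmax(sizes)))
    else:
        sizes = {int(t): int((lab == t).sum()) for t in touching}
        comp = lab == max(sizes, key=sizes.get)
    hull = morphology.convex_hull_image(comp)
    return BreastMask(mask=hull, pectoral_mask=np.zeros_like(hull), convexity_applied=True)


# ---------------------------------------------------------------------------
# pectoral muscle


def remove_pectoral(
    img: ProcessedMammogram,
    breast: BreastMask,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> BreastMask:
    """Detect and remove the pectoral muscle from an MLO breast mask.

    The muscle shows as a bright wedge in the oriented upper-left corner.
    Candidate pixels (above the Otsu cut-off of the upper-left breast
    window) are reduced to the connected component touching both the top
    and left edges; a straight line is fitted to its lower-right boundary
    and everything above-left of the line is assigned to the pectoral mask.
    CC views carry no pectoral muscle: the call is a no-op.
    """
    if img.view != "MLO":
        logger.info("remove_pectoral: non-MLO view, nothing to do")
        return breast
    px = img.pixels
    mask = breast.mask
    h, w = mask.shape
    win = np.zeros_like(mask)
    win[: int(0.7 * h), : int(0.7 * w)] = True
    sel = mask & win
    vals = px[sel]
    if vals.size < 16 or vals.max() == vals.min():
        return breast
    thr = filters.threshold_otsu(vals)
    cand = sel & (px >= thr)
    cand = morphology.remove_small_objects(cand, max_size=max(32, mask.size // 5000))
    lab = measure.label(cand, connectivity=2)
    top = set(np.unique(lab[0, :])) - {0}
    left = set(np.unique(lab[:, 0])) - {0}
    ids = top & left
    if not ids:
        ids = {i for i in top if (lab[: max(1, h // 10), 0] == i).any()}
    if not ids:
        return breast
    comp = np.isin(lab, list(ids))
    comp = binary_fill_holes(comp)
    if comp.sum() < config.pectoral_min_area_fraction * mask.sum():
        return breast

    rows = np.flatnonzero(comp.any(axis=1))
    edge_r, edge_c = [], []
    for r in rows:
        edge_r.append(r)
        edge_c.append(np.flatnonzero(comp[r])[-1])
    edge_r, edge_c = np.asarray(edge_r, float), np.asarray(edge_c, float)
    if edge_r.size >= 3 and np.ptp(edge_r) > 0:
        slope, intercept = np.polyfit(edge_r, edge_c, 1)
    else:
        slope, intercept = 0.0, float(edge_c.mean())
    rr = np.arange(h, dtype=float)
    boundary = intercept + slope * rr
    pect = (np.arange(w)[None, :] <= boundary[:, None]) & mask
    # never allow the line to claim the bulk of the breast
    if pect.sum() > 0.5 * mask.sum():
        pect = comp & mask
    new_mask = mask & ~pect
    return BreastMask(
        mask=new_mask,
        pectoral_mask=breast.pectoral_mask | pect,
        convexity_applied=breast.convexity_applied,
    )


# ---------------------------------------------------------------------------
# intensity pre-processing


def apply_clahe(
    img: ProcessedMammogram,
    breast: BreastMask,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> np.ndarray:
    """Contrast limited adaptive histogram equalisation within the breast.

    Returns a float matrix on the native intensity scale [0, 2^bit_depth-1],
    zero outside the breast mask.  Deterministic.
    """
    px = img.pixels.astype(float) / img.max_value
    ny, nx = config.clahe_tiles
    h, w = px.shape
    kernel = (max(2, h // ny), max(2, w // nx))
    eq = exposure.equalize_adapthist(px, kernel_size=kernel, clip_limit=config.clahe_clip_limit)
    out = eq * img.max_value
    out[~breast.mask] = 0.0
    return out


def background_subtract(
    matrix: np.ndarray, radius: int | None = None,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> np.ndarray:
    """Subtract the morphologically opened image from the original.

    Opening with a disk structuring element removes any bright structure
    narrower than the disk; the difference (a white top-hat) therefore
    keeps small/thin bright detail and suppresses broad background,
    easing the low dense/fatty contrast.  Output is clipped at zero.
    """
    r = config.opening_radius_px if radius is None else radius
    m = np.asarray(matrix, float)
    # the decomposed (octagonal) disk is within a pixel of the exact disk
    # and an order of magnitude faster on full-size images
    footprint = morphology.disk(r, decomposition="sequence" if r >= 8 else None)
    opened = morphology.opening(m, footprint)
    return np.clip(m - opened, 0.0, None)


# ---------------------------------------------------------------------------
# multi-thresholding


def _kapur_entropy_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Maximum-entropy (Kapur) threshold: maximise the summed Shannon
    entropies of the sub-histograms below and above the cut."""
    hist, edges = np.histogram(values, bins=nbins)
    p = hist.astype(float) / hist.sum()
    c = np.cumsum(p)
    best, best_t = -np.inf, 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in range(1, nbins):
            w0, w1 = c[t - 1], 1.0 - c[t - 1]
            if w0 <= 0 or w1 <= 0:
                continue
            p0 = p[:t] / w0
            p1 = p[t:] / w1
            h0 = -np.nansum(np.where(p0 > 0, p0 * np.log(p0), 0.0))
            h1 = -np.nansum(np.where(p1 > 0, p1 * np.log(p1), 0.0))
            if h0 + h1 > best:
                best, best_t = h0 + h1, t
    return float(edges[best_t])


_THRESHOLD_FUNCS = {
    "otsu": lambda v: float(filters.threshold_otsu(v)),
    "isodata": lambda v: float(np.atleast_1d(filters.threshold_isodata(v))[0]),
    "mean": lambda v: float(v.mean()),
    "median": lambda v: float(np.median(v)),
    "triangle": lambda v: float(filters.threshold_triangle(v)),
    "max_entropy": _kapur_entropy_threshold,
    "li": lambda v: float(filters.threshold_li(v)),
}


def compute_cutoffs(
    matrix: np.ndarray,
    mask: np.ndarray,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> np.ndarray:
    """Apply the configured seven thresholding methods to the breast pixels.

    Returns the cut-offs in the configured method order.  A degenerate
    (single-valued) histogram yields seven identical cut-offs and a warning.
    """
    values = np.asarray(matrix, float)[np.asarray(mask, bool)]
    if values.size == 0:
        raise ValueError("empty mask: no pixels to threshold")
    if np.ptp(values) == 0:
        warnings.warn("degenerate histogram: all breast pixels share one value")
        return np.full(len(config.threshold_methods), float(values[0]))
    out = []
    for name in config.threshold_methods:
        try:
            out.append(_THRESHOLD_FUNCS[name](values))
        except KeyError:
            raise ValueError(f"unknown thresholding method {name!r}") from None
    return np.asarray(out, float)


def define_regions(
    cutoffs: np.ndarray,
    matrix: np.ndarray,
    mask: np.ndarray,
    bg_subtracted: np.ndarray | None = None,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> RegionSet:
    """Build the twelve intra-breast analysis regions.

    From the sorted cut-offs c1 <= ... <= c7:

    * ``layer_k`` (k = 1..6): pixels with intensity >= c_k — a nested family
      of upper threshold sets;
    * ``band_k`` (k = 1..4): pixels in [c_{k+1}, c_{k+2}) — slices through
      the mid-histogram;
    * ``breast``: the whole (pectoral-free) breast mask;
    * ``core``: high-signal set of the background-subtracted image (its own
      Otsu cut within the breast).

    Regions overlap by design; they do not partition the breast.
    """
    mask = np.asarray(mask, bool)
    m = np.asarray(matrix, float)
    c = np.sort(np.asarray(cutoffs, float))
    regions: list[np.ndarray] = []
    for k in range(6):
        regions.append((m >= c[k]) & mask)
    for k in range(4):
        regions.append((m >= c[k + 1]) & (m < c[k + 2]) & mask)
    regions.append(mask.copy())
    if bg_subtracted is None:
        core = regions[2].copy()
    else:
        bg = np.asarray(bg_subtracted, float)
        vals = bg[mask]
        if vals.size and np.ptp(vals) > 0:
            core = (bg >= filters.threshold_otsu(vals)) & mask
        else:
            core = np.zeros_like(mask)
    regions.append(core)
    return RegionSet(cutoffs=c, regions=regions, labels=tuple(config.region_labels))


def segment_dense(
    matrix: np.ndarray,
    mask: np.ndarray,
    regions: RegionSet,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> np.ndarray:
    """Select the dense-tissue mask from the multi-threshold family.

    Default rule: threshold the contrast-equalised image at the median of
    the seven cut-offs — robust to any single method misfiring.  A fixed
    ``layer_k`` rule can be configured instead.
    """
    mask = np.asarray(mask, bool)
    if config.dense_rule == "median":
        thr = float(np.median(regions.cutoffs))
        return (np.asarray(matrix, float) >= thr) & mask
    if config.dense_rule.startswith("layer_"):
        return regions[config.dense_rule] & mask
    raise ValueError(f"unknown dense rule {config.dense_rule!r}")


def casam_area(dense: np.ndarray, breast: np.ndarray) -> float:
    """Square-root area percent density: sqrt(100 * |dense| / |breast|).

    ``dense`` must be a subset of ``breast``; the value lies in [0, 10]
    (10 means the whole breast is dense).
    """
    dense = np.asarray(dense, bool)
    breast = np.asarray(breast, bool)
    nb = int(breast.sum())
    if nb == 0:
        raise ValueError("empty breast mask")
    if (dense & ~breast).any():
        raise ValueError("dense mask extends outside the breast mask")
    return float(np.sqrt(100.0 * dense.sum() / nb))


# ---------------------------------------------------------------------------
# full chain


def _embed(arr: np.ndarray, shape: tuple[int, int], crop: tuple[slice, slice]) -> np.ndarray:
    if arr.shape == shape:
        return arr
    out = np.zeros(shape, dtype=arr.dtype)
    out[crop] = arr
    return out


def segment_mammogram(
    img: ProcessedMammogram,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> SegmentationResult:
    """Run the whole chain: orient, crop, mask, de-pectoralise, CLAHE,
    background-subtract, multi-threshold, twelve regions, dense mask.

    All returned matrices are embedded back onto the oriented full-image
    grid, so they can be compared directly with ground-truth masks.
    Deterministic: identical input gives identical output.
    """
    oriented = normalize_orientation(img)
    shape = oriented.pixels.shape
    cropped, crop = crop_borders(oriented, config)
    breast = compute_breast_mask(cropped, config)
    breast = remove_pectoral(cropped, breast, config)
    eq = apply_clahe(cropped, breast, config)
    bg = background_subtract(cropped.pixels.astype(float), config=config)
    bg[~breast.mask] = 0.0
    cutoffs = compute_cutoffs(eq, breast.mask, config)
    regions = define_regions(cutoffs, eq, breast.mask, bg, config)
    dense = segment_dense(eq, breast.mask, regions, config)

    breast_full = BreastMask(
        mask=_embed(breast.mask, shape, crop),
        pectoral_mask=_embed(breast.pectoral_mask, shape, crop),
        convexity_applied=breast.convexity_applied,
    )
    regions_full = RegionSet(
        cutoffs=regions.cutoffs,
        regions=[_embed(r, shape, crop) for r in regions.regions],
        labels=regions.labels,
    )
    return SegmentationResult(
        image=oriented,
        breast=breast_full,
        dense_mask=_embed(dense, shape, crop),
        regions=regions_full,
        clahe_image=_embed(eq, shape, crop),
        bg_subtracted=_embed(bg, shape, crop),
        crop=crop,
    )
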