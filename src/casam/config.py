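"""Configuration for the segmentation and feature pipeline.

The multi-threshold catalogue, the 12-region scheme and the CLAHE settings
are deliberately configuration rather than code: the method's contract is
the *structure* (7 cut-offs, 12 intra-breast regions, a fixed-length feature
vector), while the exact catalogue entries are tunable choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: The seven intra-breast thresholding methods, applied to the
#: contrast-equalised breast pixels.  Order is part of the contract.
DEFAULT_THRESHOLD_METHODS = (
    "otsu",
    "isodata",
    "mean",
    "median",
    "triangle",
    "max_entropy",
    "li",
)

#: The 12 intra-breast region labels.  Layer regions are upper threshold
#: sets (pixels at or above a cut-off); band regions are slices between
#: cut-offs; ``breast`` is the whole (pectoral-free) breast; ``core`` is the
#: high-signal set of the background-subtracted image.
DEFAULT_REGION_LABELS = (
    "layer_1", "layer_2", "layer_3", "layer_4", "layer_5", "layer_6",
    "band_1", "band_2", "band_3", "band_4",
    "breast", "core",
)


@dataclass
class SegmentationConfig:
    """Tunables for the pre-processing and segmentation chain.

    Attributes
    ----------
    clahe_clip_limit : float
        CLAHE clip limit as a fraction of the intensity range.
    clahe_tiles : tuple
        CLAHE tile grid (rows, cols).
    opening_radius_px : int
        Radius of the disk structuring element for morphological background
        subtraction, in pixels at the native resolution of the study images
        (~100 um pixels); scale with pixel spacing for other resolutions.
    threshold_methods : tuple of str
        The 7 cut-off methods, in order.
    dense_rule : str
        Which cut-off defines the dense mask: ``median`` (median of the 7
        cut-offs applied to the equalised image, the default) or
        ``layer_k`` for a fixed layer.
    pseudo_colormap : str
        Matplotlib colormap used for the pseudo-colour breast-masking step;
        must map tissue intensities into positive chroma (reddish) under the
        NTSC Q channel and air into non-positive chroma.
    """

    clahe_clip_limit: float = 0.003
    clahe_tiles: tuple[int, int] = (8, 8)
    opening_radius_px: int = 50
    threshold_methods: tuple[str, ...] = DEFAULT_THRESHOLD_METHODS
    region_labels: tuple[str, ...] = DEFAULT_REGION_LABELS
    dense_rule: str = "median"
    pseudo_colormap: str = "Reds"
    crop_background_fraction: float = 0.02  # of max value; below = empty margin
    pectoral_min_area_fraction: float = 0.005

    def __post_init__(self) -> None:
        if len(self.threshold_methods) != 7:
            raise ValueError("exactly 7 thresholding methods are required")
        if len(self.region_labels) != 12:
            raise ValueError("exactly 12 region labels are required")


DEFAULT_SEGMENTATION = SegmentationConfig()
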