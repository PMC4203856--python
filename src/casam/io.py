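"""Reading processed mammograms and their acquisition headers.

Processed ("for presentation") full-field digital mammograms arrive either as
DICOM files or, for synthetic fixtures, as a plain PNG/TIFF pixel matrix with
a JSON sidecar holding the header fields.  After loading, images are always
bright-is-dense: fibroglandular tissue has high intensity, air is dark.

The X-ray system settings stored in the header (kVp, exposure, tube current,
compressed breast thickness, ...) carry information about breast composition
that survives the vendor's raw-to-processed intensity transform; they are
expanded here into the fixed 15-element predictor set used by the volumetric
model.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionParameters",
    "ProcessedMammogram",
    "AP_FEATURE_NAMES",
    "read_processed_mammogram",
    "write_processed_mammogram",
    "derive_ap_features",
    "normalize_orientation",
]

#: Default mapping from DICOM anode target material names to the numeric
#: 0/1 code used as a model predictor.  Configurable because the coding is
#: device-fleet specific.
DEFAULT_ANODE_CODES = {"MOLYBDENUM": 0.0, "RHODIUM": 1.0, "TUNGSTEN": 1.0}


@dataclass
class AcquisitionParameters:
    """X-ray acquisition settings extracted from the image header.

    Any field may be ``None`` when the corresponding header tag is absent;
    the three tags required by the derived predictor set (exposure time,
    exposure in microampere-seconds, compressed breast thickness) must be
    strictly positive for :func:`derive_ap_features` to succeed.
    """

    kvp: Optional[float] = None                  # kilovolts peak
    exposure_time: Optional[float] = None        # ms
    xray_tube_current: Optional[float] = None    # mA
    exposure: Optional[float] = None             # mAs
    exposure_in_uas: Optional[float] = None      # microampere-seconds
    body_part_thickness: Optional[float] = None  # mm, compressed
    compression_force: Optional[float] = None    # device units (~N)
    anode_target_material: Optional[float] = None  # numeric code in [0, 1]
    relative_xray_exposure: Optional[float] = None  # device units
    organ_dose: Optional[float] = None           # dGy (device units)


@dataclass
class ProcessedMammogram:
    """A processed mammogram: pixel matrix plus acquisition header.

    ``pixels`` is a 2-D non-negative integer array in display-intensity
    units, already converted so that dense tissue is bright.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    laterality: str = "L"            # "L" or "R"
    view: str = "MLO"                # "MLO" or "CC"
    ap: AcquisitionParameters = field(default_factory=AcquisitionParameters)
    source: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D matrix")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel values outside [0, {2**self.bit_depth - 1}] "
                f"for bit depth {self.bit_depth}"
            )
        if self.laterality not in ("L", "R"):
            raise ValueError("laterality must be 'L' or 'R'")
        if self.view not in ("MLO", "CC"):
            raise ValueError("view must be 'MLO' or 'CC'")
        self.pixels = px

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


#: Canonical ordering of the 15 header-derived predictors.
AP_FEATURE_NAMES = (
    "KVP",
    "XTC",
    "ExposureTime",
    "XRayTubeCurrent",
    "Exposure",
    "ExposureInuAs",
    "BodyPartThickness",
    "LogExposureInuAs",
    "InvBodyPartThickness",
    "LogBodyPartThickness",
    "InvExposureInuAs",
    "CompressionForce",
    "AnodeTargetMaterial",
    "RelativeXrayExposure",
    "OrganDose",
)

# DICOM tag keyword -> AcquisitionParameters attribute
_DICOM_AP_MAP = {
    "KVP": "kvp",
    "ExposureTime": "exposure_time",
    "XRayTubeCurrent": "xray_tube_current",
    "Exposure": "exposure",
    "ExposureInuAs": "exposure_in_uas",
    "BodyPartThickness": "body_part_thickness",
    "CompressionForce": "compression_force",
    "RelativeXRayExposure": "relative_xray_exposure",
    "OrganDose": "organ_dose",
}


def derive_ap_features(ap: AcquisitionParameters) -> dict[str, float]:
    """Expand acquisition parameters into the 15 named model predictors.

    XTC is the tube-current proxy ExposureInuAs / ExposureTime; the log and
    reciprocal transforms of exposure and compressed thickness capture the
    roughly multiplicative physics of X-ray attenuation.  Logs are natural.

    Raises
    ------
    ValueError
        If a quantity entering a log or reciprocal is missing or
        non-positive; the message names the offending tag.
    """
    required = {
        "ExposureTime": ap.exposure_time,
        "ExposureInuAs": ap.exposure_in_uas,
        "BodyPartThickness": ap.body_part_thickness,
    }
    for tag, value in required.items():
        if value is None or not math.isfinite(value) or value <= 0:
            raise ValueError(f"acquisition parameter {tag} must be strictly positive, got {value!r}")

    def _f(x: Optional[float]) -> float:
        return float(x) if x is not None else float("nan")

    feats = {
        "KVP": _f(ap.kvp),
        "XTC": float(ap.exposure_in_uas) / float(ap.exposure_time),
        "ExposureTime": float(ap.exposure_time),
        "XRayTubeCurrent": _f(ap.xray_tube_current),
        "Exposure": _f(ap.exposure),
        "ExposureInuAs": float(ap.exposure_in_uas),
        "BodyPartThickness": float(ap.body_part_thickness),
        "LogExposureInuAs": math.log(ap.exposure_in_uas),
        "InvBodyPartThickness": 1.0 / float(ap.body_part_thickness),
        "LogBodyPartThickness": math.log(ap.body_part_thickness),
        "InvExposureInuAs": 1.0 / float(ap.exposure_in_uas),
        "CompressionForce": _f(ap.compression_force),
        "AnodeTargetMaterial": _f(ap.anode_target_material),
        "RelativeXrayExposure": _f(ap.relative_xray_exposure),
        "OrganDose": _f(ap.organ_dose),
    }
    assert tuple(feats) == AP_FEATURE_NAMES
    return feats


def _ap_from_mapping(header: dict, anode_codes: dict[str, float]) -> AcquisitionParameters:
    ap = AcquisitionParameters()
    aliases = {
        "kvp": "kvp", "KVP": "kvp",
        "exposure_time": "exposure_time", "ExposureTime": "exposure_time",
        "xray_tube_current": "xray_tube_current", "XRayTubeCurrent": "xray_tube_current",
        "exposure": "exposure", "Exposure": "exposure",
        "exposure_in_uas": "exposure_in_uas", "ExposureInuAs": "exposure_in_uas",
        "body_part_thickness": "body_part_thickness", "BodyPartThickness": "body_part_thickness",
        "compression_force": "compression_force", "CompressionForce": "compression_force",
        "anode_target_material": "anode_target_material",
        "AnodeTargetMaterial": "anode_target_material",
        "relative_xray_exposure": "relative_xray_exposure",
        "RelativeXrayExposure": "relative_xray_exposure",
        "organ_dose": "organ_dose", "OrganDose": "organ_dose",
    }
    for key, attr in aliases.items():
        if key in header and header[key] is not None:
            val = header[key]
            if attr == "anode_target_material" and isinstance(val, str):
                val = anode_codes.get(val.upper())
                if val is None:
                    warnings.warn(f"unknown anode target material {header[key]!r}; recorded as absent")
                    continue
            setattr(ap, attr, float(val))
    return ap


def read_processed_mammogram(
    path: str | Path,
    anode_codes: dict[str, float] | None = None,
) -> ProcessedMammogram:
    """Read a processed mammogram from DICOM or from an image + JSON sidecar.

    The header dialect is selected by extension: ``.dcm`` is parsed with
    pydicom; anything else is loaded as a grayscale image whose sidecar
    ``<stem>.json`` supplies bit depth, laterality, view, photometric
    polarity and acquisition tags.  Images stored with inverted polarity
    (air bright, as with DICOM MONOCHROME1) are complemented on load so
    dense tissue is always bright.

    Missing pixel data is a hard error; missing individual acquisition tags
    are recorded as absent with a warning.
    """
    path = Path(path)
    codes = DEFAULT_ANODE_CODES if anode_codes is None else anode_codes
    if not path.exists():
        raise FileNotFoundError(path)

    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path), force=True)
        if "PixelData" not in ds:
            raise ValueError(f"{path}: DICOM file has no pixel data")
        px = np.asarray(ds.pixel_array)
        bit_depth = int(getattr(ds, "BitsStored", 0) or int(px.max()).bit_length() or 8)
        inverted = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1"
        header: dict = {}
        for keyword, attr in _DICOM_AP_MAP.items():
            if hasattr(ds, keyword):
                header[attr] = ds.get(keyword)
        if hasattr(ds, "AnodeTargetMaterial"):
            header["anode_target_material"] = str(ds.AnodeTargetMaterial)
        missing = [k for k in _DICOM_AP_MAP if not hasattr(ds, k)]
        if missing:
            warnings.warn(f"{path.name}: acquisition tags absent from header: {', '.join(missing)}")
        laterality = str(getattr(ds, "ImageLaterality", getattr(ds, "Laterality", "L")) or "L")
        view = str(getattr(ds, "ViewPosition", "MLO") or "MLO")
    else:
        import imageio.v3 as iio

        px = np.asarray(iio.imread(str(path)))
        if px.ndim == 3:  # grayscale stored with redundant channels
            px = px[..., 0]
        sidecar = path.with_suffix(".json")
        header = {}
        bit_depth = int(px.max()).bit_length() if px.size else 8
        inverted = False
        laterality, view = "L", "MLO"
        if sidecar.exists():
            header = json.loads(sidecar.read_text())
            bit_depth = int(header.get("bit_depth", bit_depth))
            inverted = header.get("photometric_polarity", "bright-is-dense") == "inverted"
            laterality = header.get("laterality", "L")
            view = header.get("view", "MLO")
        else:
            warnings.warn(f"{path.name}: no JSON sidecar found; acquisition tags recorded as absent")

    px = px.astype(np.int64, copy=False)
    if inverted:
        px = (2**bit_depth - 1) - px
    ap = _ap_from_mapping(header, codes)
    return ProcessedMammogram(
        pixels=px, bit_depth=bit_depth, laterality=laterality, view=view,
        ap=ap, source=str(path),
    )


def write_processed_mammogram(
    img: ProcessedMammogram,
    path: str | Path,
    photometric_polarity: str = "bright-is-dense",
) -> Path:
    """Write a mammogram as 16-bit PNG/TIFF plus a JSON header sidecar.

    Used for synthetic fixtures; round-trips exactly through
    :func:`read_processed_mammogram`.
    """
    import imageio.v3 as iio

    path = Path(path)
    px = img.pixels
    if photometric_polarity == "inverted":
        px = img.max_value - px
    iio.imwrite(str(path), px.astype(np.uint16))
    header = {
        "bit_depth": img.bit_depth,
        "photometric_polarity": photometric_polarity,
        "laterality": img.laterality,
        "view": img.view,
    }
    ap = img.ap
    for attr in (
        "kvp", "exposure_time", "xray_tube_current", "exposure", "exposure_in_uas",
        "body_part_thickness", "compression_force", "anode_target_material",
        "relative_xray_exposure", "organ_dose",
    ):
        val = getattr(ap, attr)
        if val is not None:
            header[attr] = val
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path


def normalize_orientation(img: ProcessedMammogram) -> ProcessedMammogram:
    """Orient the image so breast tissue abuts the left edge.

    Right-breast images are acquired mirrored, with the chest wall on the
    right; segmentation assumes the chest wall (and, for MLO views, the
    pectoral muscle) in the upper-left.  The side is decided from the pixel
    mass of the two image halves, which makes the operation idempotent:
    normalising an already-normalised image changes nothing.
    """
    px = img.pixels
    half = px.shape[1] // 2
    left_mass = float(px[:, :half].sum())
    right_mass = float(px[:, px.shape[1] - half:].sum())
    if right_mass > left_mass:
        return replace(img, pixels=px[:, ::-1].copy())
    return img
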