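"""Synthetic mammogram phantoms and cohort tables with known ground truth.

Two generators make the whole pipeline testable without clinical data:

* :func:`generate_phantom` draws a processed-style MLO mammogram — a
  semicircular breast against a dark background, a triangular pectoral
  wedge in the upper-left, and a blob-textured dense component hitting a
  requested dense-area fraction exactly — pushed through a monotone
  sigmoid intensity curve plus mild unsharp masking that emulates the
  vendor raw-to-processed transform, with a plausible acquisition header.

* :func:`generate_cohort` draws subject tables with the statistical
  structure of a density study: a SNP genotype (additive 0/1/2), age, BMI,
  menopausal status, HRT use, a parity / age-at-first-birth factor,
  correlated density outcomes on their analysis scales (log volumetric,
  sqrt area, predicted log volumetric) with configurable per-allele
  effects, and case-control status from a logistic model on density.

Generator defaults are realistic study conditions: covariate scales and
acquisition-parameter distributions follow published screening-cohort
summaries, per-allele density effects default to published estimates for
a density-associated SNP, and the outcome correlation structure
reproduces the volumetric/area correlations reported for these measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, binary_erosion, binary_dilation

from .io import AcquisitionParameters, ProcessedMammogram

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "CohortConfig",
    "generate_phantom",
    "generate_cohort",
    "generate_case_control_cohort",
    "generate_feature_outcome",
    "vendor_transform",
]


# ---------------------------------------------------------------------------
# phantom images


@dataclass
class PhantomConfig:
    """Tunables for the image phantom.

    ``dense_fraction`` is the target dense-area share of the (pectoral-free)
    breast; the generator hits it exactly by rank-selecting pixels of a
    smoothed random field.  Intensity levels are on a [0, 1] tissue scale
    before the vendor-style transform.
    """

    shape: tuple[int, int] = (320, 256)
    dense_fraction: float = 0.2
    include_pectoral: bool = True
    laterality: str = "L"
    noise_sd: float = 0.035
    fat_level: float = 0.38
    dense_level: float = 0.68
    pectoral_level: float = 0.74
    air_level: float = 0.01
    blob_sigma: float = 10.0
    vendor_curve: bool = True
    unsharp_amount: float = 0.25
    bit_depth: int = 12
    label_strip: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.dense_fraction <= 0.95):
            raise ValueError("dense_fraction must lie in [0, 0.95]")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom, in the as-stored pixel frame."""

    breast_mask: np.ndarray
    pectoral_mask: np.ndarray
    dense_mask: np.ndarray
    dense_fraction: float
    thickness_mm: float
    ap: AcquisitionParameters


def vendor_transform(x: np.ndarray, gain: float = 6.0) -> np.ndarray:
    """Strictly monotone sigmoid contrast curve emulating raw-to-processed
    display conversion.  Input and output on [0, 1]."""
    lo = 1.0 / (1.0 + np.exp(gain * 0.5))
    hi = 1.0 / (1.0 + np.exp(-gain * 0.5))
    y = 1.0 / (1.0 + np.exp(-gain * (np.asarray(x, float) - 0.5)))
    return (y - lo) / (hi - lo)


# Acquisition-parameter distributions matching the published cohort summary
# (means and SDs of the model-development subset).
_AP_DISTS = {
    "kvp": (29.11, 1.17),
    "exposure_time": (721.0, 252.86),
    "xray_tube_current": (68.12, 14.66),
    "exposure": (47.42, 13.40),
    "exposure_in_uas": (47403.0, 13388.0),
    "body_part_thickness": (58.53, 14.53),
    "relative_xray_exposure": (4748.0, 1746.0),
    "organ_dose": (0.010, 0.0022),
    "compression_force": (102.0, 29.69),
}


def _sample_ap(rng: np.random.Generator) -> AcquisitionParameters:
    ap = AcquisitionParameters()
    for attr, (mu, sd) in _AP_DISTS.items():
        lo = 0.05 * mu  # physical quantities are positive
        setattr(ap, attr, float(max(lo, rng.normal(mu, sd))))
    ap.anode_target_material = float(rng.random() < 0.823)
    return ap


def generate_phantom(
    config: PhantomConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[ProcessedMammogram, PhantomTruth]:
    """Draw one phantom mammogram and its ground truth.

    Deterministic given the seed.  The dense mask is the top-k set of a
    Gaussian-smoothed noise field inside the eligible breast interior, with
    k chosen so that |dense| / |breast| equals the requested fraction to
    the nearest pixel.
    """
    cfg = PhantomConfig() if config is None else config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = cfg.shape
    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)

    # semicircular (half-elliptical) breast abutting the left edge
    cy, ry, rx = h / 2.0, 0.46 * h, 0.72 * w
    ellipse = ((rows - cy) / ry) ** 2 + (cols / rx) ** 2 <= 1.0

    # triangular pectoral wedge filling the upper-left corner, as in an MLO
    # view where the muscle runs from the axilla down the chest wall
    pectoral = np.zeros_like(ellipse)
    if cfg.include_pectoral:
        h_left, w_top = 0.55 * h, 0.32 * w
        pectoral = cols / w_top + rows / h_left <= 1.0

    breast = (ellipse | pectoral) & ~pectoral

    # dense component: exact-fraction top-k of a smooth random field
    eligible = binary_erosion(breast, iterations=2)
    if cfg.include_pectoral:
        eligible &= ~binary_dilation(pectoral, iterations=4)
    k = int(round(cfg.dense_fraction * breast.sum()))
    if k > eligible.sum():
        raise ValueError("infeasible dense fraction for this geometry")
    dense = np.zeros_like(breast)
    if k > 0:
        field = gaussian_filter(rng.normal(size=cfg.shape), cfg.blob_sigma)
        flat = np.where(eligible.ravel(), field.ravel(), -np.inf)
        dense.ravel()[np.argpartition(flat, -k)[-k:]] = True

    tissue = np.full(cfg.shape, cfg.air_level)
    tissue[breast] = cfg.fat_level
    tissue[dense] = cfg.dense_level
    tissue[pectoral] = cfg.pectoral_level
    tissue = gaussian_filter(tissue, 0.8)
    noise = rng.normal(0.0, cfg.noise_sd, cfg.shape)
    noise[~(ellipse | pectoral)] *= 0.15  # quiet air background
    tissue = np.clip(tissue + noise, 0.0, 1.0)

    if cfg.vendor_curve:
        tissue = vendor_transform(tissue)
    if cfg.unsharp_amount > 0:
        blur = gaussian_filter(tissue, 3.0)
        tissue = np.clip(tissue + cfg.unsharp_amount * (tissue - blur), 0.0, 1.0)
    if cfg.label_strip:
        r0, r1 = int(0.04 * h), int(0.10 * h)
        c0 = int(0.86 * w)
        strip = np.zeros(cfg.shape, bool)
        strip[r0:r1, c0 : w - 2] = True
        strip &= rng.random(cfg.shape) < 0.55  # text-like speckle
        tissue[strip] = 0.98

    maxv = 2**cfg.bit_depth - 1
    pixels = np.round(tissue * maxv).astype(np.int64)

    ap = _sample_ap(rng)
    if cfg.laterality == "R":
        pixels = pixels[:, ::-1].copy()
        breast, pectoral, dense = (m[:, ::-1].copy() for m in (breast, pectoral, dense))

    img = ProcessedMammogram(
        pixels=pixels, bit_depth=cfg.bit_depth, laterality=cfg.laterality,
        view="MLO", ap=ap,
    )
    truth = PhantomTruth(
        breast_mask=breast, pectoral_mask=pectoral, dense_mask=dense,
        dense_fraction=float(dense.sum()) / float(breast.sum()),
        thickness_mm=float(ap.body_part_thickness), ap=ap,
    )
    return img, truth


# ---------------------------------------------------------------------------
# cohort tables


#: Covariate category frequencies of the genetic-association (control)
#: subset of the published cohort summary, including implicit missingness.
_MENOPAUSE_PROBS = {"pre": 508 / 1011, "post": 477 / 1011, "missing": 26 / 1011}
_HRT_PROBS = {"never": 707 / 1011, "past": 204 / 1011, "current": 42 / 1011, "missing": 58 / 1011}
_PARITY_PROBS = {
    "nulliparous": 101 / 1011,
    "par<=2_afb<=25": 250 / 1011,
    "par<=2_afb>25": 380 / 1011,
    "par>2_afb<=25": 154 / 1011,
    "par>2_afb>25": 99 / 1011,
    "missing": 27 / 1011,
}

PARITY_LEVELS = tuple(k for k in _PARITY_PROBS if k != "missing")


@dataclass
class CohortConfig:
    """Generative model for a density-genetics cohort table.

    Density outcomes share a latent "true density" factor, which induces
    the published cross-measure correlations (about 0.84 between the log
    volumetric and sqrt-area measures, 0.91 between the log volumetric
    measure and its image-based prediction).  Per-allele genotype effects
    act directly on each outcome; case status follows a logistic model on
    the log volumetric measure, so regression on a correlated surrogate
    measure is attenuated by the corresponding regression slope — matching
    the published pattern of case-control estimates.

    Defaults are the published effect estimates and cohort scales.
    """

    n: int = 1011
    maf: float = 0.15
    beta_g_vol: float = -0.138    # per allele, log volumetric scale
    beta_g_area: float = -0.254   # per allele, sqrt-area scale
    beta_g_cvol: float = -0.113   # per allele, predicted log volumetric
    mean_vol: float = 2.01
    mean_area: float = 4.57
    mean_cvol: float = 2.01
    sd_vol: float = 0.56
    sd_area: float = 1.00
    sd_cvol: float = 0.48
    # share of residual outcome variance carried by the latent density
    # factor, calibrated (with the covariate signal) to the published
    # cross-measure correlations of 0.84 and 0.91
    rho_vol: float = 0.85
    rho_area: float = 0.786
    rho_cvol: float = 0.946
    # covariate effects (per unit / per category) on the log volumetric scale;
    # area-scale effects are scaled by sd_area / sd_vol
    beta_age: float = -0.012
    beta_bmi: float = -0.035
    beta_postmeno: float = -0.10
    beta_hrt_current: float = 0.10
    beta_hrt_past: float = 0.02
    beta_parity: float = -0.03    # per step along the parity/AFB factor
    age_mean: float = 53.52
    age_sd: float = 9.45
    bmi_mean: float = 25.92
    bmi_sd: float = 4.46
    case_intercept: float = -3.1  # baseline log-odds of being a case
    case_log_or: float = 0.978    # per unit of the log volumetric measure
    covariate_missingness: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.n < 10:
            raise ValueError("n must be at least 10")
        for name in ("sd_vol", "sd_area", "sd_cvol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _categorical(rng, probs: dict[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], float)
    return np.asarray(keys, object)[rng.choice(len(keys), size=n, p=p / p.sum())]


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a subject table: genotype, covariates, density outcomes, status.

    Genotype is Binomial(2, maf) (Hardy-Weinberg); density outcomes are
    linear in genotype and covariates plus a shared latent factor and
    independent noise; case status is Bernoulli from the logistic case
    model.  Columns are on their analysis scales (``volpara_log``,
    ``casam_area_sqrt``, ``casam_vol``).
    """
    cfg = CohortConfig() if config is None else config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.n

    g = rng.binomial(2, cfg.maf, n).astype(float)
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, n)
    meno_p = _MENOPAUSE_PROBS if cfg.covariate_missingness else {
        k: v for k, v in _MENOPAUSE_PROBS.items() if k != "missing"}
    hrt_p = _HRT_PROBS if cfg.covariate_missingness else {
        k: v for k, v in _HRT_PROBS.items() if k != "missing"}
    par_p = _PARITY_PROBS if cfg.covariate_missingness else {
        k: v for k, v in _PARITY_PROBS.items() if k != "missing"}
    meno = _categorical(rng, meno_p, n)
    hrt = _categorical(rng, hrt_p, n)
    parity = _categorical(rng, par_p, n)

    parity_step = np.array(
        [PARITY_LEVELS.index(p) if p in PARITY_LEVELS else 2 for p in parity], float
    )
    # categorical contributions are centred against their sampling
    # probabilities so the configured outcome means are the marginal means
    def prob(d, key):
        return d.get(key, 0.0) / sum(d.values())

    e_parity = sum(PARITY_LEVELS.index(k) * prob(par_p, k) for k in PARITY_LEVELS)
    e_parity += 2.0 * prob(par_p, "missing")
    covar_lp = (
        cfg.beta_age * (age - cfg.age_mean)
        + cfg.beta_bmi * (bmi - cfg.bmi_mean)
        + cfg.beta_postmeno * ((meno == "post") - prob(meno_p, "post"))
        + cfg.beta_hrt_current * ((hrt == "current") - prob(hrt_p, "current"))
        + cfg.beta_hrt_past * ((hrt == "past") - prob(hrt_p, "past"))
        + cfg.beta_parity * (parity_step - e_parity)
    )

    latent = rng.normal(size=n)

    def outcome(mean, beta_g, sd, rho, scale):
        eps = rng.normal(size=n)
        resid = sd * (np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps)
        return mean + beta_g * (g - 2 * cfg.maf) + scale * covar_lp + resid

    vol = outcome(cfg.mean_vol, cfg.beta_g_vol, cfg.sd_vol, cfg.rho_vol, 1.0)
    area = outcome(cfg.mean_area, cfg.beta_g_area, cfg.sd_area, cfg.rho_area,
                   cfg.sd_area / cfg.sd_vol)
    cvol = outcome(cfg.mean_cvol, cfg.beta_g_cvol, cfg.sd_cvol, cfg.rho_cvol,
                   cfg.sd_cvol / cfg.sd_vol)

    logit = cfg.case_intercept + cfg.case_log_or * (vol - cfg.mean_vol)
    p_case = 1.0 / (1.0 + np.exp(-logit))
    status = np.where(rng.random(n) < p_case, "case", "control")

    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "genotype": g.astype(int),
            "age": age,
            "bmi": bmi,
            "menopausal": meno,
            "hrt": hrt,
            "parity_afb": parity,
            "status": status,
            "volpara_log": vol,
            "casam_area_sqrt": area,
            "casam_vol": cvol,
        }
    )


def generate_feature_outcome(
    n: int = 400,
    p: int = 504,
    n_informative: int = 10,
    loading_range: tuple[float, float] = (0.5, 0.9),
    noise_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Synthetic feature table and log-volumetric outcome with known truth.

    Emulates the structure that makes image features predictive of
    volumetric density: a latent density factor drives both the outcome
    (plus Gaussian noise of ``noise_sd``) and ``n_informative`` features
    (with per-feature loadings drawn from ``loading_range``); the remaining
    features are independent noise.  Returns (features, outcome, latent).
    """
    if n_informative > p:
        raise ValueError("n_informative cannot exceed the number of features")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = rng.normal(size=n)
    X = rng.normal(size=(n, p))
    loadings = rng.uniform(*loading_range, n_informative)
    for j in range(n_informative):
        a = loadings[j]
        X[:, j] = a * latent + np.sqrt(1 - a**2) * X[:, j]
    y = latent + rng.normal(0.0, noise_sd, n)
    cols = [f"feat_{j:03d}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y, latent


def generate_case_control_cohort(
    n_cases: int = 47,
    n_controls: int = 1011,
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample a case-control table with fixed margins.

    Draws from the prospective model of :func:`generate_cohort` until the
    requested numbers of cases and controls are collected — the sampling
    design of a density case-control study.  Logistic slope estimates stay
    consistent under this design; only the intercept shifts.
    """
    cfg = CohortConfig() if config is None else config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cases, controls = [], []
    need_cases, need_controls = n_cases, n_controls
    guard = 0
    while (need_cases > 0 or need_controls > 0) and guard < 200:
        batch = generate_cohort(cfg, rng)
        cases.append(batch[batch["status"] == "case"].iloc[:need_cases])
        controls.append(batch[batch["status"] == "control"].iloc[:need_controls])
        need_cases = n_cases - sum(len(c) for c in cases)
        need_controls = n_controls - sum(len(c) for c in controls)
        guard += 1
    out = pd.concat(cases + controls, ignore_index=True)
    out["id"] = np.arange(1, len(out) + 1)
    return out
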