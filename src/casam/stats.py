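"""Association analysis layer: density ~ genotype and case-control models.

Implements the statistical workflow of a density-genetics study around a
single SNP coded additively 0/1/2:

* linear models of a density measure (on its analysis scale: natural log
  for volumetric, square root for area percent density) on genotype with
  the standard epidemiological adjustment set (age, BMI, menopausal
  status, HRT use, parity / age at first birth), Wald tests and 95% CIs;
* unconditional logistic case-control models of status on a density
  measure with partial (age, BMI) or full adjustment;
* per-feature association scans: Box-Cox transformed image features
  regressed on genotype, summarised by -log10 QQ tables;
* a permutation global test of the null that no feature carries genotype
  association beyond density, age and BMI: the test statistic is the
  number of per-feature Wald p-values below 0.05, referred to its
  distribution over datasets with permuted genotypes.

Missing covariate categories (an explicit ``"missing"`` level) are handled
by complete-case exclusion by default, with a switch to keep them as a
factor level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "AssocResult",
    "STANDARD_ADJUSTERS",
    "transform_density",
    "read_cohort_table",
    "summarize_cohort",
    "fit_genetic_model",
    "fit_case_control_model",
    "boxcox",
    "feature_residuals",
    "permutation_global_test",
    "qq_summary",
    "feature_association_scan",
]

#: The standard adjustment set of the density models.
STANDARD_ADJUSTERS = ("age", "bmi", "menopausal", "hrt", "parity_afb")

_CATEGORICAL = {"menopausal", "hrt", "parity_afb"}

#: Canonical cohort-table columns.
CANONICAL_COLUMNS = (
    "id", "genotype", "age", "bmi", "menopausal", "hrt", "parity_afb",
    "status", "volpara_log", "casam_area_sqrt", "casam_vol",
)


@dataclass
class AssocResult:
    """One fitted association: estimate, 95% Wald CI, p-value, bookkeeping."""

    estimate: float
    ci_low: float
    ci_high: float
    p_wald: float
    n_used: int
    adjustment_set: tuple[str, ...]
    term: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


# ---------------------------------------------------------------------------
# transforms and table IO


def transform_density(values, kind: str) -> np.ndarray:
    """Put a density measure on its analysis scale.

    ``sqrt_area`` for area percent density, ``log_vol`` (natural log) for
    volumetric percent density, ``identity`` otherwise.
    """
    v = np.asarray(values, float)
    if kind == "sqrt_area":
        if (v < 0).any():
            bad = np.flatnonzero(v < 0)
            raise ValueError(f"negative values under sqrt at rows {bad[:10].tolist()}")
        return np.sqrt(v)
    if kind == "log_vol":
        if (v <= 0).any():
            bad = np.flatnonzero(v <= 0)
            raise ValueError(f"non-positive values under log at rows {bad[:10].tolist()}")
        return np.log(v)
    if kind == "identity":
        return v
    raise ValueError(f"unknown transform {kind!r}")


def read_cohort_table(path, column_map: dict | str | None = None) -> pd.DataFrame:
    """Read an analysis cohort table (CSV) into canonical columns.

    ``column_map`` maps canonical names to the file's column names and may
    carry per-column value recodes under a ``values`` key, e.g.::

        {"genotype": "rs_geno", "status": "cc",
         "values": {"status": {"1": "case", "0": "control"}}}

    A YAML/JSON file path is accepted in place of the dict.  Unmapped
    canonical columns are taken verbatim when present.
    """
    if isinstance(column_map, str):
        import yaml

        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
    column_map = dict(column_map or {})
    recodes = column_map.pop("values", {})
    raw = pd.read_csv(path)
    out = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            col = raw[src]
            if canon in recodes:
                col = col.astype(str).map(lambda x, rc=recodes[canon]: rc.get(x, x))
            out[canon] = col
    df = pd.DataFrame(out)
    if "genotype" in df:
        df["genotype"] = pd.to_numeric(df["genotype"])
        bad = ~df["genotype"].isin([0, 1, 2])
        if bad.any():
            raise ValueError(f"genotype values outside 0/1/2 in {int(bad.sum())} rows")
    return df


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort-characteristics summary: mean (sd) or n (%) per variable."""
    rows = []
    for col in ("age", "bmi", "volpara_log", "casam_area_sqrt", "casam_vol"):
        if col in table:
            v = pd.to_numeric(table[col], errors="coerce").dropna()
            rows.append({"variable": col, "level": "", "mean": v.mean(), "sd": v.std(),
                         "n": int(v.size), "percent": np.nan})
    n_total = len(table)
    for col in ("menopausal", "hrt", "parity_afb", "status"):
        if col in table:
            counts = table[col].value_counts(dropna=False)
            for level, n in counts.items():
                rows.append({"variable": col, "level": str(level), "mean": np.nan,
                             "sd": np.nan, "n": int(n), "percent": 100.0 * n / n_total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design matrices


def _design(
    table: pd.DataFrame,
    terms: list[str],
    include_missing_category: bool,
) -> tuple[pd.DataFrame, pd.Index]:
    """Build a design matrix with dummy-coded categoricals.

    Rows with a ``"missing"`` level in any categorical term are dropped
    unless ``include_missing_category`` keeps them as an explicit level.
    Returns the matrix (with intercept) and the index of retained rows.
    """
    df = table.copy()
    keep = pd.Series(True, index=df.index)
    for t in terms:
        if t not in df.columns:
            raise ValueError(f"column {t!r} absent from table")
        if t in _CATEGORICAL and not include_missing_category:
            keep &= df[t].astype(str) != "missing"
        keep &= df[t].notna()
    df = df.loc[keep]
    parts = [pd.Series(1.0, index=df.index, name="const")]
    for t in terms:
        if t in _CATEGORICAL:
            dummies = pd.get_dummies(df[t].astype(str), prefix=t, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(pd.to_numeric(df[t]).astype(float))
    X = pd.concat(parts, axis=1)
    return X, df.index


def _check_collinear(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name columns involved in exact aliasing
        _, r = np.linalg.qr(arr)
        aliased = [X.columns[i] for i in range(arr.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"collinear design; aliased columns: {aliased}")


def _wald(est: float, se: float) -> tuple[float, float, float]:
    z = est / se
    p = 2.0 * sps.norm.sf(abs(z))
    return est - 1.96 * se, est + 1.96 * se, max(p, np.nextafter(0, 1))


# ---------------------------------------------------------------------------
# model fits


def fit_genetic_model(
    table: pd.DataFrame,
    outcome: str,
    extra_adjust: str | None = None,
    include_missing_category: bool = False,
) -> AssocResult:
    """Linear model of a density measure on genotype, standard adjustment.

    Genotype enters as a continuous 0/1/2 allele count; the reported
    estimate is the per-allele effect on the outcome's analysis scale with
    a 95% Wald CI and two-sided normal-reference p-value.  ``extra_adjust``
    adds a second density measure to the adjusters (the "residual
    association" analysis).  Complete-case rows only; n_used is reported.
    """
    terms = ["genotype", *STANDARD_ADJUSTERS]
    if extra_adjust:
        terms.append(extra_adjust)
    X, idx = _design(table, terms, include_missing_category)
    y = pd.to_numeric(table.loc[idx, outcome]).astype(float)
    ok = y.notna()
    X, y = X.loc[ok], y.loc[ok]
    if len(y) < 30:
        raise ValueError(f"only {len(y)} complete-case rows; need at least 30")
    if X["genotype"].nunique() < 2:
        raise ValueError("genotype is constant in the analysis rows")
    _check_collinear(X)
    fit = sm.OLS(y.to_numpy(), X.to_numpy(float)).fit()
    i = list(X.columns).index("genotype")
    lo, hi, p = _wald(fit.params[i], fit.bse[i])
    return AssocResult(
        estimate=float(fit.params[i]), ci_low=float(lo), ci_high=float(hi),
        p_wald=float(p), n_used=int(len(y)),
        adjustment_set=tuple(t for t in terms if t != "genotype"),
        term="genotype",
    )


def fit_case_control_model(
    table: pd.DataFrame,
    density: str,
    adjustment: str = "partial",
    extra_adjust: str | None = None,
    include_missing_category: bool = False,
) -> AssocResult:
    """Unconditional logistic model of case-control status on density.

    ``adjustment="partial"`` adjusts for age and BMI only (guarding against
    over-adjustment with few cases); ``"full"`` uses the standard set.  The
    estimate is the log odds ratio per unit of the density measure on its
    analysis scale.
    """
    if adjustment == "partial":
        adjusters = ["age", "bmi"]
    elif adjustment == "full":
        adjusters = list(STANDARD_ADJUSTERS)
    else:
        raise ValueError("adjustment must be 'partial' or 'full'")
    terms = [density, *adjusters]
    if extra_adjust:
        terms.append(extra_adjust)
    X, idx = _design(table, terms, include_missing_category)
    y = (table.loc[idx, "status"].astype(str) == "case").astype(float)
    n_cases = int(y.sum())
    if n_cases < 10:
        raise ValueError(f"need at least 10 cases, found {n_cases}")
    if n_cases == len(y):
        raise ValueError("no controls in the analysis rows")
    _check_collinear(X)
    model = sm.Logit(y.to_numpy(), X.to_numpy(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = model.fit(disp=0, maxiter=200)
            except Exception:
                # Newton can hit a singular Hessian under quasi-separation in
                # sparse covariate categories; BFGS is slower but stable
                fit = model.fit(disp=0, maxiter=1000, method="bfgs")
    except Exception as e:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic fit failed (possible separation): {e}") from e
    i = list(X.columns).index(density)
    if not np.isfinite(fit.bse[i]) or abs(fit.params[i]) > 50:
        raise ValueError(
            f"separation detected: unbounded estimate for {density} "
            f"(estimate={fit.params[i]:.3g}, se={fit.bse[i]:.3g})"
        )
    if not np.isfinite(fit.bse).all() or np.max(np.abs(fit.params)) > 50:
        bad = [str(c) for c, b, e in zip(X.columns, fit.bse, fit.params)
               if not np.isfinite(b) or abs(e) > 50]
        warnings.warn(f"quasi-separation in nuisance terms: {bad}")
    lo, hi, p = _wald(fit.params[i], fit.bse[i])
    return AssocResult(
        estimate=float(fit.params[i]), ci_low=float(lo), ci_high=float(hi),
        p_wald=float(p), n_used=int(len(y)),
        adjustment_set=tuple(terms[1:]), term=density,
    )


# ---------------------------------------------------------------------------
# feature-level analyses


def boxcox(values, lambda_grid: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Box-Cox transform with maximum-likelihood lambda over a grid.

    The grid is [-2, 2] in steps of 0.05.  Non-positive inputs are shifted
    by (1 - min) before transforming; the shift is applied consistently and
    a constant vector is an error (no information about lambda).
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(v) == 0:
        raise ValueError("constant vector: Box-Cox transform undefined")
    shift = 0.0
    if v.min() <= 0:
        shift = 1.0 - v.min()
        v = v + shift
    if v.min() <= 0:
        raise ValueError("values remain non-positive after shift")
    grid = np.arange(-2.0, 2.0 + 1e-9, 0.05) if lambda_grid is None else np.asarray(lambda_grid)
    lls = np.array([sps.boxcox_llf(lam, v) for lam in grid])
    lam = float(grid[int(np.argmax(lls))])
    transformed = sps.boxcox(v, lmbda=lam)
    return transformed, lam


def feature_residuals(
    features: pd.DataFrame,
    table: pd.DataFrame,
    adjusters: tuple[str, ...] = ("volpara_log", "age", "bmi"),
) -> pd.DataFrame:
    """Least-squares residuals of each feature on the adjuster set.

    Each feature column is regressed (with intercept) on the adjusters;
    the residual matrix keeps the column order.  Zero-variance residuals
    (features exactly explained, or constant) are flagged via a warning so
    downstream tests can drop them.
    """
    for a in adjusters:
        if a not in table.columns:
            raise ValueError(f"adjuster {a!r} absent from table")
    Z = np.column_stack(
        [np.ones(len(table))] + [pd.to_numeric(table[a]).to_numpy(float) for a in adjusters]
    )
    F = features.to_numpy(float)
    beta, *_ = np.linalg.lstsq(Z, F, rcond=None)
    resid = F - Z @ beta
    flat = resid.std(axis=0) < 1e-10
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} features have zero-variance residuals; "
            "exclude them from downstream tests"
        )
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


def _simple_regression_pvalues(Y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Two-sided Wald p-values for per-column simple regressions Y ~ g."""
    n, m = Y.shape
    gc = g - g.mean()
    sgg = float(gc @ gc)
    Yc = Y - Y.mean(axis=0)
    beta = (gc @ Yc) / sgg
    ssy = (Yc**2).sum(axis=0)
    sse = np.maximum(ssy - beta**2 * sgg, 0.0)
    sigma2 = sse / max(n - 2, 1)
    se = np.sqrt(sigma2 / sgg)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    return 2.0 * sps.norm.sf(np.abs(z))


def permutation_global_test(
    residuals: pd.DataFrame | np.ndarray,
    genotype: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Permutation test of the global null that no feature is associated.

    The statistic is the count of per-feature Wald p-values below 0.05
    from simple regressions of the (density/age/BMI-adjusted) feature
    residuals on genotype.  Genotypes are permuted ``n_perm`` times; the
    global p-value uses the add-one estimator
    (1 + #{permuted >= observed}) / (n_perm + 1).  Seed-reproducible.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; the global p-value is coarse")
    Y = residuals.to_numpy(float) if isinstance(residuals, pd.DataFrame) else np.asarray(residuals, float)
    keep = Y.std(axis=0) > 1e-10
    Y = Y[:, keep]
    g = np.asarray(genotype, float)
    if g.size != Y.shape[0]:
        raise ValueError("genotype and residuals are not aligned")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = int((_simple_regression_pvalues(Y, g) < 0.05).sum())
    perm_stats = np.empty(n_perm, int)
    for b in range(n_perm):
        perm_stats[b] = int((_simple_regression_pvalues(Y, rng.permutation(g)) < 0.05).sum())
    p_global = (1.0 + np.sum(perm_stats >= observed)) / (n_perm + 1.0)
    return {
        "observed_statistic": observed,
        "p_global": float(p_global),
        "n_perm": int(n_perm),
        "n_features": int(Y.shape[1]),
        "perm_statistics": perm_stats,
    }


def qq_summary(pvalues) -> pd.DataFrame:
    """-log10 QQ table: observed order statistics vs uniform expectation."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    obs = -np.log10(np.sort(p))
    return pd.DataFrame({"expected": exp, "observed": obs})


def feature_association_scan(
    features: pd.DataFrame,
    table: pd.DataFrame,
    extra_adjust: str | None = None,
    include_missing_category: bool = False,
) -> pd.Series:
    """Per-feature genotype association p-values with standard adjustment.

    Each feature is Box-Cox transformed, then regressed on genotype plus
    the standard adjusters (optionally plus one density measure); the
    two-sided Wald p for genotype is collected.  Feed the result to
    :func:`qq_summary`.
    """
    terms = ["genotype", *STANDARD_ADJUSTERS]
    if extra_adjust:
        terms.append(extra_adjust)
    X, idx = _design(table, terms, include_missing_category)
    Xa = X.to_numpy(float)
    gi = list(X.columns).index("genotype")
    pvals = {}
    for name in features.columns:
        v = pd.to_numeric(features.loc[idx, name]).to_numpy(float)
        if np.ptp(v) == 0:
            pvals[name] = np.nan
            continue
        y, _ = boxcox(v)
        fit = sm.OLS(y, Xa).fit()
        _, _, p = _wald(fit.params[gi], fit.bse[gi])
        pvals[name] = p
    return pd.Series(pvals, name="p_wald")
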