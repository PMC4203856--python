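"""CASAM-Vol: random-forest prediction of log volumetric density.

Volumetric density algorithms (Volpara and kin) operate only on raw
("for processing") mammograms, which clinics rarely store.  CASAM-Vol
side-steps this by learning, on a training set where both image types
exist, a random-forest regression from processed-image features (489 image
measurements + 15 acquisition-parameter predictors) to the natural log of
the volumetric percent density.  Applied to a processed image alone, the
forest output is a volumetric density estimate on the log scale.

The forest uses 500 trees; the variables-tried-per-split (mtry) is the
tuning parameter, selected by out-of-bag error over a small grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor

__all__ = ["VolModel", "train", "predict", "evaluate", "save_model", "load_model"]

DEFAULT_N_TREES = 500


@dataclass
class VolModel:
    """A trained volumetric-density prediction model.

    Prediction refuses feature tables whose column names do not exactly
    match the training manifest, so a model can never silently be applied
    to a differently assembled feature set.
    """

    forest: RandomForestRegressor
    feature_names: list[str]
    seed: int
    n_trees: int
    tuned_mtry: int
    training_summary: dict = field(default_factory=dict)


def _mtry_grid(p: int) -> list[int]:
    grid = {max(1, p // 10), max(1, p // 3), max(1, int(np.sqrt(p))), max(1, p // 2)}
    return sorted(grid)


def train(
    features: pd.DataFrame,
    log_volpara: np.ndarray | pd.Series,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> VolModel:
    """Fit the random forest against the log volumetric reference.

    ``features`` is an n x p table (image features + acquisition-parameter
    predictors, p = 504 in the standard assembly); the outcome must already
    be on the natural-log scale.  mtry is tuned by out-of-bag R^2 over
    {p/10, p/3, sqrt(p), p/2}; ties go to the smaller value.  Deterministic
    given the seed.
    """
    X = features.to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else [
        f"x{i}" for i in range(X.shape[1])
    ]
    y = np.asarray(log_volpara, float)
    if X.shape[0] != y.size:
        raise ValueError("features and outcome lengths differ")
    if X.shape[0] < 50:
        raise ValueError(f"need at least 50 training rows, got {X.shape[0]}")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("training data contain missing or non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; nothing to learn")

    p = X.shape[1]
    best = None
    for mtry in _mtry_grid(p):
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry, oob_score=True,
            random_state=seed, n_jobs=1, bootstrap=True,
        )
        rf.fit(X, y)
        if best is None or rf.oob_score_ > best[1]:
            best = (mtry, rf.oob_score_, rf)
    mtry, oob, rf = best
    train_pred = rf.predict(X)
    summary = {
        "n": int(X.shape[0]),
        "oob_r2": float(oob),
        "train_correlation": float(np.corrcoef(train_pred, y)[0, 1]),
    }
    return VolModel(
        forest=rf, feature_names=names, seed=seed,
        n_trees=n_trees, tuned_mtry=int(mtry), training_summary=summary,
    )


def predict(model: VolModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predict log volumetric density for new processed-image feature rows."""
    if isinstance(features, pd.DataFrame):
        got = list(features.columns)
        if got != model.feature_names:
            missing = [n for n in model.feature_names if n not in got]
            extra = [n for n in got if n not in model.feature_names]
            raise ValueError(
                "feature names do not match the model manifest; "
                f"missing={missing[:5]}{'...' if len(missing) > 5 else ''}, "
                f"unexpected={extra[:5]}{'...' if len(extra) > 5 else ''}"
            )
        X = features.to_numpy(float)
    else:
        X = np.asarray(features, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {X.shape[1]}"
            )
    return model.forest.predict(X)


def evaluate(predictions: np.ndarray, reference: np.ndarray) -> dict:
    """Pearson correlation and paired values for a prediction-vs-reference
    scatter (the standard agreement summary for density measures)."""
    x = np.asarray(predictions, float)
    y = np.asarray(reference, float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return {
        "pearson_r": float(r),
        "p_value": float(p),
        "n": int(x.size),
        "pairs": pd.DataFrame({"prediction": x, "reference": y}),
    }


def save_model(model: VolModel, path: str | Path) -> Path:
    """Persist a model as a joblib archive with a version + name manifest."""
    import joblib

    path = Path(path)
    payload = {
        "format_version": 1,
        "feature_names": model.feature_names,
        "seed": model.seed,
        "n_trees": model.n_trees,
        "tuned_mtry": model.tuned_mtry,
        "training_summary": model.training_summary,
        "forest": model.forest,
    }
    joblib.dump(payload, path)
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps({"format_version": 1, "feature_names": model.feature_names}, indent=1)
    )
    return path


def load_model(path: str | Path) -> VolModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model format: {payload.get('format_version')!r}")
    return VolModel(
        forest=payload["forest"],
        feature_names=payload["feature_names"],
        seed=payload["seed"],
        n_trees=payload["n_trees"],
        tuned_mtry=payload["tuned_mtry"],
        training_summary=payload["training_summary"],
    )
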