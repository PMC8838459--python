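"""Calibration of measured PPG intensities onto the simulated intensity scale.

Measured systolic/diastolic PPG intensities live in arbitrary device units;
the Monte Carlo intensity table lives in detected-weight-per-packet units.
A gradient-boosted regression-tree ensemble (XGBoost) maps the per-subject
feature vector (systolic intensity, diastolic intensity, skewness, kurtosis,
BMI, pulse rate) to the simulated intensity at the subject's reference
pressure — separately for the systolic branch (target: table intensity at
reference SBP) and the diastolic branch (target at reference DBP).  No
per-subject personalization is used.

Model accuracy is reported as the mean R^2 over 10-fold cross-validation
repeated three times with derived seeds; the returned model is refit on all
rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold, cross_val_score
from xgboost import XGBRegressor

__all__ = [
    "FEATURE_COLUMNS",
    "DEFAULT_HYPERPARAMS",
    "CalibrationDataset",
    "CalibrationModel",
    "build_calibration_dataset",
    "fit_calibration",
    "predict_calibrated_intensity",
]

FEATURE_COLUMNS = (
    "systolic_intensity",
    "diastolic_intensity",
    "skewness",
    "kurtosis",
    "bmi",
    "pulse_rate",
)

# Ensemble defaults; all overridable through `hyperparams`.
DEFAULT_HYPERPARAMS = {
    "n_estimators": 300,
    "max_depth": 4,
    "learning_rate": 0.05,
    "subsample": 0.9,
}


@dataclass
class CalibrationDataset:
    """Feature matrix plus simulated-intensity targets for one branch."""

    branch: str                 # "systolic" | "diastolic"
    features: pd.DataFrame      # columns FEATURE_COLUMNS, index subject ids
    targets: np.ndarray         # simulated intensity at the reference pressure
    excluded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        if self.features.isna().any().any() or np.any(~np.isfinite(self.targets)):
            raise ValueError("calibration dataset contains missing values")
        if np.any(self.targets < 0):
            raise ValueError("targets must be non-negative")
        if len(self.features) != len(self.targets):
            raise ValueError("features and targets length mismatch")


@dataclass
class CalibrationModel:
    branch: str
    booster: XGBRegressor
    hyperparams: dict
    cv_r2: float
    cv_scores: np.ndarray
    seed: int
    # the ensemble is fit on the standardized target (tree building loses
    # precision on targets many orders of magnitude below 1); predictions
    # are mapped back with this affine transform
    y_mean: float = 0.0
    y_scale: float = 1.0

    @property
    def feature_importances(self) -> pd.Series:
        """Gain-based importance per feature, normalized to sum to 1."""
        score = self.booster.get_booster().get_score(importance_type="gain")
        vals = np.array([score.get(f"f{i}", 0.0)
                         for i in range(len(FEATURE_COLUMNS))])
        total = vals.sum()
        return pd.Series(vals / total if total > 0 else vals,
                         index=list(FEATURE_COLUMNS))

    def save(self, path) -> None:
        """Persist as <path> (xgboost JSON) + <path>.meta.json."""
        # persist the underlying Booster directly: the sklearn-wrapper
        # save path is broken against current scikit-learn releases
        self.booster.get_booster().save_model(path)
        with open(str(path) + ".meta.json", "w") as f:
            json.dump({
                "branch": self.branch, "hyperparams": self.hyperparams,
                "cv_r2": self.cv_r2, "cv_scores": list(self.cv_scores),
                "seed": self.seed, "feature_columns": list(FEATURE_COLUMNS),
                "y_mean": self.y_mean, "y_scale": self.y_scale,
            }, f, indent=2)

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        import xgboost as xgb

        booster = XGBRegressor()
        booster._Booster = xgb.Booster(model_file=str(path))
        with open(str(path) + ".meta.json") as f:
            meta = json.load(f)
        return cls(branch=meta["branch"], booster=booster,
                   hyperparams=meta["hyperparams"], cv_r2=meta["cv_r2"],
                   cv_scores=np.asarray(meta["cv_scores"]), seed=meta["seed"],
                   y_mean=meta.get("y_mean", 0.0), y_scale=meta.get("y_scale", 1.0))


def build_calibration_dataset(features: pd.DataFrame, references: pd.DataFrame,
                              table, branch: str) -> CalibrationDataset:
    """Assemble features and table-interpolated targets for one branch.

    ``features`` must carry FEATURE_COLUMNS indexed by subject id;
    ``references`` the columns ``sbp``/``dbp`` on the same index.  The target
    per subject is the linear interpolation of the intensity table at the
    reference SBP (systolic branch) or DBP (diastolic branch).  Subjects
    whose reference pressure falls outside the table range are excluded and
    listed in ``excluded``.
    """
    if branch not in ("systolic", "diastolic"):
        raise ValueError("branch must be 'systolic' or 'diastolic'")
    col = "sbp" if branch == "systolic" else "dbp"
    common = features.index.intersection(references.index)
    feats = features.loc[common, list(FEATURE_COLUMNS)]
    press = references.loc[common, col].astype(float)
    lo, hi = table.pressures[0], table.pressures[-1]
    in_range = (press >= lo) & (press <= hi)
    excluded = list(common[~in_range])
    feats = feats[in_range]
    press = press[in_range]
    targets = table.interp(press.to_numpy())
    return CalibrationDataset(branch=branch, features=feats,
                              targets=np.asarray(targets, dtype=float),
                              excluded=excluded)


def fit_calibration(dataset: CalibrationDataset, hyperparams: dict | None = None,
                    seed: int = 0, n_splits: int = 10,
                    n_repeats: int = 3) -> CalibrationModel:
    """Fit the boosted-tree ensemble with repeated k-fold validation.

    The headline accuracy is the mean R^2 over ``n_splits``-fold CV repeated
    ``n_repeats`` times (fold shuffling seeded from ``seed``); the returned
    model is refit on all rows.  Deterministic for a given dataset and seed.
    """
    if len(dataset.features) < 20:
        raise ValueError("need at least 20 rows to calibrate")
    if np.ptp(dataset.targets) == 0:
        raise ValueError("degenerate constant target")
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    # canonical row order (by subject id) so CV folds are row-order invariant
    order = np.argsort(dataset.features.index.to_numpy())
    X = dataset.features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)[order]
    targets = dataset.targets[order]
    y_mean = float(np.mean(targets))
    y_scale = float(np.std(targets))
    y = (targets - y_mean) / y_scale

    def make_model():
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **hp)

    cv = RepeatedKFold(n_splits=n_splits, n_repeats=n_repeats,
                       random_state=(seed * 9973 + 17) % (2 ** 31))
    scores = cross_val_score(make_model(), X, y, cv=cv, scoring="r2")
    final = make_model().fit(X, y)
    return CalibrationModel(
        branch=dataset.branch, booster=final, hyperparams=hp,
        cv_r2=float(np.mean(scores)), cv_scores=np.asarray(scores), seed=seed,
        y_mean=y_mean, y_scale=y_scale,
    )


def predict_calibrated_intensity(model: CalibrationModel, features) -> np.ndarray:
    """Predict simulated-scale intensities for feature rows.

    Accepts a DataFrame with FEATURE_COLUMNS (any column order) or a single
    mapping; returns finite non-negative predictions (negative raw ensemble
    outputs are clamped to zero).
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise ValueError(f"missing features {missing}")
        if features[list(FEATURE_COLUMNS)].isna().any().any():
            raise ValueError("feature rows contain missing values")
        X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    else:
        try:
            X = np.array([[float(features[c]) for c in FEATURE_COLUMNS]])
        except (KeyError, TypeError) as exc:
            raise ValueError(f"incomplete feature vector: {exc}") from exc
    raw = model.booster.predict(X).astype(float)
    pred = model.y_mean + model.y_scale * raw
    return np.clip(pred, 0.0, None)
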