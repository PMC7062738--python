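"""Multivariate prediction of conscious state from resting-state markers.

Each subject/session is summarized by 68 features: every one of the 17
markers crossed with the four combinations of its central tendency over
epochs (80% trimmed mean or SD) and its spatial summary over channels
(mean or SD).  A linear support-vector classifier, preceded by
standardization and univariate-F selection of the top 20% of features
(ceil(0.2 x 68) = 14), is trained on a labeled VS/UWS-vs-MCS reference
cohort; the penalty C is chosen by an inner stratified 5-fold grid search
over {1e-6 ... 1e-1} and decision values are mapped to probabilities by
Platt scaling.  The stimulation effect per subject is the change in the
calibrated P(MCS) from the pre- to the post-stimulation recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import EpochSet
from .markers import MARKER_IDS, compute_marker_epochs, trimmed_mean_80

C_GRID = [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1]
SELECT_FRACTION = 0.2

_SUMMARY_NAMES = ["tm80_mean", "tm80_sd", "sd_mean", "sd_sd"]

FEATURE_NAMES = [f"{m}__{s}" for m in MARKER_IDS for s in _SUMMARY_NAMES]


def build_features(per_epoch: dict[str, np.ndarray]) -> pd.Series:
    """68-entry feature vector from per-epoch x channel marker arrays.

    The four summaries per marker are: trimmed mean over epochs then mean
    over channels; trimmed mean then SD over channels; SD over epochs then
    mean over channels; SD over epochs then SD over channels.
    """
    missing = set(MARKER_IDS) - set(per_epoch)
    if missing:
        raise ValueError(f"missing markers: {sorted(missing)}")
    values = {}
    for m in MARKER_IDS:
        arr = np.asarray(per_epoch[m], float)
        if arr.ndim != 2:
            raise ValueError(f"marker {m} must be (epochs, channels)")
        tm = trimmed_mean_80(arr, axis=0)
        sd = arr.std(axis=0, ddof=0)
        values[f"{m}__tm80_mean"] = tm.mean()
        values[f"{m}__tm80_sd"] = tm.std(ddof=0)
        values[f"{m}__sd_mean"] = sd.mean()
        values[f"{m}__sd_sd"] = sd.std(ddof=0)
    fv = pd.Series(values).reindex(FEATURE_NAMES)
    if fv.isna().any() or not np.all(np.isfinite(fv.to_numpy())):
        raise ValueError("feature vector contains non-finite entries")
    return fv


def features_from_epoch_sets(epoch_sets: list[EpochSet], tau_ms: float = 32.0) -> pd.Series:
    """Feature vector averaged over resting epoching iterations."""
    fvs = [build_features(compute_marker_epochs(ep, tau_ms=tau_ms)) for ep in epoch_sets]
    return pd.concat(fvs, axis=1).mean(axis=1)


@dataclass
class TrainedClassifier:
    model: CalibratedClassifierCV
    feature_names: list[str]
    selected_mask: np.ndarray  # from a fit of the selector on the full data
    chosen_c: float
    cv_folds: int
    seed: int
    n_training: int

    @property
    def n_selected(self) -> int:
        return int(self.selected_mask.sum())


def _pipeline(c: float) -> Pipeline:
    k = math.ceil(SELECT_FRACTION * len(FEATURE_NAMES))
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("select", SelectKBest(f_classif, k=k)),
            ("svm", SVC(kernel="linear", C=c)),
        ]
    )


def _check_features(features: pd.DataFrame) -> np.ndarray:
    if list(features.columns) != FEATURE_NAMES:
        raise ValueError("feature columns must match the canonical 68 names in order")
    return features.to_numpy(float)


def train(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    cv_folds: int = 5,
    c_grid: list[float] = C_GRID,
) -> TrainedClassifier:
    """Fit the selector + linear SVM + Platt calibration on a labeled cohort.

    ``labels`` holds "MCS" / "VS" strings (MCS is the positive class).
    Feature selection and C search run inside the training folds only.
    """
    X = _check_features(features)
    y = (np.asarray(labels) == "MCS").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if len(y) < 10:
        raise ValueError("need at least 10 training subjects")

    inner = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    grid = GridSearchCV(
        _pipeline(1.0),
        {"svm__C": list(c_grid)},
        cv=inner,
        scoring="roc_auc",
        n_jobs=None,
    )
    grid.fit(X, y)
    chosen_c = float(grid.best_params_["svm__C"])

    calib_cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed + 1)
    model = CalibratedClassifierCV(_pipeline(chosen_c), method="sigmoid", cv=calib_cv)
    model.fit(X, y)

    k = math.ceil(SELECT_FRACTION * len(FEATURE_NAMES))
    selector = SelectKBest(f_classif, k=k).fit(StandardScaler().fit_transform(X), y)
    return TrainedClassifier(
        model=model,
        feature_names=FEATURE_NAMES,
        selected_mask=selector.get_support(),
        chosen_c=chosen_c,
        cv_folds=cv_folds,
        seed=seed,
        n_training=len(y),
    )


def cross_validated_auc(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    cv_folds: int = 5,
    c: float | None = None,
) -> float:
    """Outer stratified CV AUC of the selection + SVM pipeline."""
    X = _check_features(features)
    y = (np.asarray(labels) == "MCS").astype(int)
    outer = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    pipe = _pipeline(c if c is not None else 1e-2)
    return float(cross_val_score(pipe, X, y, cv=outer, scoring="roc_auc").mean())


def predict_mcs(clf: TrainedClassifier, fv: pd.Series) -> float:
    """Calibrated probability of the MCS class for one feature vector."""
    if list(fv.index) != clf.feature_names:
        raise ValueError("feature names do not match the trained classifier")
    prob = clf.model.predict_proba(fv.to_numpy(float)[None, :])[0]
    mcs_col = int(np.flatnonzero(clf.model.classes_ == 1)[0])
    return float(prob[mcs_col])


def delta_prediction(clf: TrainedClassifier, pre_fv: pd.Series, post_fv: pd.Series) -> float:
    """Post-minus-pre change in the calibrated P(MCS)."""
    return predict_mcs(clf, post_fv) - predict_mcs(clf, pre_fv)


def save_classifier(clf: TrainedClassifier, path) -> None:
    """Persist a trained classifier as a versioned joblib bundle."""
    import joblib

    joblib.dump(
        {
            "format_version": 1,
            "model": clf.model,
            "feature_names": clf.feature_names,
            "selected_mask": clf.selected_mask,
            "chosen_c": clf.chosen_c,
            "cv_folds": clf.cv_folds,
            "seed": clf.seed,
            "n_training": clf.n_training,
        },
        path,
    )


def load_classifier(path) -> TrainedClassifier:
    import joblib

    bundle = joblib.load(path)
    if bundle.get("format_version") != 1:
        raise ValueError("unsupported classifier bundle version")
    return TrainedClassifier(
        model=bundle["model"],
        feature_names=bundle["feature_names"],
        selected_mask=bundle["selected_mask"],
        chosen_c=bundle["chosen_c"],
        cv_folds=bundle["cv_folds"],
        seed=bundle["seed"],
        n_training=bundle["n_training"],
    )
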