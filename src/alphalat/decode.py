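"""Single-trial left/right attention decoding.

Features are log-transformed window-averaged alpha powers in a sensor
subset chosen by a leave-subject-out ROI procedure (the held-out subject's
data never influences their own sensor selection).  Classification uses a
linear maximum-margin classifier with the regularization strength chosen
by an inner cross-validation nested inside ten sequential outer folds, so
reported accuracies are honest estimates of single-trial performance.
Chance level for the balanced left/right problem is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
import sklearn
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .layout import SensorArray
from .stats import ROIPair, binomial_ci, define_rois

__all__ = [
    "FeatureMatrix",
    "CvResult",
    "log_power_features",
    "loso_sensor_selection",
    "nested_cv_accuracy",
    "classify_all",
    "DEFAULT_C_GRID",
]

#: logarithmic regularization grid searched by the inner cross-validation
DEFAULT_C_GRID = tuple(10.0 ** np.arange(-3, 4))


@dataclass
class FeatureMatrix:
    """Trials x selected sensors of log alpha power, with class labels."""

    features: np.ndarray
    labels: np.ndarray  # hemifield per trial ("left"/"right")
    condition: str = ""
    sensor_subset: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class CvResult:
    """Outer-fold accuracies of one subject x condition decoding run."""

    fold_accuracies: np.ndarray
    fold_sizes: np.ndarray
    chosen_C: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def n_correct(self) -> int:
        return int(round((self.fold_accuracies * self.fold_sizes).sum()))

    @property
    def n_trials(self) -> int:
        return int(self.fold_sizes.sum())


def log_power_features(
    power: np.ndarray, labels, sensor_subset, condition: str = ""
) -> FeatureMatrix:
    """Natural-log alpha power restricted to a sensor subset.

    Scaling all powers by a constant only shifts every feature, which a
    linear classifier absorbs into its bias.
    """
    subset = np.asarray(sensor_subset, dtype=int)
    sub = np.asarray(power, dtype=float)[:, subset]
    if np.any(~np.isfinite(sub)) or np.any(sub <= 0):
        bad = np.argwhere(~(np.isfinite(sub) & (sub > 0)))
        t, s = bad[0]
        raise ValueError(
            f"nonpositive power at trial {t}, sensor {subset[s]}: cannot take log"
        )
    return FeatureMatrix(
        features=np.log(sub),
        labels=np.asarray(labels),
        condition=condition,
        sensor_subset=subset,
    )


def loso_sensor_selection(
    maps_by_subject: dict,
    held_out_subject,
    sensors: SensorArray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng=None,
):
    """Sensor subset for one subject from all *other* subjects' maps.

    Runs the ROI definition on the reduced cohort and returns the union of
    the two hemispheric ROIs.  When the reduced cohort yields no
    significant cluster the selection falls back to all sensors (flagged),
    mirroring the all-sensor feature variant.

    Returns ``(sensor_indices, used_fallback, ROIPair)``.
    """
    others = [s for s in maps_by_subject if s != held_out_subject]
    if len(maps_by_subject) < 3:
        raise ValueError("leave-subject-out selection needs at least 3 subjects")
    maps = np.stack([maps_by_subject[s] for s in others])
    rois = define_rois(maps, sensors, alpha=alpha, n_perm=n_perm, rng=rng)
    if rois.is_empty:
        return np.arange(sensors.n_sensors), True, rois
    return rois.union(), False, rois


def _sequential_folds(n: int, n_folds: int):
    """Contiguous near-equal blocks of ``range(n)`` in chronological order."""
    return np.array_split(np.arange(n), n_folds)


def _scaled(Xtr, Xte):
    """Standardize both matrices by the training fold's mean/SD."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _score_grid(Xtr, ytr, Xte, yte, c_grid) -> np.ndarray:
    """Test accuracy for every regularization strength.

    Labels are 0/1 integers; scoring is done directly from the fitted
    hyperplane to keep the inner grid search cheap.
    """
    Xtr, Xte = _scaled(Xtr, Xte)
    scores = np.empty(len(c_grid))
    with warnings.catch_warnings():
        # the dual coordinate-descent solver may stop at max_iter with a
        # negligible duality gap on near-separable folds; harmless here
        warnings.simplefilter("ignore", ConvergenceWarning)
        for ci, C in enumerate(c_grid):
            clf = LinearSVC(C=C, dual=True, max_iter=10000).fit(Xtr, ytr)
            pred = (Xte @ clf.coef_[0] + clf.intercept_[0]) > 0
            scores[ci] = np.mean(pred.astype(int) == yte)
    return scores


def _fit_score(Xtr, ytr, Xte, yte, C: float) -> float:
    return float(_score_grid(Xtr, ytr, Xte, yte, [C])[0])


def nested_cv_accuracy(
    fm: FeatureMatrix,
    outer_folds: int = 10,
    inner_folds: int = 5,
    c_grid=DEFAULT_C_GRID,
) -> CvResult:
    """Nested cross-validated accuracy of the linear max-margin classifier.

    Trials are cut into ``outer_folds`` sequential blocks; for each outer
    fold an inner sequential cross-validation on the training 90% picks
    the regularization strength with the best mean inner accuracy (ties
    resolved toward stronger regularization, i.e. the smaller C), the
    classifier is refit on the full training set and scored on the
    held-out block.
    """
    X = fm.features
    classes, y = np.unique(fm.labels, return_inverse=True)
    n = len(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if min((y == c).sum() for c in (0, 1)) < outer_folds:
        raise ValueError(f"need at least {outer_folds} trials per class")
    c_grid = np.asarray(sorted(c_grid))
    accs, sizes, cs = [], [], []
    # features were validated finite upstream; skip sklearn's per-fit checks
    with sklearn.config_context(assume_finite=True):
        for test_idx in _sequential_folds(n, outer_folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            ytr = y[train_idx]
            if len(np.unique(ytr)) < 2:
                raise ValueError(
                    "a training fold lost one of the classes; interleave trials"
                )
            inner = _sequential_folds(len(train_idx), inner_folds)
            inner_scores = np.zeros(len(c_grid))
            for val_local in inner:
                fit_local = np.setdiff1d(np.arange(len(train_idx)), val_local)
                Xi, yi = X[train_idx[fit_local]], ytr[fit_local]
                Xv, yv = X[train_idx[val_local]], ytr[val_local]
                if len(np.unique(yi)) < 2:
                    raise ValueError("an inner fold lost one of the classes")
                inner_scores += _score_grid(Xi, yi, Xv, yv, c_grid)
            best_C = float(c_grid[int(np.argmax(inner_scores))])  # first max = smallest C
            accs.append(_fit_score(X[train_idx], ytr, X[test_idx], y[test_idx], best_C))
            sizes.append(len(test_idx))
            cs.append(best_C)
    return CvResult(
        fold_accuracies=np.asarray(accs),
        fold_sizes=np.asarray(sizes),
        chosen_C=np.asarray(cs),
    )


def classify_all(
    summaries_by_subject: dict,
    trials_by_subject: dict,
    maps_by_subject: dict,
    sensors: SensorArray,
    conditions=None,
    feature_sets=("roi", "all"),
    outer_folds: int = 10,
    inner_folds: int = 5,
    c_grid=DEFAULT_C_GRID,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng=None,
    chance_level: float = 0.05,
) -> pd.DataFrame:
    """Left/right decoding per subject x condition for ROI and all-sensor
    features.

    Parameters mirror the single-subject operations: ``summaries_by_subject``
    maps subject -> (n_trials, n_sensors) window-averaged planar alpha
    power, ``trials_by_subject`` the matching trial tables and
    ``maps_by_subject`` the condition-averaged modulation maps feeding the
    leave-subject-out sensor selection.

    Returns a table with one row per subject x condition x feature set:
    accuracy, fold bookkeeping, the fallback flag, and whether pooled fold
    counts beat chance by a Clopper-Pearson interval at ``chance_level``.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for subject in summaries_by_subject:
        if "roi" in feature_sets:
            subset, fallback, _ = loso_sensor_selection(
                maps_by_subject, subject, sensors, alpha=alpha, n_perm=n_perm, rng=rng
            )
        trials = trials_by_subject[subject]
        power = summaries_by_subject[subject]
        conds = conditions
        if conds is None:
            conds = (
                trials[["difficulty", "eccentricity"]].drop_duplicates().itertuples(index=False)
            )
            conds = [tuple(c) for c in conds]
        for cond in conds:
            mask = (
                (trials["difficulty"] == cond[0]) & (trials["eccentricity"] == cond[1])
            ).to_numpy()
            labels = trials.loc[mask, "hemifield"].to_numpy()
            for fs_name in feature_sets:
                if fs_name == "roi":
                    sel, fb = subset, fallback
                else:
                    sel, fb = np.arange(sensors.n_sensors), False
                fm = log_power_features(
                    power[mask], labels, sel, condition="-".join(cond)
                )
                cv = nested_cv_accuracy(fm, outer_folds, inner_folds, c_grid)
                lo, _hi = binomial_ci(cv.n_correct, cv.n_trials, 1 - 2 * chance_level)
                rows.append(
                    {
                        "subject": subject,
                        "difficulty": cond[0],
                        "eccentricity": cond[1],
                        "feature_set": fs_name,
                        "n_sensors": len(sel),
                        "fallback_all_sensors": fb,
                        "n_trials": cv.n_trials,
                        "accuracy": cv.mean_accuracy,
                        "above_chance": lo > 0.5,
                    }
                )
    return pd.DataFrame(rows)
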