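"""Three-class variant classification: CHIP vs GERMLINE vs ARTIFACT.

The classifier is the decision core of the pipeline: a tree ensemble
(gradient-boosted trees or random forest) trained on labeled feature
vectors, applied to every functional merged call.  Evaluation follows the
usual one-vs-rest reduction of the 3x3 confusion matrix to per-class
precision, recall, specificity, F1 (the harmonic mean of precision and
recall) and accuracy; feature influence is reported as normalized split
gain.

:class:`VariantClassifier` is a scikit-learn-compatible estimator (``fit`` /
``predict`` / ``predict_proba`` / ``get_params``), so it composes with
sklearn model selection; separate instances are trained per data type
(WES / WGS / WES+WGS) and variant type (SNV / INDEL), tagged in the saved
bundle together with the frozen feature-schema hash.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.utils.validation import check_is_fitted

from .feature_annot import CLASS_LABELS, INDEL_FEATURES, SNV_FEATURES, schema_hash

__all__ = [
    "TrainConfig",
    "VariantClassifier",
    "split_train_test",
    "confusion",
    "metrics_from_confusion",
    "f1_from_precision_recall",
    "Metrics",
    "save_model",
    "load_model",
]

#: pinned default hyperparameters; tuning on this problem yields negligible
#: gains over these, so they are simply fixed
GBT_DEFAULTS: dict = {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1}
RF_DEFAULTS: dict = {"n_estimators": 500, "max_features": "sqrt"}


@dataclass
class TrainConfig:
    """Training-run configuration for one (data type, variant type) model."""

    model_kind: str = "gbt"  # gbt | rf
    data_type: str = "WGS"  # WES | WGS | WES+WGS
    variant_type: str = "SNV"  # SNV | INDEL
    train_fraction: float = 0.8
    cv_folds: int = 5
    rng_seed: int = 0
    hyperparameters: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.model_kind not in ("gbt", "rf"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


class SchemaMismatchError(ValueError):
    """Prediction-time features do not match the training schema."""


class VariantClassifier(BaseEstimator, ClassifierMixin):
    """Tree-ensemble 3-class variant classifier.

    Parameters
    ----------
    model_kind : {"gbt", "rf"}
        Gradient-boosted trees (xgboost) or random forest (scikit-learn).
    variant_type : {"SNV", "INDEL"}
        Selects the frozen 26- or 24-feature schema.
    data_type : {"WES", "WGS", "WES+WGS"}
        Provenance tag carried in saved bundles.
    random_state : int
        Seed; training is deterministic given the seed at a single thread.
    hyperparameters : dict or None
        Overrides merged onto the pinned defaults.

    Attributes
    ----------
    classes_ : ndarray of the three labels in fixed encoding order
    model_ : the fitted underlying estimator
    schema_hash_ : hash of the feature order the model was fitted on
    """

    def __init__(
        self,
        model_kind: str = "gbt",
        variant_type: str = "SNV",
        data_type: str = "WGS",
        random_state: int = 0,
        hyperparameters: dict | None = None,
    ):
        self.model_kind = model_kind
        self.variant_type = variant_type
        self.data_type = data_type
        self.random_state = random_state
        self.hyperparameters = hyperparameters

    # -- internals ---------------------------------------------------------

    @property
    def _feature_names(self) -> tuple[str, ...]:
        return SNV_FEATURES if self.variant_type == "SNV" else INDEL_FEATURES

    def _validate_X(self, X) -> np.ndarray:
        names = self._feature_names
        if isinstance(X, pd.DataFrame):
            if tuple(X.columns) != names:
                missing = set(names) - set(X.columns)
                extra = set(X.columns) - set(names)
                raise SchemaMismatchError(
                    f"feature columns do not match the {self.variant_type} schema"
                    f" (missing {sorted(missing)}, unexpected {sorted(extra)})"
                    if missing or extra
                    else "feature columns are out of order; reorder to the schema"
                )
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(names):
                raise SchemaMismatchError(
                    f"expected {len(names)} features for {self.variant_type}, "
                    f"got shape {arr.shape}"
                )
        if np.isnan(arr).any():
            bad = [names[j] for j in np.unique(np.nonzero(np.isnan(arr))[1])]
            raise ValueError(f"NaN values in features: {bad}")
        return arr

    def _build(self, n_present: int = 3):
        if self.model_kind == "gbt":
            from xgboost import XGBClassifier

            params = {**GBT_DEFAULTS, **(self.hyperparameters or {})}
            extra = (
                {"objective": "multi:softprob", "num_class": n_present}
                if n_present > 2
                else {"objective": "binary:logistic"}
            )
            return XGBClassifier(
                random_state=self.random_state,
                n_jobs=1,
                tree_method="hist",
                **extra,
                **params,
            )
        params = {**RF_DEFAULTS, **(self.hyperparameters or {})}
        return RandomForestClassifier(
            random_state=self.random_state, n_jobs=1, **params
        )

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, tune: bool = False, param_grid: Mapping | None = None):
        """Fit on labeled vectors; optional k-fold grid-search tuning."""
        arr = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.array(CLASS_LABELS)
        label_to_code = {lab: i for i, lab in enumerate(CLASS_LABELS)}
        unknown = set(y) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        codes = np.array([label_to_code[lab] for lab in y])
        # fit on contiguous codes of the classes actually present (tree
        # backends reject gaps); remember the mapping for probability expansion
        present = np.unique(codes)
        self._present_codes_ = present
        fit_codes = np.searchsorted(present, codes)
        est = self._build(n_present=len(present))
        if tune and param_grid:
            gs = GridSearchCV(est, dict(param_grid), cv=5, n_jobs=1)
            gs.fit(arr, fit_codes)
            est = gs.best_estimator_
            self.tuned_params_ = gs.best_params_
        else:
            est.fit(arr, fit_codes)
        self.model_ = est
        self.schema_hash_ = schema_hash(self.variant_type)
        self.n_features_in_ = arr.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if schema_hash(self.variant_type) != self.schema_hash_:
            raise SchemaMismatchError("feature schema changed since training")
        arr = self._validate_X(X)
        proba = self.model_.predict_proba(arr)
        if proba.ndim == 1:  # binary backend returns P(class 1)
            proba = np.column_stack([1 - proba, proba])
        # expand to the fixed three columns via the present-class mapping
        if proba.shape[1] != 3 or len(self._present_codes_) != 3:
            full = np.zeros((proba.shape[0], 3))
            for j, code in enumerate(self._present_codes_):
                full[:, int(code)] = proba[:, j]
            proba = full
        return proba

    def predict(self, X) -> np.ndarray:
        """Argmax-probability labels; exact ties resolve to the first class
        in the fixed encoding order (CHIP, GERMLINE, ARTIFACT)."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def feature_gain(self) -> pd.Series:
        """Per-feature split-gain importance, normalized to sum to 1 and
        sorted descending.  Features never used in a split score 0."""
        check_is_fitted(self, "model_")
        names = list(self._feature_names)
        if self.model_kind == "gbt":
            booster = self.model_.get_booster()
            raw = booster.get_score(importance_type="gain")
            gains = np.zeros(len(names))
            for key, g in raw.items():
                idx = int(key[1:]) if key.startswith("f") else names.index(key)
                gains[idx] = g
        elif hasattr(self.model_, "feature_importances_"):
            gains = np.asarray(self.model_.feature_importances_, dtype=float)
        else:
            raise TypeError("feature gain requires a tree-ensemble model")
        total = gains.sum()
        if total > 0:
            gains = gains / total
        return pd.Series(gains, index=names).sort_values(ascending=False)


def split_train_test(
    X: pd.DataFrame, y: Sequence[str], cfg: TrainConfig
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Deterministic stratified 80/20 split (by ``cfg.train_fraction``).

    Rows are assigned by a content-independent order (a seeded permutation
    of a stable sort of the rows), so shuffled input order yields identical
    membership.  A class with a single vector goes to the training side;
    empty classes only warn.
    """
    if len(X) < 10:
        raise ValueError("need at least 10 labeled vectors to split")
    y = np.asarray(y)
    # canonical row order independent of input permutation
    order = np.lexsort([X[c].to_numpy() for c in reversed(X.columns)])
    Xc, yc = X.iloc[order].reset_index(drop=True), y[order]

    counts = pd.Series(yc).value_counts()
    singletons = set(counts[counts < 2].index)
    mask = np.array([lab in singletons for lab in yc])
    X_rest, y_rest = Xc[~mask], yc[~mask]
    Xtr, Xte, ytr, yte = train_test_split(
        X_rest,
        y_rest,
        train_size=cfg.train_fraction,
        random_state=cfg.rng_seed,
        stratify=y_rest,
    )
    if mask.any():  # singleton classes are forced into training
        Xtr = pd.concat([Xtr, Xc[mask]])
        ytr = np.concatenate([ytr, yc[mask]])
    return (
        Xtr.reset_index(drop=True),
        Xte.reset_index(drop=True),
        ytr,
        yte,
    )


def confusion(
    predictions: Sequence[str], truth_labels: Sequence[str]
) -> pd.DataFrame:
    """3x3 confusion matrix (rows = actual, columns = predicted)."""
    predictions = np.asarray(predictions)
    truth_labels = np.asarray(truth_labels)
    if len(predictions) != len(truth_labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions, "
            f"{len(truth_labels)} truth labels"
        )
    cm = pd.DataFrame(
        0, index=list(CLASS_LABELS), columns=list(CLASS_LABELS), dtype=int
    )
    for t, p in zip(truth_labels, predictions):
        cm.loc[t, p] += 1
    return cm


@dataclass(frozen=True)
class Metrics:
    """One-vs-rest performance metrics for a single class."""

    precision: float
    recall: float
    specificity: float
    f1: float
    accuracy: float
    undefined: frozenset[str] = frozenset()


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den else (float("nan"), True)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 as the harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2 * precision * recall / (precision + recall)


def metrics_from_confusion(cm: pd.DataFrame, cls: str) -> Metrics:
    """One-vs-rest reduction of a 3x3 confusion matrix for ``cls``.

    tp: actual ``cls`` predicted ``cls``; fn: actual ``cls`` predicted
    otherwise; fp: other classes predicted ``cls``; tn: the rest.
    Division-by-zero cases return NaN with the metric named in
    ``undefined``.
    """
    if cm.to_numpy().sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = int(cm.loc[cls, cls])
    fn = int(cm.loc[cls].sum() - tp)
    fp = int(cm[cls].sum() - tp)
    tn = int(cm.to_numpy().sum() - tp - fn - fp)
    undefined = set()
    precision, u = _safe_div(tp, tp + fp)
    if u:
        undefined.add("precision")
    recall, u = _safe_div(tp, tp + fn)
    if u:
        undefined.add("recall")
    specificity, u = _safe_div(tn, tn + fp)
    if u:
        undefined.add("specificity")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
        undefined.add("f1")
    else:
        f1 = f1_from_precision_recall(precision, recall)
    accuracy, u = _safe_div(tp + tn, tp + tn + fp + fn)
    if u:
        undefined.add("accuracy")
    return Metrics(precision, recall, specificity, f1, accuracy, frozenset(undefined))


# --------------------------------------------------------------------------
# persistence: single-file bundle with schema hash, config and seed
# --------------------------------------------------------------------------

def save_model(clf: VariantClassifier, path: str) -> None:
    check_is_fitted(clf, "model_")
    joblib.dump(
        {
            "estimator": clf,
            "schema_hash": clf.schema_hash_,
            "model_kind": clf.model_kind,
            "data_type": clf.data_type,
            "variant_type": clf.variant_type,
            "random_state": clf.random_state,
        },
        path,
    )


def load_model(path: str) -> VariantClassifier:
    bundle = joblib.load(path)
    clf: VariantClassifier = bundle["estimator"]
    if bundle["schema_hash"] != schema_hash(clf.variant_type):
        raise SchemaMismatchError(
            "stored model was trained on a different feature schema"
        )
    return clf
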