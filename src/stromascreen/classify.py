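"""Random-forest classification of candidate objects.

Assigns each detected object to VIABLE_ALL, DEAD_ALL, MSC or ARTIFACT
from its feature vector, standing in for the interactive
machine-learning step of high-content co-culture analysis.  Labels come
from simulator ground truth or a user-supplied CSV rather than an
annotation GUI.  Class imbalance is handled by weighting classes
inversely to their frequency; a stratified cross-validated accuracy is
stored with the fitted model, and the feature schema is hashed so a
model can never silently be applied to a different feature layout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .features import FEATURE_NAMES, SCHEMA_VERSION

CLASS_LABELS = ("VIABLE_ALL", "DEAD_ALL", "MSC", "ARTIFACT")
MIN_EXAMPLES_PER_CLASS = 10


def feature_schema_hash(names=FEATURE_NAMES) -> str:
    """Short stable digest of the ordered feature schema."""
    payload = SCHEMA_VERSION + ":" + ",".join(names)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class TrainingSet:
    """Feature table with one class label per object."""

    features: pd.DataFrame
    labels: pd.Series
    provenance: str = "synthetic ground truth"

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")
        self.labels = pd.Series(np.asarray(self.labels, dtype=object), name="label")
        self.features = self.features.reset_index(drop=True)
        self.labels = self.labels.reset_index(drop=True)

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts()

    def validate(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.features.columns]
        if missing:
            raise ValueError(f"training features missing columns: {missing[:5]}...")
        unknown = set(self.labels) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        counts = self.class_counts()
        if len(counts) < 2:
            raise ValueError("training set must contain at least 2 classes")
        weak = counts[counts < MIN_EXAMPLES_PER_CLASS]
        if len(weak):
            raise ValueError(
                f"classes with fewer than {MIN_EXAMPLES_PER_CLASS} examples: "
                f"{dict(weak)}"
            )


@dataclass
class ClassifierModel:
    """A fitted random forest plus the metadata needed to apply it safely."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    cv_accuracy: float
    training_seed: int
    schema_hash: str

    def check_schema(self, features: pd.DataFrame) -> None:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:5]}...")
        if feature_schema_hash(self.feature_names) != self.schema_hash:
            raise ValueError("feature schema hash mismatch")


def train(
    training_set: TrainingSet,
    n_estimators: int = 300,
    seed: int = 0,
    cv_folds: int = 5,
) -> ClassifierModel:
    """Fit the random forest and record its cross-validated accuracy.

    Deterministic given (data, hyperparameters, seed).  The held-out
    accuracy is a stratified k-fold estimate (folds reduced if a class
    has fewer members than folds), computed before the final fit on all
    data.
    """
    training_set.validate()
    X = training_set.features.loc[:, list(FEATURE_NAMES)].to_numpy(float)
    y = training_set.labels.to_numpy(object)
    seed = int(seed) & 0x7FFFFFFF

    def make_rf() -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=seed,
            class_weight="balanced",
            n_jobs=1,
        )

    folds = int(min(cv_folds, training_set.class_counts().min()))
    folds = max(folds, 2)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_accuracy = float(cross_val_score(make_rf(), X, y, cv=cv, scoring="accuracy").mean())
    estimator = make_rf().fit(X, y)
    return ClassifierModel(
        estimator=estimator,
        feature_names=tuple(FEATURE_NAMES),
        classes=tuple(estimator.classes_),
        cv_accuracy=cv_accuracy,
        training_seed=seed,
        schema_hash=feature_schema_hash(),
    )


def predict(
    model: ClassifierModel, features: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted labels and class-probability table for a feature table.

    Probabilities sum to 1 per object.  An empty table yields empty
    outputs; a schema mismatch raises.
    """
    model.check_schema(features)
    if len(features) == 0:
        return (
            np.empty(0, dtype=object),
            pd.DataFrame(columns=list(model.classes)),
        )
    X = features.loc[:, list(model.feature_names)].to_numpy(float)
    labels = model.estimator.predict(X)
    proba = pd.DataFrame(
        model.estimator.predict_proba(X), columns=list(model.classes)
    )
    return labels, proba


def save_model(model: ClassifierModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> ClassifierModel:
    model = joblib.load(path)
    if not isinstance(model, ClassifierModel):
        raise ValueError(f"{path} does not contain a stromascreen ClassifierModel")
    return model
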