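"""Training, prediction and time-budget aggregation.

The classifier is a soft-margin support-vector machine with a radial
basis kernel (cost 10, gamma 0.01 on raw feature units) decomposed into
pairwise one-vs-one subproblems with majority voting; vote ties resolve
to the class with the lowest canonical index.  Given a classified label
sequence, the time spent in each activity is the epoch length (5 s)
times the number of epochs assigned to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from actitime.activities import Activity, CANONICAL_ORDER
from actitime.features import (
    FeatureSet,
    ThresholdRule,
    apply_step_threshold,
    extract_features,
)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassifierConfig:
    """Support-vector machine settings.

    ``cost`` is the soft-margin penalty C, ``gamma`` the radial-basis
    width parameter; both refer to raw (unstandardized) feature units.
    ``tol`` is the dual optimizer's stopping tolerance, recorded for
    reproducibility.  The multiclass scheme is pairwise one-vs-one with
    majority voting.
    """

    kernel: str = "rbf"
    cost: float = 10.0
    gamma: float = 0.01
    multiclass: str = "one_vs_one"
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.kernel != "rbf":
            raise ValueError("only the radial-basis kernel is supported")
        if self.multiclass != "one_vs_one":
            raise ValueError("only one-vs-one decomposition is supported")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reapply it.

    ``classes`` lists the activities seen in training (canonical order);
    the model never predicts a class it was not trained on.  When
    ``threshold_at_inference`` is set the training-time step-threshold
    rule is reapplied to prediction inputs so the classifier sees the
    same feature distribution at both stages.
    """

    config: ClassifierConfig
    feature_set: FeatureSet
    classes: tuple[Activity, ...]
    svc: SVC
    n_per_class: dict[Activity, int]
    threshold_rule: Optional[ThresholdRule] = None
    threshold_at_inference: bool = True
    standardize: bool = False
    scale_mean: Optional[np.ndarray] = None
    scale_std: Optional[np.ndarray] = None


def _encode(y: Sequence[Activity]) -> np.ndarray:
    return np.array([Activity(v).index for v in y], dtype=int)


def train(
    X: np.ndarray,
    y: Sequence[Activity],
    config: ClassifierConfig = ClassifierConfig(),
    feature_set: Optional[FeatureSet] = None,
) -> TrainedModel:
    """Fit the one-vs-one RBF support-vector machine on labeled vectors.

    Deterministic given identical inputs and config.  Requires at least
    two classes and a consistent vector length.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d array (n samples x n features)")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    codes = _encode(y)
    present = sorted(set(codes.tolist()))
    if len(present) < 2:
        raise ValueError("training requires at least two classes")
    if feature_set is None:
        feature_set = FeatureSet("six" if X.shape[1] == 6 else "eight")
    if X.shape[1] != len(feature_set):
        raise ValueError(
            f"feature length {X.shape[1]} does not match {feature_set.kind}-feature set"
        )
    # libsvm's one-vs-one voting breaks ties toward the first class in its
    # (ascending) class list, i.e. the lowest canonical index.
    svc = SVC(
        kernel=config.kernel,
        C=config.cost,
        gamma=config.gamma,
        tol=config.tol,
        decision_function_shape="ovo",
        break_ties=False,
        random_state=config.seed,
    )
    svc.fit(X, codes)
    classes = tuple(CANONICAL_ORDER[i] for i in present)
    counts = {CANONICAL_ORDER[i]: int((codes == i).sum()) for i in present}
    return TrainedModel(
        config=config,
        feature_set=feature_set,
        classes=classes,
        svc=svc,
        n_per_class=counts,
    )


def predict(model: TrainedModel, X: np.ndarray) -> list[Activity]:
    """Predict one activity per feature vector (deterministic)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return []
    if X.ndim != 2 or X.shape[1] != len(model.feature_set):
        raise ValueError(
            f"expected vectors of length {len(model.feature_set)}, got shape {X.shape}"
        )
    if model.standardize and model.scale_mean is not None:
        X = (X - model.scale_mean) / model.scale_std
    codes = model.svc.predict(X)
    return [CANONICAL_ORDER[int(c)] for c in codes]


def fit_on_samples(
    samples: pd.DataFrame,
    feature_set: FeatureSet,
    config: ClassifierConfig = ClassifierConfig(),
    threshold_rule: Optional[ThresholdRule] = ThresholdRule(),
    threshold_at_inference: bool = True,
    standardize: bool = False,
) -> TrainedModel:
    """End-to-end training from labeled fused samples.

    Applies the step-threshold preprocessing, extracts the requested
    feature set and fits the classifier.  ``standardize`` (off by
    default) z-scores features on training statistics.
    """
    if threshold_rule is not None:
        samples = apply_step_threshold(samples, threshold_rule)
    X, y = extract_features(samples, feature_set)
    if y is None or any(v is None for v in y):
        raise ValueError("training samples must all be labeled")
    mean = std = None
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std
    model = train(X, y, config, feature_set)
    model.threshold_rule = threshold_rule
    model.threshold_at_inference = threshold_at_inference
    model.standardize = standardize
    model.scale_mean = mean
    model.scale_std = std
    return model


def predict_on_samples(model: TrainedModel, samples: pd.DataFrame) -> pd.Series:
    """Classify fused samples, honoring the model's preprocessing flags."""
    if model.threshold_rule is not None and model.threshold_at_inference:
        samples = apply_step_threshold(samples, model.threshold_rule)
    X, _ = extract_features(samples.drop(columns=["label"], errors="ignore"), model.feature_set)
    labels = predict(model, X)
    return pd.Series(labels, index=samples.index, name="predicted")


@dataclass
class TimeBudget:
    """Per-activity total seconds and shares of classified time.

    ``seconds[a] = epoch_s * count(a)``; proportions are ``None`` for an
    empty label sequence (flagged undefined rather than NaN).
    """

    seconds: dict[Activity, float]
    proportions: Optional[dict[Activity, float]]
    total_seconds: float
    epoch_s: float = 5.0

    def hours(self) -> dict[Activity, float]:
        return {a: s / 3600.0 for a, s in self.seconds.items()}


def aggregate_time(
    labels: Sequence[Activity], epoch_s: float = 5.0
) -> TimeBudget:
    """Label sequence -> per-activity time totals and proportions."""
    seconds = {a: 0.0 for a in CANONICAL_ORDER}
    for l in labels:
        seconds[Activity(l)] += epoch_s
    total = epoch_s * len(labels)
    if len(labels) == 0:
        return TimeBudget(seconds=seconds, proportions=None, total_seconds=0.0, epoch_s=epoch_s)
    props = {a: s / total for a, s in seconds.items()}
    return TimeBudget(seconds=seconds, proportions=props, total_seconds=total, epoch_s=epoch_s)


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Persist a trained model (versioned joblib container)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": model.config,
        "feature_kind": model.feature_set.kind,
        "classes": [a.value for a in model.classes],
        "svc": model.svc,
        "n_per_class": {a.value: n for a, n in model.n_per_class.items()},
        "threshold_rule": model.threshold_rule,
        "threshold_at_inference": model.threshold_at_inference,
        "standardize": model.standardize,
        "scale_mean": model.scale_mean,
        "scale_std": model.scale_std,
    }
    joblib.dump(payload, path)


def load_model(path: Union[str, Path]) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return TrainedModel(
        config=payload["config"],
        feature_set=FeatureSet(payload["feature_kind"]),
        classes=tuple(Activity(v) for v in payload["classes"]),
        svc=payload["svc"],
        n_per_class={Activity(k): v for k, v in payload["n_per_class"].items()},
        threshold_rule=payload["threshold_rule"],
        threshold_at_inference=payload["threshold_at_inference"],
        standardize=payload["standardize"],
        scale_mean=payload["scale_mean"],
        scale_std=payload["scale_std"],
    )
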