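"""Coupled classifier bank for multiclass arrhythmia recognition.

Four methods share one interface: a multilayer perceptron (single hidden
layer of 10 units), a boosted decision-tree ensemble (100 learning cycles,
small trees), a support vector machine (linear kernel by default, posterior
probabilities via Platt scaling), and a Gaussian naive Bayes classifier.
Multiclass problems are reduced to binary ones with one-versus-one (OVO)
coding: one binary learner per unordered class pair, pairwise posteriors
averaged into class scores that sum to one.  Features are z-scored from the
training data for the MLP and SVM (a unit kernel scale is only meaningful on
standardized inputs); tree and naive Bayes learners see raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .records import FEATURE_NAMES, FeatureRecord, feature_matrix

_METHODS = ("mlp", "rf", "svm", "nb")
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Training-time parameters of one recognition model.

    Defaults follow the reference settings: MLP hidden layer of 10,
    boosted ensemble of 100 cycles with 10-node trees, linear SVM with unit
    kernel scale and OVO coding, Gaussian class-conditional densities for NB.
    """

    method: str = "nb"
    mlp_hidden: int = 10
    rf_cycles: int = 100
    rf_max_nodes: int = 10
    rf_aggregation: str = "boost"  # "boost" (default) or "bag"
    svm_kernel: str = "linear"  # "linear" or "rbf"
    svm_scale: float = 1.0
    coding: str = "ovo"
    class_weight: str | None = None  # None or "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.svm_kernel not in ("linear", "rbf"):
            raise ValueError("svm_kernel must be 'linear' or 'rbf'")
        if self.coding not in ("ovo", "ova"):
            raise ValueError("coding must be 'ovo' or 'ova'")
        if self.rf_aggregation not in ("boost", "bag"):
            raise ValueError("rf_aggregation must be 'boost' or 'bag'")
        if min(self.mlp_hidden, self.rf_cycles, self.rf_max_nodes) < 1:
            raise ValueError("sizes must be positive")
        if self.svm_scale <= 0:
            raise ValueError("svm_scale must be positive")


@dataclass
class Prediction:
    """A predicted symptom label with posterior-like per-class scores."""

    label: int
    scores: dict[int, float]


@dataclass
class PatternModel:
    """One trained recognition model for a subset of symptom classes."""

    config: ModelConfig
    classes: tuple[int, ...]
    learners: dict[tuple[int, ...], object]
    scaler_mean: np.ndarray | None
    scaler_sd: np.ndarray | None
    n_per_class: dict[int, int] = field(default_factory=dict)

    @property
    def n_learners(self) -> int:
        return len(self.learners)


def _base_estimator(config: ModelConfig, seed: int):
    if config.method == "mlp":
        # small feature sets need a patient optimizer: default adam patience
        # (10 epochs) abandons training near the random initialization
        return MLPClassifier(
            hidden_layer_sizes=(config.mlp_hidden,),
            max_iter=500,
            tol=1e-6,
            learning_rate_init=0.01,
            early_stopping=True,
            validation_fraction=0.2,
            n_iter_no_change=50,
            random_state=seed,
        )
    if config.method == "rf":
        if config.rf_aggregation == "bag":
            return RandomForestClassifier(
                n_estimators=config.rf_cycles,
                max_leaf_nodes=config.rf_max_nodes,
                class_weight=config.class_weight,
                random_state=seed,
            )
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_leaf_nodes=config.rf_max_nodes,
                class_weight=config.class_weight,
                random_state=seed,
            ),
            n_estimators=config.rf_cycles,
            random_state=seed,
        )
    if config.method == "svm":
        # sigmoid (Platt-style) calibration of the margin into posteriors
        return CalibratedClassifierCV(
            SVC(
                kernel=config.svm_kernel,
                gamma=1.0 / config.svm_scale**2,
                class_weight=config.class_weight,
                random_state=seed,
            ),
            method="sigmoid",
            ensemble=False,
        )
    return GaussianNB()


def _needs_scaling(method: str) -> bool:
    return method in ("mlp", "svm")


def train(features: list[FeatureRecord], config: ModelConfig) -> PatternModel:
    """Fit one recognition model on labelled centroid features.

    Requires at least two classes and five records per class.  Under OVO
    coding, ``C(k, 2)`` binary learners are fitted on the pairwise subsets;
    under OVA, ``k`` one-versus-rest learners.  Deterministic under a fixed
    ``config.seed``.
    """
    X, y = feature_matrix(features)
    if X.shape[0] == 0:
        raise ValueError("no training records")
    if np.any(y < 0):
        raise ValueError("all training records must be labelled")
    if not np.all(np.isfinite(X)):
        raise ValueError("NaN or infinite feature values in training data")
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 5:
        raise ValueError("need at least 5 records per class")

    if _needs_scaling(config.method):
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mean) / sd
    else:
        mean = sd = None
        Xs = X

    learners: dict[tuple[int, ...], object] = {}
    if config.coding == "ovo":
        tasks = [(a, b) for a, b in combinations(classes, 2)]
    else:
        tasks = [(c,) for c in classes]
    for i, key in enumerate(tasks):
        seed_i = (config.seed + 10007 * (i + 1)) % (2**31 - 1)
        est = _base_estimator(config, seed_i)
        if len(key) == 2:
            a, b = key
            mask = (y == a) | (y == b)
            est.fit(Xs[mask], y[mask])
        else:
            (c,) = key
            est.fit(Xs, (y == c).astype(int))
        learners[key] = est
    return PatternModel(
        config=config,
        classes=classes,
        learners=learners,
        scaler_mean=mean,
        scaler_sd=sd,
        n_per_class=counts,
    )


def _score_matrix(model: PatternModel, X: np.ndarray) -> np.ndarray:
    """Aggregate binary posteriors into normalized per-class scores."""
    if model.scaler_mean is not None:
        X = (X - model.scaler_mean) / model.scaler_sd
    k = len(model.classes)
    idx = {c: j for j, c in enumerate(model.classes)}
    scores = np.zeros((X.shape[0], k))
    for key, est in model.learners.items():
        proba = est.predict_proba(X)
        cols = {int(c): j for j, c in enumerate(est.classes_)}
        if len(key) == 2:
            a, b = key
            scores[:, idx[a]] += proba[:, cols[a]]
            scores[:, idx[b]] += proba[:, cols[b]]
        else:
            (c,) = key
            scores[:, idx[c]] += proba[:, cols[1]]
    totals = scores.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return scores / totals


def predict(model: PatternModel, features: list[FeatureRecord]) -> list[Prediction]:
    """Score feature records; ties break toward the lower symptom ID."""
    X, _ = feature_matrix(features)
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"feature dimension must be {len(FEATURE_NAMES)}")
    S = _score_matrix(model, X)
    out = []
    for row in S:
        j = int(np.argmax(row))  # argmax returns the first (lowest-ID) maximum
        out.append(
            Prediction(
                label=model.classes[j],
                scores={c: float(v) for c, v in zip(model.classes, row)},
            )
        )
    return out


def predict_scores(model: PatternModel, features: list[FeatureRecord]) -> np.ndarray:
    """Normalized per-class score matrix, columns ordered as ``model.classes``."""
    X, _ = feature_matrix(features)
    return _score_matrix(model, X)


class ModelLoadError(RuntimeError):
    """A model bundle could not be read or has an incompatible format."""


def save_model(model: PatternModel, path: str | Path) -> Path:
    """Serialize a trained model bundle (config, scaling, learners, seed)."""
    path = Path(path)
    joblib.dump(
        {
            "format_version": _FORMAT_VERSION,
            "config": model.config,
            "classes": model.classes,
            "learners": model.learners,
            "scaler_mean": model.scaler_mean,
            "scaler_sd": model.scaler_sd,
            "n_per_class": model.n_per_class,
        },
        path,
    )
    return path


def load_model(path: str | Path) -> PatternModel:
    try:
        data = joblib.load(path)
    except Exception as exc:
        raise ModelLoadError(f"cannot read model bundle {path}: {exc}") from exc
    if not isinstance(data, dict) or data.get("format_version") != _FORMAT_VERSION:
        raise ModelLoadError(
            f"model bundle {path} has unsupported format "
            f"(expected version {_FORMAT_VERSION})"
        )
    return PatternModel(
        config=data["config"],
        classes=tuple(data["classes"]),
        learners=data["learners"],
        scaler_mean=data["scaler_mean"],
        scaler_sd=data["scaler_sd"],
        n_per_class=data["n_per_class"],
    )


def with_seed(config: ModelConfig, seed: int) -> ModelConfig:
    """A copy of ``config`` with a different seed (folds, refits)."""
    return replace(config, seed=seed)
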