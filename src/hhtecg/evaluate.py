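"""Confusion metrics, ROC/AUC, cross-validation and pattern-pair evaluation.

Metrics follow the standard confusion-count definitions::

    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    sensitivity = TP / (TP + FN)            (true-positive rate)
    specificity = 1 - FP / (FP + TN)        (one minus false-positive rate)

ROC curves enumerate all score cut-points; AUC is the trapezoid area, and the
single reported (sensitivity, specificity) operating point maximizes Youden's
J = sensitivity + specificity - 1.  Pattern evaluation mirrors the coupled
analysis layout: one multiclass model per method, scored on every unordered
symptom pair and on every one-versus-rest class of the test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .models import ModelConfig, PatternModel, predict_scores, train, with_seed
from .records import FEATURE_NAMES, FeatureRecord, feature_matrix


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("empty confusion table")


@dataclass
class Metrics:
    """Accuracy/sensitivity/specificity; a zero denominator leaves the value
    ``None`` and records the metric name in ``undefined`` instead of
    propagating NaN."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    undefined: tuple[str, ...] = ()


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    undefined = []
    total = c.tp + c.tn + c.fp + c.fn
    accuracy = (c.tp + c.tn) / total
    if c.tp + c.fn > 0:
        sensitivity = c.tp / (c.tp + c.fn)
    else:
        sensitivity, undefined = None, undefined + ["sensitivity"]
    if c.fp + c.tn > 0:
        specificity = 1.0 - c.fp / (c.fp + c.tn)
    else:
        specificity, undefined = None, undefined + ["specificity"]
    return Metrics(accuracy, sensitivity, specificity, tuple(undefined))


@dataclass
class ROCResult:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    curve: list[tuple[float, float]]  # (fpr, tpr), monotone, anchored at (0,0),(1,1)
    threshold: float = float("nan")


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> ROCResult:
    """ROC over all cut-points of a positive-class score.

    Reported sensitivity/specificity/accuracy are taken at the cut-point
    maximizing Youden's J (first such point when tied).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    pos = truth == 1
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present in the truth labels")
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    thr = float(thresholds[best])
    pred = scores >= thr
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    m = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    return ROCResult(
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        accuracy=m.accuracy,
        auc=auc,
        curve=list(zip(fpr.tolist(), tpr.tolist())),
        threshold=thr,
    )


@dataclass
class PatternReport:
    """ROC results of one pattern (a symptom pair or a one-vs-rest class)."""

    pattern: tuple[str, ...]  # ("pair", a, b) or ("ovr", c) stringified
    results: dict[str, ROCResult]  # method -> result
    n_test: int


def _pair_pattern(a: int, b: int) -> tuple[str, ...]:
    return ("pair", str(a), str(b))


def _ovr_pattern(c: int) -> tuple[str, ...]:
    return ("ovr", str(c))


def _pattern_reports(
    models: dict[str, PatternModel],
    test_features: list[FeatureRecord],
) -> list[PatternReport]:
    X, y = feature_matrix(test_features)
    if np.any(y < 0):
        raise ValueError("test records must be labelled")
    classes = sorted(set(int(c) for c in np.unique(y)))
    score_mats = {m: predict_scores(model, test_features) for m, model in models.items()}
    col = {m: {c: j for j, c in enumerate(model.classes)} for m, model in models.items()}
    reports: list[PatternReport] = []
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        if not mask.any():
            raise ValueError(f"no test records for pattern ({a}, {b})")
        truth = (y[mask] == b).astype(int)  # higher symptom ID is the positive class
        results = {}
        for m, S in score_mats.items():
            sa = S[mask][:, col[m][a]]
            sb = S[mask][:, col[m][b]]
            denom = sa + sb
            denom[denom == 0] = 1.0
            results[m] = roc_auc(sb / denom, truth)
        reports.append(PatternReport(_pair_pattern(a, b), results, int(mask.sum())))
    for c in classes:
        truth = (y == c).astype(int)
        results = {
            m: roc_auc(S[:, col[m][c]], truth) for m, S in score_mats.items()
        }
        reports.append(PatternReport(_ovr_pattern(c), results, int(y.size)))
    return reports


def evaluate_patterns(
    train_features: list[FeatureRecord],
    test_features: list[FeatureRecord],
    configs: ModelConfig | list[ModelConfig],
) -> list[PatternReport]:
    """Train one multiclass model per config and score every pattern.

    For ``k`` symptom classes in the test set this yields ``C(k, 2)`` pairwise
    reports (test set restricted to the two classes) plus ``k`` one-versus-rest
    reports, each carrying one :class:`ROCResult` per method.
    """
    if isinstance(configs, ModelConfig):
        configs = [configs]
    models = {cfg.method: train(train_features, cfg) for cfg in configs}
    return _pattern_reports(models, test_features)


def reports_to_table(reports: list[PatternReport]) -> pd.DataFrame:
    """Flatten reports into a (pattern, method, metrics) table for CSV export."""
    rows = []
    for rep in reports:
        name = "-".join(rep.pattern[1:]) if rep.pattern[0] == "pair" else f"{rep.pattern[1]}-vs-rest"
        for method, r in sorted(rep.results.items()):
            rows.append(
                {
                    "pattern": name,
                    "method": method,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "accuracy": r.accuracy,
                    "auc": r.auc,
                    "n_test": rep.n_test,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FoldResult:
    fold: int
    reports: list[PatternReport]
    n_train: int
    n_test: int


def cross_validate(
    features: list[FeatureRecord],
    config: ModelConfig | list[ModelConfig],
    k: int = 5,
    seed: int = 0,
) -> list[FoldResult]:
    """Stratified k-fold cross-validation (default 5-fold: 80%/20% splits).

    Records are ordered by a stable key (label, then feature values) before
    fold assignment, so shuffling the input order does not change the folds.
    Per-class fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    configs = [config] if isinstance(config, ModelConfig) else list(config)
    order = sorted(
        range(len(features)),
        key=lambda i: (features[i].label, tuple(features[i].features)),
    )
    feats = [features[i] for i in order]
    X, y = feature_matrix(feats)
    if np.any(y < 0):
        raise ValueError("all records must be labelled for cross-validation")
    class_counts = np.bincount(y)
    if class_counts[class_counts > 0].min() < k:
        raise ValueError("every class needs at least k records")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for fold_i, (tr_idx, te_idx) in enumerate(skf.split(X, y)):
        tr = [feats[i] for i in tr_idx]
        te = [feats[i] for i in te_idx]
        models = {
            cfg.method: train(tr, with_seed(cfg, (seed + fold_i) % (2**31 - 1)))
            for cfg in configs
        }
        folds.append(
            FoldResult(
                fold=fold_i,
                reports=_pattern_reports(models, te),
                n_train=len(tr),
                n_test=len(te),
            )
        )
    return folds


def mean_auc(folds: list[FoldResult]) -> pd.DataFrame:
    """Per-pattern, per-method mean and best AUC across folds."""
    tables = []
    for f in folds:
        t = reports_to_table(f.reports)
        t["fold"] = f.fold
        tables.append(t)
    df = pd.concat(tables, ignore_index=True)
    return (
        df.groupby(["pattern", "method"])["auc"]
        .agg(mean_auc="mean", best_auc="max")
        .reset_index()
    )


def pairwise_feature_test(
    features: list[FeatureRecord],
    feature_name: str,
    class_a: int,
    class_b: int,
    method: str = "welch",
) -> float:
    """Two-sided two-sample location test of one feature between two classes.

    ``method="welch"`` uses the unequal-variance t-test,
    ``method="mannwhitney"`` the Mann–Whitney U test.  Degenerate input with
    zero spread and equal means returns p = 1.
    """
    if feature_name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}")
    j = FEATURE_NAMES.index(feature_name)
    X, y = feature_matrix(features)
    xa = X[y == class_a, j]
    xb = X[y == class_b, j]
    if xa.size < 2 or xb.size < 2:
        raise ValueError("both classes need at least 2 records")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
        return 1.0
    if method == "welch":
        res = stats.ttest_ind(xa, xb, equal_var=False)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    else:
        raise ValueError("method must be 'welch' or 'mannwhitney'")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def feature_significance_table(
    features: list[FeatureRecord], method: str = "welch"
) -> pd.DataFrame:
    """Full 10-pair x 6-feature p-value table for the present classes."""
    _, y = feature_matrix(features)
    classes = sorted(set(int(c) for c in np.unique(y)))
    rows = []
    for a, b in combinations(classes, 2):
        row: dict[str, object] = {"pattern": f"{a}-{b}"}
        for name in FEATURE_NAMES:
            row[name] = pairwise_feature_test(features, name, a, b, method=method)
        rows.append(row)
    return pd.DataFrame(rows)
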