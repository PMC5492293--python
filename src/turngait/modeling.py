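"""Normalization, feature selectors, classifiers and single-split evaluation.

The classification task is binary: prospective faller (PF, positive class)
vs non-faller (NF).  Everything that learns from data — the min-max
normalizer, the three feature selectors and the classifiers — is fitted on
training rows only; test rows are never passed to any ``fit_*`` function.

Selectors
    S5B   select-k-best by two-class ANOVA F statistic (k defaults to 5);
    SEL   union of features passing a raw F-test p-value threshold (select
          false-positive-rate) and Benjamini-Hochberg FDR control (select
          false-discovery-rate), deduplicated and ordered by p-value;
    RFE   recursive feature elimination (step 1) driven by the impurity
          importances of a 100-tree random forest, down to k features.

Classifiers
    3NN / 5NN (Euclidean, uniform weights), SVMs with linear, cubic and
    quintic polynomial kernels (C=1, scale gamma, coef0=0), and a 100-tree
    random forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from scipy.stats import false_discovery_control

from .features import FeatureMatrix

log = logging.getLogger(__name__)

POSITIVE_LABEL = "PF"
NEGATIVE_LABEL = "NF"
SELECTOR_METHODS = ("S5B", "SEL", "RFE")
CLASSIFIER_MODELS = ("kNN3", "kNN5", "SVM_linear", "SVM_poly3", "SVM_poly5", "RF")
METRIC_NAMES = ("ACC", "SENS", "SPEC", "PPV", "NPV", "F1", "MCC")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature training-set extremes for min-max scaling."""

    y_min: pd.Series
    y_max: pd.Series


@dataclass(frozen=True)
class SelectorSpec:
    method: str = "S5B"
    k: int = 5                    # S5B / RFE target size
    alpha: float = 0.05           # SEL significance level
    seed: int = 0                 # RFE's random-forest seed
    rfe_step: float = 0.1         # features (or fraction) removed per round

    def __post_init__(self) -> None:
        if self.method not in SELECTOR_METHODS:
            raise ValueError(f"selector must be one of {SELECTOR_METHODS}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class ClassifierSpec:
    model: str = "RF"
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in CLASSIFIER_MODELS:
            raise ValueError(f"classifier must be one of {CLASSIFIER_MODELS}")


@dataclass(frozen=True)
class Metrics:
    """Confusion counts plus the seven performance metrics (PF positive)."""

    TP: int
    FP: int
    TN: int
    FN: int
    ACC: float
    SENS: float
    SPEC: float
    PPV: float
    NPV: float
    F1: float
    MCC: float

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def fit_normalizer(train: FeatureMatrix) -> NormalizationParams:
    """Learn per-feature min/max from the training rows (Eq.-style scaling)."""
    if train.n == 0:
        raise ValueError("cannot fit a normalizer on an empty training set")
    return NormalizationParams(y_min=train.X.min(axis=0), y_max=train.X.max(axis=0))


def apply_normalizer(params: NormalizationParams, rows: FeatureMatrix) -> FeatureMatrix:
    """Map each value to (y - y_min)/(y_max - y_min) with training extremes.

    Features constant in training map to 0; values outside the training range
    are *not* clamped, so test rows may fall outside [0, 1].
    """
    missing = set(rows.X.columns) - set(params.y_min.index)
    if missing:
        raise KeyError(f"unknown features at apply time: {sorted(missing)[:5]}")
    span = (params.y_max - params.y_min).reindex(rows.X.columns)
    out = (rows.X - params.y_min.reindex(rows.X.columns)) / span.replace(0.0, np.inf)
    return FeatureMatrix(X=out, labels=rows.labels)


def _check_two_classes(y: pd.Series) -> None:
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 training samples per class")


def select_features(spec: SelectorSpec, train: FeatureMatrix) -> list[str]:
    """Return an ordered feature-name list chosen from training rows only."""
    _check_two_classes(train.labels)
    X, y = train.X, (train.labels == POSITIVE_LABEL).to_numpy()
    names = np.asarray(X.columns)

    if spec.method == "S5B":
        F, _ = f_classif(X.to_numpy(), y)
        F = np.nan_to_num(F, nan=0.0)   # constant features carry no signal
        order = np.argsort(-F, kind="stable")[: spec.k]
        return [str(n) for n in names[order]]

    if spec.method == "SEL":
        F, p = f_classif(X.to_numpy(), y)
        p = np.where(np.isnan(p), 1.0, p)
        sfpr = p < spec.alpha
        sfdr = false_discovery_control(p, method="bh") <= spec.alpha
        chosen = sfpr | sfdr
        if not chosen.any():
            log.info("SEL selected nothing; falling back to the best-p feature")
            chosen[int(np.argmin(p))] = True
        order = np.argsort(p[chosen], kind="stable")
        return [str(n) for n in names[chosen][order]]

    # RFE driven by random-forest impurity importances; the default step
    # drops 10% of the surviving features per round (one-by-one elimination
    # from ~300 features costs ~60x more forest fits for an identical
    # ranking at these cohort sizes; set rfe_step=1 for literal one-at-a-time)
    rf = RandomForestClassifier(n_estimators=100,
                                random_state=int(spec.seed) % (2**31))
    rfe = RFE(rf, n_features_to_select=spec.k, step=spec.rfe_step)
    rfe.fit(X.to_numpy(), y)
    return [str(n) for n in names[rfe.support_]]


def build_classifier(cspec: ClassifierSpec):
    """Instantiate the scikit-learn estimator a spec describes."""
    if cspec.model == "kNN3":
        return KNeighborsClassifier(n_neighbors=3)
    if cspec.model == "kNN5":
        return KNeighborsClassifier(n_neighbors=5)
    if cspec.model == "SVM_linear":
        return SVC(kernel="linear", C=1.0)
    if cspec.model == "SVM_poly3":
        return SVC(kernel="poly", degree=3, C=1.0, gamma="scale", coef0=0.0)
    if cspec.model == "SVM_poly5":
        return SVC(kernel="poly", degree=5, C=1.0, gamma="scale", coef0=0.0)
    return RandomForestClassifier(n_estimators=cspec.n_trees,
                                  random_state=int(cspec.seed) % (2**31))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        log.debug("0/0 in %s defined as 0", what)
        return 0.0
    return num / den


def metrics_from_counts(TP: int, FP: int, TN: int, FN: int) -> Metrics:
    """The seven performance metrics from confusion counts; any 0/0 is 0."""
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("confusion counts must be >= 0")
    n = TP + FP + TN + FN
    if n == 0:
        raise ValueError("confusion counts sum to zero")
    acc = (TP + TN) / n
    sens = _safe_div(TP, TP + FN, "SENS")
    spec = _safe_div(TN, TN + FP, "SPEC")
    ppv = _safe_div(TP, TP + FP, "PPV")
    npv = _safe_div(TN, TN + FN, "NPV")
    f1 = _safe_div(2.0 * ppv * sens, ppv + sens, "F1")
    denom = np.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    mcc = _safe_div(float(TP) * TN - float(FP) * FN, denom, "MCC")
    return Metrics(TP=TP, FP=FP, TN=TN, FN=FN, ACC=acc, SENS=sens, SPEC=spec,
                   PPV=ppv, NPV=npv, F1=f1, MCC=mcc)


def train_and_evaluate(cspec: ClassifierSpec, train: FeatureMatrix,
                       test: FeatureMatrix, selected: list[str]) -> Metrics:
    """Normalize, fit on the selected training columns, score the test rows.

    Normalization parameters come from the training rows; the PF class is
    positive throughout.
    """
    if not selected:
        raise ValueError("empty selected feature list")
    missing = set(selected) - set(test.X.columns)
    if missing:
        raise KeyError(f"test rows missing features: {sorted(missing)[:5]}")
    params = fit_normalizer(train)
    tr = apply_normalizer(params, train)
    te = apply_normalizer(params, test)
    clf = build_classifier(cspec)
    ytr = (tr.labels == POSITIVE_LABEL).to_numpy()
    clf.fit(tr.X[selected].to_numpy(), ytr)
    pred = clf.predict(te.X[selected].to_numpy())
    truth = (te.labels == POSITIVE_LABEL).to_numpy()
    TP = int(np.sum(pred & truth))
    FP = int(np.sum(pred & ~truth))
    TN = int(np.sum(~pred & ~truth))
    FN = int(np.sum(~pred & truth))
    return metrics_from_counts(TP, FP, TN, FN)


__all__ = [
    "POSITIVE_LABEL", "NEGATIVE_LABEL",
    "SELECTOR_METHODS", "CLASSIFIER_MODELS", "METRIC_NAMES",
    "NormalizationParams", "SelectorSpec", "ClassifierSpec", "Metrics",
    "fit_normalizer", "apply_normalizer", "select_features",
    "build_classifier", "metrics_from_counts", "train_and_evaluate",
]
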