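"""Training classifiers on anonymized data and measuring their
performance relative to models trained on the original records.

The protocol: split the record indices of the *original* dataset into
stratified folds.  Per fold, (a) a classifier is trained on the
anonymized rows of the training folds (fully suppressed rows dropped)
and evaluated on the held-out *original* rows after preprocessing them
exactly as the training data was transformed (generalization and
categorization re-applied; suppression, sampling and aggregation leave
the value domain intact and need no preprocessing); (b) the same
classifier type and a zero-rule baseline are trained on the unmodified
training folds.  Pooled out-of-fold predictions yield one-vs-all ROC
AUCs, Brier scores and the two relative measures: relative AUC
(anonymized vs original, both measured above the zero-rule baseline) and
the Brier skill score 1 − Brier_anonymized / Brier_original.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .anonymizer import AnonymizationResult
from .dataset import AttributeConfig, Dataset, GeneralizationScheme
from .errors import ConfigError, DegenerateModelError, UndefinedMetricError
from .hierarchy import Hierarchy

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "preprocess_features",
    "train",
    "evaluate_relative",
    "roc_and_auc",
    "one_vs_all",
    "brier_score",
    "brier_skill_score",
    "relative_auc",
]

CLASSIFIER_KINDS = ("logistic_regression", "naive_bayes", "random_forest", "zero_rule")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier type plus the hyperparameters that matter here."""

    kind: str = "logistic_regression"
    regularization: float = 1.0  # inverse strength C (logistic regression)
    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigError(f"unknown classifier kind {self.kind!r}")


def _estimator(spec: ClassifierSpec):
    if spec.kind == "logistic_regression":
        return LogisticRegression(C=spec.regularization, max_iter=2000)
    if spec.kind == "naive_bayes":
        return GaussianNB()
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, max_depth=spec.max_depth, random_state=spec.seed
        )
    return DummyClassifier(strategy="prior")


def _feature_kinds(
    features: Sequence[str],
    base_kinds: Mapping[str, str],
    scheme: GeneralizationScheme | None,
) -> tuple[list[str], list[str]]:
    """Split features into numeric vs categorical for encoding purposes.

    A declared-numeric attribute stays numeric only while untouched by
    generalization (level 0); generalized or categorized values are opaque
    labels to the model and are one-hot encoded like any category.
    """
    numeric, categorical = [], []
    for a in features:
        level = scheme.level(a) if scheme is not None else 0
        if base_kinds.get(a) == "numeric" and level == 0:
            numeric.append(a)
        else:
            categorical.append(a)
    return numeric, categorical


def _pipeline(spec: ClassifierSpec, numeric: list[str], categorical: list[str]) -> Pipeline:
    num_steps = [("to_float", _NumericCoercer()), ("impute", SimpleImputer(strategy="mean"))]
    if spec.kind == "logistic_regression":
        num_steps.append(("scale", StandardScaler()))
    transformers = []
    if numeric:
        transformers.append(("num", Pipeline(num_steps), numeric))
    if categorical:
        transformers.append(
            ("cat", OneHotEncoder(handle_unknown="ignore", sparse_output=False), categorical)
        )
    ct = ColumnTransformer(transformers, remainder="drop")
    return Pipeline([("encode", ct), ("model", _estimator(spec))])


class _NumericCoercer:
    """Coerce text cells to floats; unparseable cells (e.g. suppression
    tokens) become NaN for the imputer."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.column_stack(
            [pd.to_numeric(pd.Series(np.asarray(X)[:, j]), errors="coerce").to_numpy(float)
             for j in range(np.asarray(X).shape[1])]
        )

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self


def preprocess_features(
    records: pd.DataFrame,
    scheme: GeneralizationScheme,
    hierarchies: Mapping[str, Hierarchy],
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Transform raw feature values the way the anonymized training data
    was transformed: re-apply generalization/categorization at the
    scheme's levels; everything else (suppression, sampling, aggregation)
    passes through because those transformations preserve the domain.
    Unknown values map to the hierarchy's top level, so a deployed model
    never fails on unseen input.
    """
    out = records.copy()
    cols = features if features is not None else out.columns
    for a in cols:
        level = scheme.level(a)
        if level == 0 or a not in out.columns:
            continue
        h = hierarchies.get(a)
        if h is None:
            raise ConfigError(f"attribute {a!r} generalized but has no hierarchy")
        uniq = out[a].unique()
        mapping = {v: h.generalize(str(v), level, unknown="top") for v in uniq}
        out[a] = out[a].map(mapping)
    return out


def train(
    spec: ClassifierSpec,
    d: Dataset,
    features: Sequence[str],
    target: str,
    scheme: GeneralizationScheme | None = None,
) -> Pipeline:
    """Fit a classifier on the unsuppressed rows of ``d``.

    ``scheme`` tells the encoder which declared-numeric features have been
    turned into categorical labels by generalization.
    """
    keep = ~d.suppressed
    X = d.df.loc[keep, list(features)]
    y = d.df.loc[keep, target].to_numpy(object)
    if spec.kind != "zero_rule" and len(np.unique(y)) < 2:
        raise DegenerateModelError(
            f"training data has {len(np.unique(y))} target class(es); need >= 2"
        )
    numeric, categorical = _feature_kinds(features, d.kinds, scheme)
    pipe = _pipeline(spec, numeric, categorical)
    pipe.fit(X, y)
    return pipe


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and its trapezoid area.

    ``labels`` are 0/1 (or boolean); the AUC equals the rank statistic —
    the probability that a positive outranks a negative, ties counted ½.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class ClassMetrics:
    label: str
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float | None


def one_vs_all(
    probabilities: np.ndarray,
    labels: np.ndarray,
    class_order: Sequence[str],
) -> tuple[list[ClassMetrics], float]:
    """Evaluate an n-class probabilistic classifier as n one-vs-rest
    binary classifiers; returns per-class metrics and the unweighted macro
    AUC (classes absent from the evaluation data are excluded with a
    warning)."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pred = np.asarray(class_order, dtype=object)[np.argmax(probabilities, axis=1)]
    per_class: list[ClassMetrics] = []
    aucs = []
    for j, c in enumerate(class_order):
        pos = labels == c
        tp = int(np.sum(pos & (pred == c)))
        fn = int(np.sum(pos & (pred != c)))
        tn = int(np.sum(~pos & (pred != c)))
        fp = int(np.sum(~pos & (pred == c)))
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        if pos.all() or not pos.any():
            warnings.warn(
                f"class {c!r} has no positives/negatives in the evaluation data; "
                "AUC undefined and excluded from the macro average"
            )
            per_class.append(ClassMetrics(c, sens, spec, np.array([]), np.array([]), None))
            continue
        fpr, tpr, auc = roc_and_auc(probabilities[:, j], pos)
        aucs.append(auc)
        per_class.append(ClassMetrics(c, sens, spec, fpr, tpr, auc))
    if not aucs:
        raise UndefinedMetricError("no class with defined AUC")
    return per_class, float(np.mean(aucs))


def brier_score(probabilities: np.ndarray, labels: np.ndarray, class_order: Sequence[str]) -> float:
    """Multiclass Brier score: mean over records of the squared distance
    between the predicted distribution and the one-hot outcome.  Full
    vector convention, range [0, 2]."""
    probabilities = np.asarray(probabilities, dtype=float)
    sums = probabilities.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("each predicted distribution must sum to 1 (tolerance 1e-9)")
    onehot = (np.asarray(labels, dtype=object)[:, None] == np.asarray(class_order, dtype=object)[None, :]).astype(float)
    return float(np.mean(np.sum((probabilities - onehot) ** 2, axis=1)))


def brier_skill_score(brier_anonymized: float, brier_original: float) -> float:
    """1 − Brier_anonymized / Brier_original.  Zero when equal; positive
    (up to 1) when the anonymized-trained model is better; negative,
    unbounded below, when the original-trained model is better."""
    if brier_original == 0.0:
        return 0.0 if brier_anonymized == 0.0 else float("-inf")
    return 1.0 - brier_anonymized / brier_original


def relative_auc(
    auc_anonymized: float,
    auc_original: float,
    auc_baseline: float,
    floor: float | None = 0.0,
) -> float:
    """Percentage position of the anonymized model between the baseline
    (0%) and the original-data model (100%)."""
    denom = auc_original - auc_baseline
    if denom <= 0:
        raise UndefinedMetricError(
            "relative AUC undefined: original model does not beat the baseline"
        )
    value = 100.0 * (auc_anonymized - auc_baseline) / denom
    if floor is not None:
        value = max(value, floor)
    return value


@dataclass
class ModelMetrics:
    per_class: list[ClassMetrics]
    macro_auc: float
    brier: float
    accuracy: float


@dataclass
class EvaluationReport:
    """Pooled cross-validated performance of the anonymized-trained model
    next to the original-trained model and the zero-rule baseline."""

    target: str
    classes: list[str]
    anonymized: ModelMetrics
    original: ModelMetrics
    baseline: ModelMetrics
    relative_auc: float
    brier_skill: float
    folds: int
    seed: int
    classifier: ClassifierSpec
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        rows = [
            ("macro ROC AUC", "macro_auc", "{:.4f}"),
            ("Brier score", "brier", "{:.4f}"),
            ("accuracy", "accuracy", "{:.4f}"),
        ]
        lines = [
            f"Relative performance report — target {self.target!r} "
            f"({self.classifier.kind}, {self.folds}-fold, seed {self.seed})",
            "=" * 72,
            f"{'metric':<16}{'original':>12}{'anonymized':>12}{'0-R baseline':>14}",
        ]
        for label, attr, fmt in rows:
            lines.append(
                f"{label:<16}"
                f"{fmt.format(getattr(self.original, attr)):>12}"
                f"{fmt.format(getattr(self.anonymized, attr)):>12}"
                f"{fmt.format(getattr(self.baseline, attr)):>14}"
            )
        lines.append("-" * 72)
        lines.append(f"relative ROC AUC   {self.relative_auc:.2f}%")
        lines.append(f"Brier skill score  {self.brier_skill:.4f}")
        return "\n".join(lines)


def _proba_matrix(model: Pipeline | None, X: pd.DataFrame, class_order: list[str], prior: np.ndarray | None = None) -> np.ndarray:
    """Class probabilities aligned to ``class_order`` (absent classes get 0;
    ``model=None`` falls back to the supplied prior or uniform)."""
    n = len(X)
    k = len(class_order)
    out = np.zeros((n, k))
    if model is None:
        p = prior if prior is not None else np.full(k, 1.0 / k)
        out[:] = p
        return out
    proba = model.predict_proba(X)
    index = {c: j for j, c in enumerate(class_order)}
    for i, c in enumerate(model.classes_):
        j = index.get(c)
        if j is not None:
            out[:, j] = proba[:, i]
    # renormalize in case the model knows classes outside class_order
    out /= np.maximum(out.sum(axis=1, keepdims=True), 1e-300)
    return out


def evaluate_relative(
    d_input: Dataset,
    anonym: AnonymizationResult,
    config: AttributeConfig,
    spec: ClassifierSpec,
    target: str | None = None,
    folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Fig-of-merit evaluation: train on anonymized data, test on
    preprocessed original data, against original-trained and zero-rule
    references, via stratified k-fold cross-validation over record
    indices shared by all three models."""
    config.require_targets()
    target = target or config.targets[0]
    features = config.quasi_identifiers
    scheme = anonym.scheme
    hierarchies = config.hierarchies
    # Record suppression keeps row alignment with the input; random
    # sampling does not.  Sampling-based releases therefore train the
    # anonymized-side model once on the whole release (the model never
    # sees raw records, so there is no raw train/test leakage), while the
    # original-trained and baseline models still honour the folds.
    aligned = anonym.output.n_records == d_input.n_records
    y_all = d_input.df[target].to_numpy(object)
    # if the target itself was generalized, evaluate in the generalized space
    if scheme.level(target) > 0:
        y_all = preprocess_features(d_input.df[[target]], scheme, hierarchies)[target].to_numpy(object)
    class_counts = pd.Series(y_all).value_counts()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if class_counts.min() < folds:
        raise UndefinedMetricError(
            f"cannot stratify {folds} folds: class {class_counts.idxmin()!r} has "
            f"only {class_counts.min()} records"
        )
    class_order = sorted(class_counts.index.tolist())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    X_raw = d_input.df[features]
    X_pre = preprocess_features(X_raw, scheme, hierarchies, features)
    pooled: dict[str, list[np.ndarray]] = {"anon": [], "orig": [], "base": []}
    pooled_labels: list[np.ndarray] = []

    def _fit_anon(rows: pd.DataFrame):
        """Anonymized-side model, or (None, priors) when degenerate."""
        y_anon = rows[target].to_numpy(object) if len(rows) else np.array([], dtype=object)
        if len(np.unique(y_anon)) >= 2:
            sub = Dataset(rows, dict(anonym.output.kinds))
            return train(spec, sub, features, target, scheme=scheme), None
        prior = (
            np.array([np.mean(y_anon == c) for c in class_order], dtype=float)
            if len(y_anon)
            else None
        )
        return None, prior

    global_anon_model, global_prior = (None, None)
    if not aligned:
        all_rows = anonym.output.df.loc[~anonym.output.suppressed]
        global_anon_model, global_prior = _fit_anon(all_rows)
    for train_idx, test_idx in skf.split(np.zeros(len(y_all)), y_all):
        if aligned:
            anon_train = anonym.output.df.iloc[train_idx]
            anon_sup = anonym.output.suppressed[train_idx]
            anon_model, prior = _fit_anon(anon_train.loc[~anon_sup])
        else:
            anon_model, prior = global_anon_model, global_prior
        # original-trained model and 0-R baseline
        orig_sub = Dataset(d_input.df.iloc[train_idx], dict(d_input.kinds))
        orig_model = train(spec, orig_sub, features, target)
        base_model = train(
            ClassifierSpec(kind="zero_rule", seed=spec.seed), orig_sub, features, target
        )
        X_test_pre = X_pre.iloc[test_idx]
        X_test_raw = X_raw.iloc[test_idx]
        pooled["anon"].append(_proba_matrix(anon_model, X_test_pre, class_order, prior))
        pooled["orig"].append(_proba_matrix(orig_model, X_test_raw, class_order))
        pooled["base"].append(_proba_matrix(base_model, X_test_raw, class_order))
        pooled_labels.append(y_all[test_idx])
    labels = np.concatenate(pooled_labels)
    metrics: dict[str, ModelMetrics] = {}
    for key in ("anon", "orig", "base"):
        proba = np.vstack(pooled[key])
        per_class, macro = one_vs_all(proba, labels, class_order)
        brier = brier_score(proba, labels, class_order)
        pred = np.asarray(class_order, dtype=object)[np.argmax(proba, axis=1)]
        acc = float(np.mean(pred == labels))
        metrics[key] = ModelMetrics(per_class, macro, brier, acc)
    rel = relative_auc(
        metrics["anon"].macro_auc, metrics["orig"].macro_auc, metrics["base"].macro_auc
    )
    skill = brier_skill_score(metrics["anon"].brier, metrics["orig"].brier)
    return EvaluationReport(
        target=target,
        classes=class_order,
        anonymized=metrics["anon"],
        original=metrics["orig"],
        baseline=metrics["base"],
        relative_auc=rel,
        brier_skill=skill,
        folds=folds,
        seed=seed,
        classifier=spec,
    )
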