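"""Post-hoc group classification from per-session synchrony features.

Binary classification (e.g. ASD vs non-ASD) from the N-segment synchrony
means, with per-measure feature sets or early fusion (column concatenation),
three standard classifiers plus a majority-class baseline, repeated
stratified k-fold cross-validation, and macro-F1 scoring.  A two-way ANOVA
utility analyses score variation across age group and gender.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_recall_fscore_support
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .session_pipeline import MEASURES, SessionFeatures

__all__ = [
    "ExperimentConfig",
    "ClassificationReport",
    "AnovaResult",
    "run_experiment",
    "two_way_anova",
    "majority_macro_f1",
]

CLASSIFIERS = ("svm_rbf", "svm_linear", "logistic", "majority")


@dataclass(frozen=True)
class ExperimentConfig:
    """One classification experiment.

    feature_sets: which measures' segment means enter the feature vector;
        with ``fusion="early"`` multiple sets are concatenated before the
        single classifier fit.
    cv: repeated stratified k-fold (defaults 5 folds x 10 repeats — small
        cohorts need the repeats to stabilise the fold-level F1).
    """

    classifier: str = "svm_rbf"
    feature_sets: tuple[str, ...] = ("dtwd_prosodic",)
    fusion: str = "single"
    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        unknown = set(self.feature_sets) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown feature sets: {sorted(unknown)}")
        if not self.feature_sets:
            raise ValueError("need at least one feature set")
        if self.fusion not in ("single", "early"):
            raise ValueError("fusion must be single|early")
        if self.fusion == "single" and len(self.feature_sets) > 1:
            raise ValueError("fusion='single' takes exactly one feature set")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class ClassificationReport:
    config: ExperimentConfig
    fold_f1: np.ndarray
    mean_macro_f1: float
    per_class: dict  # class -> {"precision": .., "recall": .., "f1": ..}
    classes: tuple[str, ...]
    n_features: int


def _make_estimator(cfg: ExperimentConfig):
    if cfg.classifier == "svm_rbf":
        clf = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=cfg.seed)
    elif cfg.classifier == "svm_linear":
        clf = SVC(kernel="linear", C=1.0, random_state=cfg.seed)
    elif cfg.classifier == "logistic":
        clf = LogisticRegression(max_iter=1000, random_state=cfg.seed)
    else:
        return DummyClassifier(strategy="most_frequent")
    # scaler fit on the training folds only — no test-fold leakage
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def design_matrix(
    features: list[SessionFeatures], feature_sets: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with columns = concatenated segment means of the chosen sets."""
    X = np.stack([sf.vector(feature_sets) for sf in features])
    y = np.array([sf.label for sf in features], dtype=object)
    if any(lbl is None for lbl in y):
        raise ValueError("all sessions must carry a label")
    return X, y


def run_experiment(
    features: list[SessionFeatures], cfg: ExperimentConfig | None = None
) -> ClassificationReport:
    """Repeated stratified CV of one classifier on one feature combination."""
    cfg = cfg or ExperimentConfig()
    X, y = design_matrix(features, cfg.feature_sets)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} sessions; fewer than {cfg.n_folds} folds"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=cfg.n_folds, n_repeats=cfg.n_repeats, random_state=cfg.seed
    )
    fold_f1 = []
    y_true_all, y_pred_all = [], []
    for train, test in splitter.split(X, y):
        est = _make_estimator(cfg)
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        fold_f1.append(f1_score(y[test], pred, labels=classes, average="macro", zero_division=0))
        y_true_all.append(y[test])
        y_pred_all.append(pred)
    fold_f1 = np.array(fold_f1)
    p, r, f, _ = precision_recall_fscore_support(
        np.concatenate(y_true_all),
        np.concatenate(y_pred_all),
        labels=classes,
        zero_division=0,
    )
    per_class = {
        str(c): {"precision": float(p[i]), "recall": float(r[i]), "f1": float(f[i])}
        for i, c in enumerate(classes)
    }
    return ClassificationReport(
        config=cfg,
        fold_f1=fold_f1,
        mean_macro_f1=float(fold_f1.mean()),
        per_class=per_class,
        classes=tuple(str(c) for c in classes),
        n_features=X.shape[1],
    )


def majority_macro_f1(labels) -> float:
    """Closed-form macro-F1 of always predicting the majority class.

    With majority prevalence p, the majority class scores
    F1 = 2p / (1 + p) (precision p, recall 1) and every other class scores
    0, so macro-F1 = 2p / (C (1 + p)) for C classes.  A 60/40 binary split
    gives 0.375.
    """
    labels = np.asarray(labels, dtype=object)
    classes, counts = np.unique(labels, return_counts=True)
    p = counts.max() / counts.sum()
    return float(2 * p / (1 + p) / len(classes))


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame
    f_stats: dict
    p_values: dict


def two_way_anova(scores: pd.DataFrame, value_col: str = "f1") -> AnovaResult:
    """Two-way ANOVA of scores across ``age_group`` and ``gender``.

    Fits ``value ~ C(age_group) * C(gender)`` and returns the standard
    decomposition (main effects, interaction, residual) with F statistics
    and p-values.  Errors when any age x gender cell is empty or has fewer
    than two observations, since the interaction model is then degenerate.
    """
    required = {value_col, "age_group", "gender"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table missing columns: {sorted(missing)}")
    ages = sorted(scores["age_group"].unique())
    genders = sorted(scores["gender"].unique())
    bad = [
        (a, g)
        for a, g in product(ages, genders)
        if len(scores[(scores["age_group"] == a) & (scores["gender"] == g)]) < 2
    ]
    if bad:
        raise ValueError(f"cells with fewer than 2 observations: {bad}")
    df = scores.rename(columns={value_col: "_value"})
    model = smf.ols("_value ~ C(age_group) * C(gender)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key = {
        "C(age_group)": "age_group",
        "C(gender)": "gender",
        "C(age_group):C(gender)": "interaction",
    }
    f_stats = {key[k]: float(table.loc[k, "F"]) for k in key if k in table.index}
    p_values = {key[k]: float(table.loc[k, "PR(>F)"]) for k in key if k in table.index}
    return AnovaResult(table=table, f_stats=f_stats, p_values=p_values)
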