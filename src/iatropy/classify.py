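"""Exercise-behavior classification from D-scores or entropy features.

Protocol: 10 repetitions of stratified random 70/30 train/test splits
(seeded), with per-repeat metrics computed from the test-set confusion
matrix and reported as mean +- SD in percent; a stratified k-fold mode is
available.  The *non-exercise* group is the positive class throughout, so
sensitivity measures detection of non-exercisers.  Features are
standardized on the training split only for KNN/SVM/LDA; random forests
operate on raw features.

Classifiers (fixed hyperparameters): random forest with 100 trees and
minimum leaf size 5; KNN with 5 Euclidean neighbors; RBF-kernel SVM with
box constraint C = 1 and the median-heuristic kernel scale estimated on the
training split; LDA (least-squares solver with automatic shrinkage when the
feature count reaches the training-set size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import pairwise_distances, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .entropy import METRICS
from .montage import (BLOCK_ABBR, CONDITION_PARTS, CONDITIONS, IAT_ABBR,
                      REGION_ABBR, REGIONS)
from .rng import child_seeds

log = logging.getLogger(__name__)

POSITIVE_CLASS = "non_exercise"
CLASSIFIERS = ("RF", "KNN", "SVM", "LDA")


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which feature block feeds the classifier."""

    source: str = "envelope_only"  # dscore | all_entropy | envelope_only
    iat_scope: str = "affective"  # affective | instrumental | combined
    condition_scope: str = "both"  # compatible | incompatible | both

    def __post_init__(self) -> None:
        if self.source not in ("dscore", "all_entropy", "envelope_only"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.iat_scope not in ("affective", "instrumental", "combined"):
            raise ValueError(f"unknown iat_scope {self.iat_scope!r}")
        if self.condition_scope not in ("compatible", "incompatible", "both"):
            raise ValueError(f"unknown condition_scope {self.condition_scope!r}")

    @property
    def conditions(self) -> tuple[str, ...]:
        iats = ("affective", "instrumental") if self.iat_scope == "combined" else (self.iat_scope,)
        blocks = ("compatible", "incompatible") if self.condition_scope == "both" \
            else (self.condition_scope,)
        return tuple(c for c, (i, b) in CONDITION_PARTS.items() if i in iats and b in blocks)

    @property
    def metrics(self) -> tuple[str, ...]:
        return METRICS if self.source == "all_entropy" else ("envelope",)


@dataclass(frozen=True)
class EvalProtocol:
    kind: str = "repeated_split"  # or "kfold"
    n_repeats: int = 10
    test_size: float = 0.3
    n_splits: int = 10
    standardize: bool = True


def feature_label(condition: str, region: str, metric: str, source: str) -> str:
    """Short feature label, e.g. fronto-central affective incompatible -> FC_A_IC."""
    iat, block = CONDITION_PARTS[condition]
    base = f"{REGION_ABBR[region]}_{IAT_ABBR[iat]}_{BLOCK_ABBR[block]}"
    return base if source == "envelope_only" else f"{base}_{metric}"


def build_design(
    spec: FeatureSetSpec,
    feature_table: pd.DataFrame | None = None,
    dscores: pd.DataFrame | None = None,
    labels: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Participants x features design matrix (condition-major, region-minor,
    metric-innermost column order) plus labels when provided.

    ``dscores`` needs columns participant_id, iat_type, d_score; the feature
    table is the long format from :mod:`iatropy.features`.  Participants
    with missing features are dropped with a log message.
    """
    if spec.source == "dscore":
        if dscores is None:
            raise ValueError("dscore design requires dscores")
        iats = ("affective", "instrumental") if spec.iat_scope == "combined" else (spec.iat_scope,)
        sub = dscores[dscores["iat_type"].isin(iats)]
        X = sub.pivot_table(index="participant_id", columns="iat_type",
                            values="d_score", sort=False)
        X = X[[i for i in iats if i in X.columns]]
        X.columns = [f"D_{IAT_ABBR[i]}" for i in X.columns]
    else:
        if feature_table is None:
            raise ValueError("entropy designs require a feature table")
        sub = feature_table[
            feature_table["condition"].isin(spec.conditions)
            & feature_table["metric"].isin(spec.metrics)
        ]
        X = sub.pivot_table(index="participant_id",
                            columns=["condition", "region", "metric"],
                            values="value", sort=False)
        ordered = [
            (c, r, m)
            for c in spec.conditions for r in REGIONS for m in spec.metrics
            if (c, r, m) in X.columns
        ]
        X = X[ordered]
        X.columns = [feature_label(c, r, m, spec.source) for c, r, m in ordered]
    n_before = len(X)
    X = X.dropna()
    if len(X) < n_before:
        log.warning("dropped %d participants with missing features", n_before - len(X))
    y = None
    if labels is not None:
        y = pd.Series({p: labels[p] for p in X.index if p in labels}, name="group")
        X = X.loc[y.index]
    return X, y


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d = pairwise_distances(X)
    med = np.median(d[np.triu_indices_from(d, k=1)])
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


def _make_classifier(name: str, seed: int, X_train: np.ndarray):
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, min_samples_leaf=5,
                                      random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma=_median_heuristic_gamma(X_train))
    if name == "LDA":
        if X_train.shape[1] >= X_train.shape[0]:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _positive_scores(clf, name: str, X: np.ndarray) -> np.ndarray:
    if name == "SVM":
        s = clf.decision_function(X)
        return s if clf.classes_[1] == 1 else -s
    proba = clf.predict_proba(X)
    return proba[:, list(clf.classes_).index(1)]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    return {
        "TP": int(((y_true == 1) & (y_pred == 1)).sum()),
        "FP": int(((y_true == 0) & (y_pred == 1)).sum()),
        "TN": int(((y_true == 0) & (y_pred == 0)).sum()),
        "FN": int(((y_true == 1) & (y_pred == 0)).sum()),
    }


def _metrics_from_counts(c: Mapping[str, int]) -> dict[str, float]:
    tp, fp, tn, fn = c["TP"], c["FP"], c["TN"], c["FN"]
    total = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else np.nan
    return {
        "accuracy": 100.0 * (tp + tn) / total,
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "precision": 100.0 * prec,
        "f1": 100.0 * f1,
    }


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass
class ClassificationResults:
    """Cross-validated performance of one classifier on one feature set."""

    classifier: str
    spec: FeatureSetSpec | None
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    per_repeat: pd.DataFrame
    confusion_totals: dict[str, int]
    auc: float
    roc_points: pd.DataFrame
    importances: pd.DataFrame | None  # RF only
    feature_names: list[str]
    seed: int

    def top5_importances(self) -> pd.DataFrame:
        return rf_importance_top5(self.importances)

    def plot_roc(self, ax=None):
        """ROC curve with the AUC in the legend (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.roc_points["fpr"], self.roc_points["tpr"],
                label=f"{self.classifier} (AUC = {self.auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right", frameon=False)
        return ax

    def summary(self) -> str:
        head = f"{self.classifier}"
        if self.spec is not None:
            head += f" | {self.spec.source} / {self.spec.iat_scope} / {self.spec.condition_scope}"
        lines = [head, f"positive class = {POSITIVE_CLASS}; "
                       f"{len(self.per_repeat)} evaluation repeats; seed {self.seed}", ""]
        lines.append(f"{'metric':<12}{'mean':>8}{'sd':>8}")
        for m in METRIC_NAMES:
            lines.append(f"{m:<12}{self.metrics_mean[m]:>8.1f}{self.metrics_sd[m]:>8.1f}")
        lines.append(f"{'auc':<12}{self.auc:>8.3f}")
        if self.importances is not None:
            lines.append("")
            lines.append("top-5 RF importances (share of top-5 total):")
            for _, row in self.top5_importances().iterrows():
                lines.append(f"  {row['feature']:<16}{row['normalized_share']:.3f}")
        return "\n".join(lines)


def evaluate(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[str],
    classifier: str = "RF",
    protocol: EvalProtocol = EvalProtocol(),
    seed: int = 0,
    spec: FeatureSetSpec | None = None,
) -> ClassificationResults:
    """Run the evaluation protocol; fully deterministic given ``seed``."""
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray([1 if lab == POSITIVE_CLASS else 0 for lab in y])
    if min((ya == 1).sum(), (ya == 0).sum()) < 2:
        raise ValueError("need at least 2 participants per class")

    if protocol.kind == "repeated_split":
        seeds = child_seeds(seed, protocol.n_repeats, "splits")
        splits = []
        for s in seeds:
            tr, te = train_test_split(np.arange(len(ya)), test_size=protocol.test_size,
                                      stratify=ya, random_state=s % (2**32 - 1))
            splits.append((tr, te))
    elif protocol.kind == "kfold":
        skf = StratifiedKFold(n_splits=protocol.n_splits, shuffle=True,
                              random_state=child_seeds(seed, 1, "kfold")[0] % (2**32 - 1))
        splits = list(skf.split(Xa, ya))
    else:
        raise ValueError(f"unknown protocol kind {protocol.kind!r}")

    clf_seeds = child_seeds(seed, len(splits), "clf")
    rows, counts_total = [], {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    pooled_scores, pooled_truth = [], []
    imps = []
    for (tr, te), s in zip(splits, clf_seeds):
        if len(np.unique(ya[te])) < 2 or len(np.unique(ya[tr])) < 2:
            log.warning("degenerate split skipped")
            continue
        X_tr, X_te = Xa[tr], Xa[te]
        if protocol.standardize and classifier != "RF":
            mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        clf = _make_classifier(classifier, s, X_tr)
        clf.fit(X_tr, ya[tr])
        y_pred = clf.predict(X_te)
        counts = _confusion(ya[te], y_pred)
        for k in counts_total:
            counts_total[k] += counts[k]
        rows.append(_metrics_from_counts(counts))
        pooled_scores.append(_positive_scores(clf, classifier, X_te))
        pooled_truth.append(ya[te])
        if classifier == "RF":
            imps.append(clf.feature_importances_)

    per_repeat = pd.DataFrame(rows)
    scores = np.concatenate(pooled_scores)
    truth = np.concatenate(pooled_truth)
    if np.ptp(scores) == 0:
        log.warning("constant classifier scores; degenerate ROC")
        auc = 0.5
        roc_df = pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0], "threshold": [np.inf, -np.inf]})
    else:
        auc = float(roc_auc_score(truth, scores))
        fpr, tpr, thr = roc_curve(truth, scores)
        roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    importances = None
    if imps:
        importances = pd.DataFrame({
            "feature": feature_names,
            "importance": np.mean(imps, axis=0),
        })
    return ClassificationResults(
        classifier=classifier,
        spec=spec,
        metrics_mean={m: float(np.nanmean(per_repeat[m])) for m in METRIC_NAMES},
        metrics_sd={m: float(np.nanstd(per_repeat[m], ddof=1)) for m in METRIC_NAMES},
        per_repeat=per_repeat,
        confusion_totals=counts_total,
        auc=auc,
        roc_points=roc_df,
        importances=importances,
        feature_names=feature_names,
        seed=seed,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[str] | Sequence[int]) -> tuple[pd.DataFrame, float]:
    """ROC points and rank-statistic AUC for positive-class scores."""
    y = np.asarray([
        lab if isinstance(lab, (int, np.integer)) else int(lab == POSITIVE_CLASS)
        for lab in labels
    ])
    s = np.asarray(scores, dtype=float)
    if np.ptp(s) == 0:
        return pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0]}), 0.5
    fpr, tpr, thr = roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), float(roc_auc_score(y, s))


def rf_importance_top5(importances: pd.DataFrame) -> pd.DataFrame:
    """Top-5 features by mean impurity-decrease importance, with each share
    normalized by the total importance of the top five."""
    if importances is None or importances.empty:
        raise ValueError("no importances available (RF only)")
    top = importances.sort_values("importance", ascending=False).head(5).copy()
    total = top["importance"].sum()
    top["normalized_share"] = top["importance"] / total if total > 0 else np.nan
    return top.reset_index(drop=True)


class ExerciseClassifier:
    """Model object: a feature design + labels + one classifier family.

    ``fit(seed)`` runs the evaluation protocol and returns
    :class:`ClassificationResults`.
    """

    def __init__(self, X: pd.DataFrame, y: Sequence[str], classifier: str = "RF",
                 protocol: EvalProtocol = EvalProtocol(), spec: FeatureSetSpec | None = None):
        self.X = X
        self.y = list(y)
        self.classifier = classifier
        self.protocol = protocol
        self.spec = spec

    @classmethod
    def from_feature_table(
        cls,
        feature_table: pd.DataFrame,
        labels: Mapping[str, str],
        spec: FeatureSetSpec = FeatureSetSpec(),
        classifier: str = "RF",
        protocol: EvalProtocol = EvalProtocol(),
        dscores: pd.DataFrame | None = None,
    ) -> "ExerciseClassifier":
        X, y = build_design(spec, feature_table=feature_table, dscores=dscores, labels=labels)
        return cls(X, list(y), classifier, protocol, spec)

    def fit(self, seed: int = 0) -> ClassificationResults:
        return evaluate(self.X, self.y, self.classifier, self.protocol, seed, self.spec)
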