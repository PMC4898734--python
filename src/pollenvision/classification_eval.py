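"""Classifier training, cross-validated evaluation and technique comparison.

Four classifier kinds mirror the Weka learners of the original study:
an SMO-style sequential SVM (linear kernel), a C-SVC-style soft-margin SVM
(RBF kernel), a pruned decision tree and K-nearest-neighbors.  Evaluation
is seeded stratified k-fold cross-validation reporting the correct
classification rate (CCR), support-weighted F-measure and one-vs-rest AUC,
per fold (mean +/- sd) and aggregated; technique combinations are compared
with one-way ANOVA followed by Tukey's HSD post-test at p < alpha.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset_io import FeatureTable, ValidationError

__all__ = [
    "ClassifierSpec",
    "ConfusionMatrix",
    "FoldMetrics",
    "EvaluationReport",
    "TechniqueComparison",
    "train",
    "cross_validate",
    "cross_validate_folds",
    "stratified_folds",
    "compute_metrics",
    "metrics_from_confusion",
    "binary_auc",
    "tune_knn_k",
    "compare_techniques",
    "render_confusion",
    "fuse_features",
]

CLASSIFIER_KINDS = (
    "svm-sequential", "svm-soft-margin", "decision-tree", "k-nearest-neighbors"
)


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four classifier kinds with its (toolkit-default) knobs."""

    kind: str = "svm-soft-margin"
    C: float = 1.0
    kernel: str | None = None  # default: linear for SMO-style, RBF for C-SVC
    K: int = 1
    tree_confidence: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(f"unknown classifier kind {self.kind!r}")
        if self.C <= 0:
            raise ValidationError("C must be > 0")
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if not (0 < self.tree_confidence < 1):
            raise ValidationError("tree_confidence must be in (0, 1)")

    @property
    def tag(self) -> str:
        return {"svm-sequential": "smo", "svm-soft-margin": "csvc",
                "decision-tree": "tree", "k-nearest-neighbors": "knn"}[self.kind]


@dataclass
class ConfusionMatrix:
    """Row = true class, column = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValidationError("confusion matrix must be n_classes square")
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def ccr(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else 0.0


@dataclass
class FoldMetrics:
    ccr: float
    f_measure: float
    auc: float | None
    per_class_f: dict[str, float]
    per_class_auc: dict[str, float] | None


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-fold predictions, confusion, metrics."""

    predictions: list[tuple[str, str, str, int]]  # sample_id, true, pred, fold
    scores: np.ndarray  # (n_samples, n_classes) per-class scores
    confusion: ConfusionMatrix
    fold_metrics: list[FoldMetrics]
    extractor_tag: str = ""
    classifier: ClassifierSpec | None = None
    seed: int = 0

    def metric_mean_sd(self, name: str) -> tuple[float, float]:
        vals = [getattr(f, name) for f in self.fold_metrics]
        vals = [v for v in vals if v is not None]
        if not vals:
            return float("nan"), float("nan")
        return float(np.mean(vals)), float(np.std(vals, ddof=1))

    @property
    def ccr_per_fold(self) -> list[float]:
        return [f.ccr for f in self.fold_metrics]


# ---------------------------------------------------------------------------
# Models

class TrainedModel:
    """A fitted classifier exposing predict-with-scores.

    SVM kinds standardize features internally (statistics fit on the
    training data only) and handle multiclass one-vs-one; their per-class
    scores are one-vs-one vote fractions.  Tree and KNN scores are leaf /
    neighbor class frequencies.
    """

    def __init__(self, spec: ClassifierSpec, estimator, classes: np.ndarray):
        self.spec = spec
        self.estimator = estimator
        self.classes = classes

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.estimator.predict(x)

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        """Per-class scores, rows aligned with ``self.classes``."""
        if self.spec.kind in ("svm-sequential", "svm-soft-margin"):
            votes = self._ovo_votes(x)
            n_pairs = len(self.classes) * (len(self.classes) - 1) / 2
            return votes / max(n_pairs, 1)
        return self.estimator.predict_proba(x)

    def _ovo_votes(self, x: np.ndarray) -> np.ndarray:
        df = self.estimator.decision_function(x)
        n = len(self.classes)
        if n == 2:
            df = np.asarray(df).reshape(-1)
            votes = np.zeros((len(df), 2))
            votes[:, 1] = df > 0
            votes[:, 0] = df <= 0
            return votes
        votes = np.zeros((len(x), n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                win_i = df[:, k] > 0
                votes[win_i, i] += 1
                votes[~win_i, j] += 1
                k += 1
        return votes


def _build_estimator(spec: ClassifierSpec):
    if spec.kind == "svm-sequential":
        svc = SVC(
            kernel=spec.kernel or "linear", C=spec.C,
            decision_function_shape="ovo", random_state=spec.seed,
        )
        return Pipeline([("scale", StandardScaler()), ("svm", svc)])
    if spec.kind == "svm-soft-margin":
        svc = SVC(
            kernel=spec.kernel or "rbf", C=spec.C, gamma="auto",  # gamma = 1/d
            decision_function_shape="ovo", random_state=spec.seed,
        )
        return Pipeline([("scale", StandardScaler()), ("svm", svc)])
    if spec.kind == "decision-tree":
        # ccp pruning strength grows as the confidence threshold shrinks
        return DecisionTreeClassifier(
            min_samples_leaf=2, ccp_alpha=0.0, random_state=spec.seed
        )
    return KNeighborsClassifier(n_neighbors=spec.K)


def train(spec: ClassifierSpec, table: FeatureTable) -> TrainedModel:
    """Fit one classifier on a labeled feature table."""
    classes = np.array(sorted(set(table.labels)))
    if len(classes) < 2:
        raise ValidationError("training requires at least 2 classes")
    est = _build_estimator(spec)
    est.fit(table.values, np.asarray(table.labels))
    fitted_classes = (
        est.classes_ if hasattr(est, "classes_") else est[-1].classes_
    )
    return TrainedModel(spec, est, np.asarray(fitted_classes))


# ---------------------------------------------------------------------------
# Metrics

def binary_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equivalent to the trapezoidal area under the empirical ROC; ties in the
    scores contribute 1/2.
    """
    y_true = np.asarray(y_true, dtype=bool)
    pos = scores[y_true]
    neg = scores[~y_true]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def metrics_from_confusion(conf: ConfusionMatrix) -> tuple[float, float, dict[str, float]]:
    """(CCR, support-weighted F, per-class F) from a confusion matrix.

    Per-class F is the harmonic mean of precision and recall; a class with
    zero precision+recall scores 0.
    """
    c = conf.counts.astype(float)
    support = c.sum(axis=1)
    tp = np.diag(c)
    pred_tot = c.sum(axis=0)
    per_class = {}
    for i, name in enumerate(conf.class_names):
        prec = tp[i] / pred_tot[i] if pred_tot[i] > 0 else 0.0
        rec = tp[i] / support[i] if support[i] > 0 else 0.0
        per_class[name] = (
            2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        )
    weights = support / support.sum() if support.sum() else support
    weighted_f = float(sum(w * per_class[n]
                           for w, n in zip(weights, conf.class_names)))
    return conf.ccr, weighted_f, per_class


def compute_metrics(
    y_true: list[str],
    y_pred: list[str],
    class_names: list[str],
    scores: np.ndarray | None = None,
) -> FoldMetrics:
    """CCR, weighted F and one-vs-rest weighted AUC for one prediction set.

    ``scores`` rows align with samples, columns with ``class_names``; when
    absent, AUC is reported as unavailable (None) and CCR/F are still
    computed.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    idx = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    conf = ConfusionMatrix(counts=counts, class_names=list(class_names))
    ccr, weighted_f, per_class_f = metrics_from_confusion(conf)
    per_class_auc = None
    auc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        yt = np.array([idx[t] for t in y_true])
        per_class_auc = {}
        support = counts.sum(axis=1)
        aucs, weights = [], []
        for i, name in enumerate(class_names):
            if support[i] == 0 or support[i] == len(y_true):
                continue
            a = binary_auc(yt == i, scores[:, i])
            per_class_auc[name] = a
            aucs.append(a)
            weights.append(support[i])
        if aucs:
            auc = float(np.average(aucs, weights=weights))
    return FoldMetrics(
        ccr=ccr, f_measure=weighted_f, auc=auc,
        per_class_f=per_class_f, per_class_auc=per_class_auc,
    )


# ---------------------------------------------------------------------------
# Cross-validation

def stratified_folds(
    labels: list[str], n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified partition; errors name any class smaller than n_folds."""
    labels = np.asarray(labels)
    for cls in sorted(set(labels)):
        n_cls = int((labels == cls).sum())
        if n_cls < n_folds:
            raise ValidationError(
                f"class {cls!r} has {n_cls} samples < {n_folds} folds"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def cross_validate(
    spec: ClassifierSpec,
    table: FeatureTable,
    n_folds: int = 3,
    seed: int = 0,
    extractor_tag: str = "",
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvaluationReport:
    """Seeded stratified k-fold cross-validation of one classifier.

    Every model (including the SVM standardization) is refit per training
    fold; each sample is predicted exactly once, in its test fold.  An
    explicit ``folds`` partition may be supplied to share one split across
    classifier kinds.
    """
    if folds is None:
        folds = stratified_folds(table.labels, n_folds, seed)

    def fold_features(fold_id, tr, te):
        return table.values[tr], table.values[te]

    return cross_validate_folds(
        spec, folds, table.labels, table.sample_ids, fold_features,
        extractor_tag=extractor_tag, seed=seed,
    )


def cross_validate_folds(
    spec: ClassifierSpec,
    folds: list[tuple[np.ndarray, np.ndarray]],
    labels_in: list[str],
    sample_ids: list[str],
    fold_features,
    extractor_tag: str = "",
    seed: int = 0,
) -> EvaluationReport:
    """Cross-validation engine over externally supplied per-fold features.

    ``fold_features(fold_id, train_idx, test_idx) -> (X_train, X_test)``
    lets feature extraction that must itself be fit on the training fold
    (e.g. a BOW vocabulary) participate without leaking test data — and
    lets several classifier kinds share one expensive per-fold extraction.
    """
    class_names = sorted(set(labels_in))
    labels = np.asarray(labels_in)
    n = len(labels)
    all_scores = np.full((n, len(class_names)), np.nan)
    preds: list[tuple[str, str, str, int]] = [None] * n  # type: ignore
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    fold_metrics = []
    cls_idx = {c: i for i, c in enumerate(class_names)}
    for fold_id, (tr, te) in enumerate(folds):
        x_train, x_test = fold_features(fold_id, tr, te)
        sub = FeatureTable(
            values=x_train,
            column_names=[f"f{i}" for i in range(x_train.shape[1])],
            labels=[labels_in[i] for i in tr],
            sample_ids=[sample_ids[i] for i in tr],
        )
        model = train(spec, sub)
        y_pred = model.predict(x_test)
        raw_scores = model.predict_scores(x_test)
        # align score columns with the global class ordering
        fold_scores = np.zeros((len(te), len(class_names)))
        for j, cls in enumerate(model.classes):
            fold_scores[:, cls_idx[cls]] = raw_scores[:, j]
        all_scores[te] = fold_scores
        for i, p in zip(te, y_pred):
            preds[i] = (sample_ids[i], labels[i], str(p), fold_id)
            counts[cls_idx[labels[i]], cls_idx[str(p)]] += 1
        fold_metrics.append(
            compute_metrics(
                list(labels[te]), [str(p) for p in y_pred],
                class_names, fold_scores,
            )
        )
    if any(p is None for p in preds):
        raise ValidationError("every sample must be predicted exactly once")
    return EvaluationReport(
        predictions=preds,
        scores=all_scores,
        confusion=ConfusionMatrix(counts=counts, class_names=class_names),
        fold_metrics=fold_metrics,
        extractor_tag=extractor_tag,
        classifier=spec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Tuning and comparison

def tune_knn_k(
    evaluator,
    k_range: range | list[int] = range(1, 14),
) -> tuple[int, list[tuple[int, float]]]:
    """Pick the K maximizing ``evaluator(K)`` (ties -> smallest K)."""
    k_range = list(k_range)
    if not k_range:
        raise ValidationError("k_range must be non-empty")
    trace = [(k, float(evaluator(k))) for k in k_range]
    best = min(trace, key=lambda kv: (-kv[1], kv[0]))[0]
    return best, trace


@dataclass
class TechniqueComparison:
    groups: dict[str, list[float]]
    anova_f: float
    anova_p: float
    tukey: list[tuple[str, str, float, bool]]  # pair, adjusted p, significant
    alpha: float = 0.05
    degenerate: bool = False


def compare_techniques(
    groups: dict[str, list[float]], alpha: float = 0.05
) -> TechniqueComparison:
    """One-way ANOVA across technique groups, Tukey HSD when p < alpha.

    Each group is the per-fold metric values of one (extractor, classifier)
    combination.  With no between-group variance the F statistic is 0 and
    p = 1; all-zero within-group variance with differing means is flagged
    as degenerate.
    """
    if len(groups) < 2:
        raise ValidationError("at least 2 groups required")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
    names = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    means = [a.mean() for a in arrays]
    within_var = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    between_var = float(np.var(means))
    if between_var < 1e-30:
        return TechniqueComparison(
            groups={g: list(groups[g]) for g in names},
            anova_f=0.0, anova_p=1.0, tukey=[], alpha=alpha,
        )
    if within_var < 1e-30:
        return TechniqueComparison(
            groups={g: list(groups[g]) for g in names},
            anova_f=float("inf"), anova_p=0.0, tukey=_tukey(groups, names, alpha),
            alpha=alpha, degenerate=True,
        )
    f_stat, p = stats.f_oneway(*arrays)
    tukey = _tukey(groups, names, alpha) if p < alpha else []
    return TechniqueComparison(
        groups={g: list(groups[g]) for g in names},
        anova_f=float(f_stat), anova_p=float(p), tukey=tukey, alpha=alpha,
    )


def _tukey(groups, names, alpha) -> list[tuple[str, str, float, bool]]:
    res = stats.tukey_hsd(*[np.asarray(groups[g], dtype=float) for g in names])
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            out.append((names[i], names[j], p, p < alpha))
    return out


# ---------------------------------------------------------------------------
# Feature fusion and confusion rendering

def fuse_features(cst: FeatureTable, bow: FeatureTable) -> FeatureTable:
    """Column-wise concatenation (CST block first), matched by sample_id."""
    if cst.sample_ids != bow.sample_ids:
        unmatched = sorted(
            set(cst.sample_ids).symmetric_difference(bow.sample_ids)
        )
        raise ValidationError(
            f"sample mismatch between tables: {unmatched[:10]}"
        )
    if cst.labels != bow.labels:
        raise ValidationError("labels differ between tables")
    return FeatureTable(
        values=np.hstack([cst.values, bow.values]),
        column_names=list(cst.column_names) + list(bow.column_names),
        labels=list(cst.labels),
        sample_ids=list(cst.sample_ids),
    )


def render_confusion(
    conf: ConfusionMatrix, path: str | Path, title: str = ""
) -> None:
    """Write a thermally colored (blue -> red) confusion-matrix heatmap.

    Cells are row-normalized so each row's maximum is hottest; the raw
    count matrix is also written as delimited text next to the image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    c = conf.counts.astype(float)
    row_max = c.max(axis=1, keepdims=True)
    norm = np.divide(c, row_max, out=np.zeros_like(c), where=row_max > 0)
    n = len(conf.class_names)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.45), max(3.5, n * 0.4)))
    im = ax.imshow(norm, cmap="coolwarm", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(n), conf.class_names, rotation=90, fontsize=7)
    ax.set_yticks(range(n), conf.class_names, fontsize=7)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    if title:
        ax.set_title(title)
    if n <= 30:
        for i in range(n):
            for j in range(n):
                if conf.counts[i, j]:
                    ax.text(j, i, str(conf.counts[i, j]), ha="center",
                            va="center", fontsize=6,
                            color="white" if norm[i, j] > 0.6 else "black")
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    write_confusion_csv(conf, path.with_suffix(".csv"))


def write_confusion_csv(conf: ConfusionMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred", *conf.class_names])
        for name, row in zip(conf.class_names, conf.counts):
            writer.writerow([name, *row.tolist()])


def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    class_names = rows[0][1:]
    counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]])
    return ConfusionMatrix(counts=counts, class_names=class_names)
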