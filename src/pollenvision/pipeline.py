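"""End-to-end experiment orchestration.

One call runs the full comparison protocol: extract CST features and local
descriptors once, split into seeded stratified folds once, build a BOW
vocabulary per training fold (shared by every classifier kind), then
cross-validate each extractor x classifier combination, assemble the
summary grid of CCR / F-measure / AUC (mean +/- sd per combination) and
compare combinations with ANOVA + Tukey on the per-fold CCR.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bow_features import (
    DescriptorSet,
    build_vocabulary,
    detect_describe,
    encode_bow,
)
from .classification_eval import (
    ClassifierSpec,
    EvaluationReport,
    TechniqueComparison,
    compare_techniques,
    cross_validate_folds,
    render_confusion,
    stratified_folds,
)
from .cst_features import CSTConfig, extract_cst
from .dataset_io import (
    FeatureTable,
    LabeledImageSet,
    ValidationError,
    load_dataset,
    write_feature_table,
)
from .synthetic_data import default_class_specs, generate_dataset

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "cst_feature_table", "extract_descriptors"]

logger = logging.getLogger("pollenvision")

EXTRACTORS = ("cst", "bow", "cst+bow")

DEFAULT_CLASSIFIERS = (
    ClassifierSpec(kind="svm-sequential"),
    ClassifierSpec(kind="svm-soft-margin"),
    ClassifierSpec(kind="decision-tree"),
    ClassifierSpec(kind="k-nearest-neighbors", K=1),
)


@dataclass
class ExperimentConfig:
    """Everything needed to replay one experiment."""

    dataset_dir: str | None = None
    synthetic_classes: int = 5
    n_per_class: int = 35
    canvas: int = 256
    cst: CSTConfig = field(default_factory=CSTConfig)
    vocab_size: int = 768  # the tuned dictionary size used by default
    tune_vocab: bool = False
    classifiers: tuple[ClassifierSpec, ...] = DEFAULT_CLASSIFIERS
    extractors: tuple[str, ...] = EXTRACTORS
    n_folds: int = 3
    out_dir: str | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        for e in self.extractors:
            if e not in EXTRACTORS:
                raise ValidationError(f"unknown extractor {e!r}")


@dataclass
class ExperimentResult:
    reports: dict[tuple[str, str], EvaluationReport]  # (extractor, clf tag)
    summary: list[dict]  # rows: metric, extractor, classifier, mean, sd
    comparison: TechniqueComparison | None
    config: ExperimentConfig

    def summary_cell(self, metric: str, extractor: str, clf_tag: str):
        for row in self.summary:
            if (row["metric"], row["extractor"], row["classifier"]) == (
                    metric, extractor, clf_tag):
                return row["mean"], row["sd"]
        raise KeyError((metric, extractor, clf_tag))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # sub-seeds kept below 2**31 for portability across toolkits
    return [int(s) % (2**31) for s in
            np.random.SeedSequence(seed).generate_state(n)]


def cst_feature_table(
    dataset: LabeledImageSet, config: CSTConfig | None = None
) -> FeatureTable:
    """Extract the CST block for every image of a dataset (stateless)."""
    config = config or CSTConfig()
    rows = [extract_cst(img, config).to_array() for img in dataset.images]
    return FeatureTable(
        values=np.vstack(rows),
        column_names=config.feature_names(),
        labels=dataset.labels,
        sample_ids=[img.source_id or f"sample_{i}"
                    for i, img in enumerate(dataset.images)],
    )


def extract_descriptors(dataset: LabeledImageSet) -> list[DescriptorSet]:
    return [detect_describe(img) for img in dataset.images]


def _load_or_generate(config: ExperimentConfig) -> LabeledImageSet:
    if config.dataset_dir:
        return load_dataset(config.dataset_dir)
    specs = default_class_specs(config.synthetic_classes)
    return generate_dataset(
        specs, n_per_class=config.n_per_class,
        canvas=config.canvas, seed=config.seed,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full extractor x classifier comparison protocol.

    Features and fold-wise vocabularies are computed once and shared by all
    classifier kinds; the summary grid is a pure function of the individual
    reports.  All artifacts (per-combination metrics, confusion matrices
    and heatmaps, per-fold predictions, summary and comparison tables) are
    written under ``config.out_dir`` when it is set.
    """
    seeds = _spawn_seeds(config.seed, 4 + config.n_folds)
    fold_seed, vocab_base = seeds[0], seeds[1]
    logger.info("global seed %d; fold seed %d; vocab seeds %s",
                config.seed, fold_seed,
                [(vocab_base + f) % 2**31 for f in range(config.n_folds)])

    dataset = _load_or_generate(config)
    logger.info("dataset: %d images, %d classes",
                len(dataset), len(dataset.class_names))
    labels = dataset.labels
    sample_ids = [img.source_id or f"sample_{i}"
                  for i, img in enumerate(dataset.images)]

    cst_table = None
    if any(e in config.extractors for e in ("cst", "cst+bow")):
        logger.info("extracting CST features")
        cst_table = cst_feature_table(dataset, config.cst)

    folds = stratified_folds(labels, config.n_folds, fold_seed)

    bow_fold_hists: list[np.ndarray] = []
    if any(e in config.extractors for e in ("bow", "cst+bow")):
        logger.info("detecting interest points")
        descriptor_sets = extract_descriptors(dataset)
        for fold_id, (tr, te) in enumerate(folds):
            vseed = (vocab_base + fold_id) % (2**31)
            logger.info("fold %d: building %d-word vocabulary (seed %d)",
                        fold_id, config.vocab_size, vseed)
            vocab = build_vocabulary(
                [descriptor_sets[i] for i in tr], config.vocab_size, vseed
            )
            hists = np.vstack([
                encode_bow(ds, vocab).counts for ds in descriptor_sets
            ]).astype(float)
            bow_fold_hists.append(hists)

    def make_fold_features(extractor: str):
        def fold_features(fold_id, tr, te):
            blocks_tr, blocks_te = [], []
            if extractor in ("cst", "cst+bow"):
                blocks_tr.append(cst_table.values[tr])
                blocks_te.append(cst_table.values[te])
            if extractor in ("bow", "cst+bow"):
                h = bow_fold_hists[fold_id]
                blocks_tr.append(h[tr])
                blocks_te.append(h[te])
            return np.hstack(blocks_tr), np.hstack(blocks_te)
        return fold_features

    reports: dict[tuple[str, str], EvaluationReport] = {}
    for extractor in config.extractors:
        fold_features = make_fold_features(extractor)
        for clf in config.classifiers:
            logger.info("evaluating %s x %s", extractor, clf.tag)
            try:
                reports[(extractor, clf.tag)] = cross_validate_folds(
                    clf, folds, labels, sample_ids, fold_features,
                    extractor_tag=extractor, seed=config.seed,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'cross-validate {extractor} x {clf.tag}' failed "
                    f"(config: {config})"
                ) from exc

    summary = []
    for metric in ("ccr", "f_measure", "auc"):
        for (extractor, tag), rep in reports.items():
            mean, sd = rep.metric_mean_sd(metric)
            summary.append({
                "metric": metric, "extractor": extractor, "classifier": tag,
                "mean": mean, "sd": sd,
            })

    groups = {
        f"{extractor}:{tag}": rep.ccr_per_fold
        for (extractor, tag), rep in reports.items()
    }
    comparison = compare_techniques(groups) if len(groups) >= 2 else None

    result = ExperimentResult(
        reports=reports, summary=summary, comparison=comparison, config=config
    )
    if config.out_dir:
        _write_artifacts(result, cst_table, Path(config.out_dir))
    return result


def _write_artifacts(
    result: ExperimentResult, cst_table: FeatureTable | None, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if cst_table is not None:
        write_feature_table(cst_table, out / "cst_features.csv")
    with open(out / "summary.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["metric", "extractor", "classifier", "mean", "sd"]
        )
        writer.writeheader()
        writer.writerows(result.summary)
    if result.comparison is not None:
        _write_comparison(result.comparison, out / "comparison.csv")
    for (extractor, tag), rep in result.reports.items():
        sub = out / f"{extractor.replace('+', '_')}_{tag}"
        sub.mkdir(exist_ok=True)
        render_confusion(rep.confusion, sub / "confusion.png",
                         title=f"{extractor} + {tag}")
        with open(sub / "predictions.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "true", "predicted", "fold"])
            writer.writerows(rep.predictions)
        with open(sub / "metrics.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "mean", "sd"])
            for m in ("ccr", "f_measure", "auc"):
                mean, sd = rep.metric_mean_sd(m)
                writer.writerow([m, mean, sd])


def _write_comparison(comparison: TechniqueComparison, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["anova_f", "anova_p", "alpha"])
        writer.writerow([comparison.anova_f, comparison.anova_p,
                         comparison.alpha])
        writer.writerow([])
        writer.writerow(["group_a", "group_b", "p_adj", "significant"])
        for a, b, p_adj, sig in comparison.tukey:
            writer.writerow([a, b, p_adj, sig])
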