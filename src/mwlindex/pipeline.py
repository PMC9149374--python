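"""End-to-end orchestration: recordings -> index feature tables -> experiment.

Glue between the stage modules.  ``build_feature_tables`` takes a cohort of
recordings plus ratings and produces one labeled feature table per MWL
index (one row per subject x condition, the neutral rating 5 dropped).
``synthetic_quality_by_index`` fits the per-condition copula on each table
and scores the sampled synthetic cohort; ``run_pipeline_experiment`` adds
feature selection, augmentation, and the Monte-Carlo evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import augmentation, evaluation, features, indexes, preprocessing
from .synthetic import GeneratorConfig, RatingRecord, Recording, generate_dataset

logger = logging.getLogger(__name__)


def build_feature_tables(
    recordings: list[Recording],
    ratings: list[RatingRecord],
    index_ids: tuple[str, ...] = indexes.INDEX_IDS,
    window_s: float = 1.0,
    denoise: bool = True,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """One labeled 210-feature table per MWL index.

    Each recording is average-referenced, 1 Hz high-passed and (optionally)
    ICA-denoised, its index series computed per 1-s window, and the feature
    catalog extracted.  Rows whose rating is the neutral 5 are dropped.
    """
    label_by_key = {
        (r.subject_id, r.condition): evaluation.binarize_rating(r.rating)
        for r in ratings
    }
    rows_by_index: dict[str, list[dict]] = {iid: [] for iid in index_ids}
    for rec in recordings:
        label = label_by_key.get((rec.subject_id, rec.condition))
        if label is None:
            continue  # missing rating or neutral 5
        clean, _ = preprocessing.preprocess(rec, seed=seed, run_ica=denoise)
        series_map = indexes.compute_all_indexes(clean, window_s=window_s)
        for iid in index_ids:
            vec = features.extract_features(series_map[iid])
            row = {"subject_id": rec.subject_id, "condition": rec.condition,
                   "label": label, **vec.to_dict()}
            rows_by_index[iid].append(row)
    return {iid: pd.DataFrame(rows) for iid, rows in rows_by_index.items()}


def synthetic_quality_by_index(
    tables: dict[str, pd.DataFrame],
    n_synthetic_subjects: int = 180,
    seed: int = 0,
) -> dict[str, augmentation.SyntheticQualityReport]:
    """Fit the per-condition copula on each index table, sample the synthetic
    cohort, and score it against the original (conditions pooled)."""
    reports: dict[str, augmentation.SyntheticQualityReport] = {}
    for iid, table in tables.items():
        combined, _ = augmentation.augment_feature_table(
            table, n_synthetic_subjects, seed=seed,
            feature_cols=list(features.FEATURE_NAMES),
        )
        synth = combined[combined["subject_id"] < 0]
        reports[iid] = augmentation.quality_report(
            table, synth, feature_cols=list(features.FEATURE_NAMES)
        )
    return reports


def default_cohort_quality(
    seed: int,
    n_subjects: int = 48,
    n_synthetic_subjects: int = 180,
    denoise: bool = True,
) -> dict[str, augmentation.SyntheticQualityReport]:
    """Synthetic-data quality for the default study conditions.

    Generates the default cohort, runs the denoising pipeline, builds all
    ten index feature tables, fits the per-condition copula on each, samples
    the synthetic cohort, and returns the quality report per index.
    """
    cfg = GeneratorConfig(n_subjects=n_subjects, seed=seed)
    recordings, ratings = generate_dataset(cfg)
    tables = build_feature_tables(recordings, ratings, denoise=denoise, seed=seed)
    return synthetic_quality_by_index(
        tables, n_synthetic_subjects=n_synthetic_subjects, seed=seed
    )


@dataclass(frozen=True)
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    selections: dict[str, features.SelectionResult]
    quality: dict[str, augmentation.SyntheticQualityReport]
    report: evaluation.EvaluationReport


def run_pipeline_experiment(
    cfg: GeneratorConfig,
    index_ids: tuple[str, ...] = indexes.INDEX_IDS,
    n_synthetic_subjects: int = 180,
    iterations: int = evaluation.ITERATIONS_DEFAULT,
    learners: tuple[str, ...] = evaluation.LEARNERS,
    denoise: bool = True,
    select: bool = True,
    augment: bool = True,
    seed: int | None = None,
) -> PipelineResult:
    """Full study pipeline on a synthetic cohort.

    Generates the cohort from ``cfg``, preprocesses, computes index feature
    tables, selects features on the original data (ANOVA-F ranking, halving,
    multicollinearity pruning, scored with logistic regression), augments
    with the per-condition copula, and runs the Monte-Carlo evaluation of
    all learners with the pairwise index contrasts.
    """
    seed = cfg.seed if seed is None else seed
    recordings, ratings = generate_dataset(cfg)
    tables = build_feature_tables(
        recordings, ratings, index_ids=index_ids, denoise=denoise, seed=seed
    )

    selections: dict[str, features.SelectionResult] = {}
    selected_cols: dict[str, list[str]] = {}
    for iid, table in tables.items():
        if select:
            plan = evaluation.make_splits(table, iterations=iterations, seed=seed)
            sel = features.iterative_halving(table, learner_id="L-R", split_plan=plan)
            selections[iid] = sel
            selected_cols[iid] = list(sel.pruned)
        else:
            selected_cols[iid] = list(features.FEATURE_NAMES)

    quality: dict[str, augmentation.SyntheticQualityReport] = {}
    eval_tables: dict[str, pd.DataFrame] = {}
    if augment:
        quality = synthetic_quality_by_index(
            tables, n_synthetic_subjects=n_synthetic_subjects, seed=seed
        )
        for iid, table in tables.items():
            slim = table[["subject_id", "condition", "label"] + selected_cols[iid]]
            combined, _ = augmentation.augment_feature_table(
                slim, n_synthetic_subjects, seed=seed,
                feature_cols=selected_cols[iid],
            )
            eval_tables[iid] = combined
    else:
        eval_tables = tables

    report = evaluation.run_experiment(
        eval_tables,
        learners=learners,
        iterations=iterations,
        seed=seed,
        feature_cols_by_index=selected_cols,
    )
    return PipelineResult(tables, selections, quality, report)
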