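"""Binary workload classification under Monte-Carlo cross-validation.

Ratings 1-4 map to "suboptimal" mental workload, 6-9 to "superoptimal",
and the neutral 5 is discarded.  Models are evaluated under repeated
random subject-grouped 70/30 train/test splits (100 iterations by
default): a subject's rows always travel together, split membership is
stratified on the subject's label profile, features are z-scored with
training-set statistics only, and three learners are compared — logistic
regression (L-R), a linear-kernel SVM, and a Gini decision tree (DTR).

Metrics use "superoptimal" as the positive class:
accuracy = (tp + tn) / total, precision = tp / (tp + fp),
recall = tp / (tp + fn), f1 = harmonic mean of precision and recall,
with zero-denominator cases mapped to 0.  Pairwise comparisons use the
two-tailed pooled-variance t-test with Bonferroni multiplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

SUBOPTIMAL = "suboptimal"
SUPEROPTIMAL = "superoptimal"
POSITIVE_LABEL = SUPEROPTIMAL
LEARNERS = ("L-R", "SVM", "DTR")
METRICS = ("accuracy", "precision", "recall", "f1")

TRAIN_FRACTION_DEFAULT = 0.7
ITERATIONS_DEFAULT = 100
ALPHA_RAW = 0.05
ALPHA_BONFERRONI = 0.005


def binarize_rating(rating: int) -> str | None:
    """Map a 1-9 rating to a binary label; the neutral 5 returns None."""
    if not 1 <= rating <= 9:
        raise ValueError(f"rating out of range 1..9: {rating}")
    if rating == 5:
        return None
    return SUBOPTIMAL if rating <= 4 else SUPEROPTIMAL


@dataclass(frozen=True)
class SplitPlan:
    """Per-iteration subject-id train/test partitions."""

    iterations: int
    train_fraction: float
    splits: tuple[tuple[frozenset, frozenset], ...]
    seed: int


def make_splits(
    instances: pd.DataFrame,
    train_fraction: float = TRAIN_FRACTION_DEFAULT,
    iterations: int = ITERATIONS_DEFAULT,
    seed: int = 0,
    subject_col: str = "subject_id",
    label_col: str = "label",
) -> SplitPlan:
    """Subject-grouped, label-profile-stratified random splits.

    Subjects are stratified by the multiset of labels they contribute, so
    per-iteration train class proportions track the global ones while a
    subject's rows never straddle the train/test boundary.
    """
    profiles: dict[tuple, list] = {}
    for sid, grp in instances.groupby(subject_col):
        profile = tuple(sorted(grp[label_col]))
        profiles.setdefault(profile, []).append(sid)
    for label in (SUBOPTIMAL, SUPEROPTIMAL):
        subjects_with = {
            sid
            for sid, grp in instances.groupby(subject_col)
            if label in set(grp[label_col])
        }
        if len(subjects_with) == 1:
            raise ValueError(
                f"class {label!r} is carried by a single subject; cannot split"
            )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    splits = []
    for _ in range(iterations):
        train: list = []
        test: list = []
        for profile in sorted(profiles):
            sids = list(profiles[profile])
            rng.shuffle(sids)
            n_train = int(round(train_fraction * len(sids)))
            n_train = min(max(n_train, 1 if len(sids) > 1 else 0), len(sids) - 1) \
                if len(sids) > 1 else len(sids)
            train.extend(sids[:n_train])
            test.extend(sids[n_train:])
        splits.append((frozenset(train), frozenset(test)))
    return SplitPlan(iterations, train_fraction, tuple(splits), seed)


@dataclass(frozen=True)
class Normalizer:
    """Per-feature z-score parameters estimated on training rows."""

    mu: np.ndarray
    sigma: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        sigma_safe = np.where(self.sigma > 0, self.sigma, 1.0)
        z = (x - self.mu) / sigma_safe
        z[:, self.sigma == 0] = 0.0
        return z


def normalize(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, Normalizer]:
    """z-score with training mean and population SD; sigma=0 features map to 0."""
    train = np.asarray(train, dtype=float)
    if train.shape[0] == 0:
        raise ValueError("empty training set")
    norm = Normalizer(train.mean(axis=0), train.std(axis=0, ddof=0))
    train_z = norm.transform(train)
    test_z = norm.transform(np.asarray(test, dtype=float)) if test is not None else None
    return train_z, test_z, norm


def train_classifier(x: np.ndarray, y: np.ndarray, learner: str, seed: int = 0):
    """Fit one of the three learners on a normalized training set."""
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if learner == "L-R":
        model = LogisticRegression(C=1.0, solver="liblinear", random_state=seed)
    elif learner == "SVM":
        model = SVC(C=1.0, kernel="linear", random_state=seed)
    elif learner == "DTR":
        model = DecisionTreeClassifier(criterion="gini", random_state=seed)
    else:
        raise ValueError(f"unknown learner {learner!r}; choose from {LEARNERS}")
    model.fit(x, y)
    return model


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str = POSITIVE_LABEL
) -> ConfusionMatrix:
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.debug("metric %s undefined (zero denominator); using 0", name)
            return 0.0
        return num / den

    accuracy = ratio(cm.tp + cm.tn, cm.total, "accuracy")
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def evaluate(model, x_test: np.ndarray, y_test: np.ndarray) -> tuple[ConfusionMatrix, dict]:
    if len(y_test) == 0:
        raise ValueError("empty test set")
    cm = confusion_from_predictions(y_test, model.predict(x_test))
    return cm, metrics_from_confusion(cm)


def monte_carlo_evaluate(
    table: pd.DataFrame,
    feature_cols: list[str],
    learners: tuple[str, ...] = LEARNERS,
    split_plan: SplitPlan | None = None,
    subject_col: str = "subject_id",
    label_col: str = "label",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(learner, iteration) metrics over the Monte-Carlo split plan."""
    if split_plan is None:
        split_plan = make_splits(table, seed=seed)
    x_all = table[feature_cols].to_numpy(dtype=float)
    y_all = table[label_col].to_numpy()
    subjects = table[subject_col].to_numpy()
    rows = []
    for it, (train_ids, test_ids) in enumerate(split_plan.splits):
        train_mask = np.isin(subjects, list(train_ids))
        test_mask = np.isin(subjects, list(test_ids))
        x_tr, x_te, _ = normalize(x_all[train_mask], x_all[test_mask])
        y_tr, y_te = y_all[train_mask], y_all[test_mask]
        for learner in learners:
            model = train_classifier(x_tr, y_tr, learner, seed=split_plan.seed)
            _, m = evaluate(model, x_te, y_te)
            rows.append({"learner": learner, "iteration": it, **m})
    return pd.DataFrame(rows)


def compare_ttest(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_comparisons: int = 1,
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test (pooled variance by default) with
    Bonferroni-multiplied p-value, clipped at 1."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0, 0.0
    t, p = sp_stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), float(min(1.0, p * n_comparisons))


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

# ratio index -> its constituent single-band indexes
RATIO_COMPONENTS: dict[str, tuple[str, str]] = {
    "at-1": ("c1-theta", "c-alpha"),
    "at-2": ("c2-theta", "c-alpha"),
    "at-3": ("c3-theta", "c-alpha"),
    "ta-1": ("c1-theta", "c-alpha"),
    "ta-2": ("c2-theta", "c-alpha"),
    "ta-3": ("c3-theta", "c-alpha"),
}
# ratio-vs-ratio contrasts (electrode-count hypothesis)
RATIO_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("at-1", "at-2"),
    ("at-3", "at-2"),
    ("ta-1", "ta-2"),
    ("ta-3", "ta-2"),
)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-iteration metrics, their summary, and pairwise t-tests."""

    metrics: pd.DataFrame  # index_id, learner, iteration, 4 metrics
    summary: pd.DataFrame  # index_id, learner, metric means/sds
    ttests: pd.DataFrame  # family, learner, index_a, index_b, t, p, p_bonferroni

    def mean_metric(self, index_id: str, learner: str, metric: str = "accuracy") -> float:
        sel = (self.metrics["index_id"] == index_id) & (
            self.metrics["learner"] == learner
        )
        return float(self.metrics.loc[sel, metric].mean())


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    return (
        metrics.groupby(["index_id", "learner"])[list(METRICS)]
        .agg(["mean", "std"])
        .reset_index()
    )


def pairwise_ttests(
    metrics: pd.DataFrame,
    learners: tuple[str, ...] = LEARNERS,
    metric: str = "accuracy",
) -> pd.DataFrame:
    """Ratio-vs-component and ratio-vs-ratio contrasts, Bonferroni-corrected
    within each family."""
    available = set(metrics["index_id"].unique())

    def sample(index_id: str, learner: str) -> np.ndarray:
        sel = (metrics["index_id"] == index_id) & (metrics["learner"] == learner)
        return metrics.loc[sel, metric].to_numpy()

    component_pairs = [
        (ratio, comp)
        for ratio, comps in RATIO_COMPONENTS.items()
        for comp in comps
        if ratio in available and comp in available
    ]
    contrast_pairs = [
        (a, b) for a, b in RATIO_CONTRASTS if a in available and b in available
    ]
    rows = []
    for family, pairs in (
        ("ratio_vs_component", component_pairs),
        ("ratio_vs_ratio", contrast_pairs),
    ):
        n_comp = len(pairs) * len(learners)
        if n_comp == 0:
            continue
        for learner in learners:
            for a, b in pairs:
                t, p, p_bonf = compare_ttest(
                    sample(a, learner), sample(b, learner), n_comparisons=n_comp
                )
                rows.append(
                    {
                        "family": family,
                        "learner": learner,
                        "index_a": a,
                        "index_b": b,
                        "metric": metric,
                        "t": t,
                        "p": p,
                        "p_bonferroni": p_bonf,
                        "significant_raw": p < ALPHA_RAW,
                        "significant_bonferroni": p_bonf < ALPHA_BONFERRONI,
                    }
                )
    return pd.DataFrame(rows)


def run_experiment(
    tables: dict[str, pd.DataFrame],
    learners: tuple[str, ...] = LEARNERS,
    iterations: int = ITERATIONS_DEFAULT,
    train_fraction: float = TRAIN_FRACTION_DEFAULT,
    seed: int = 0,
    feature_cols_by_index: dict[str, list[str]] | None = None,
) -> EvaluationReport:
    """Monte-Carlo evaluation across MWL-index feature tables plus the
    pairwise index contrasts.

    ``tables`` maps index id to a labeled feature table (columns:
    subject_id, condition, label, features).  ``feature_cols_by_index``
    optionally restricts each table to a selected feature set.
    """
    from .features import FEATURE_NAMES

    frames = []
    for index_id, table in tables.items():
        if feature_cols_by_index and index_id in feature_cols_by_index:
            cols = list(feature_cols_by_index[index_id])
        else:
            cols = [c for c in table.columns if c in set(FEATURE_NAMES)]
        if not cols:
            raise ValueError(f"no feature columns found for index {index_id!r}")
        plan = make_splits(
            table, train_fraction=train_fraction, iterations=iterations, seed=seed
        )
        m = monte_carlo_evaluate(table, cols, learners=learners, split_plan=plan)
        m.insert(0, "index_id", index_id)
        frames.append(m)
    metrics = pd.concat(frames, ignore_index=True)
    return EvaluationReport(
        metrics=metrics,
        summary=summarize_metrics(metrics),
        ttests=pairwise_ttests(metrics, learners=learners),
    )
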