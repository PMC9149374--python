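"""Gaussian-copula tabular augmentation and synthetic-data quality scores.

Feature tables of EEG workload cohorts are small (one row per subject and
condition), so classifier training is augmented with synthetic rows drawn
from a Gaussian copula fitted per task-load condition: each feature keeps
its empirical marginal (inverse-ECDF sampling, so synthetic values stay
inside the observed range) while the dependence structure is the
correlation matrix of the features' normal scores.

Quality of a synthetic table against the original is summarized by three
percentage scores and their arithmetic mean:

* **field correlation stability** — 100 * (1 - mean |r_orig - r_synth| / 2)
  over all feature pairs (the division by 2 maps the largest possible
  correlation difference to 0%);
* **deep structure stability** — PCA is fitted on the standardized
  original table (components covering >= 95% variance, capped at 5), both
  tables are projected, and per-component base-2 Jensen-Shannon divergence
  between 20-bin histograms is averaged: 100 * (1 - mean JSD);
* **field distribution stability** — per-column base-2 JSD between 20-bin
  histograms on shared equal-width bins: 100 * (1 - mean JSD).

The overall score is graded Very Poor / Poor / Moderate / Good / Excellent
on 20-point bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.decomposition import PCA

N_BINS = 20
_SMOOTH = 1e-12
MIN_FIT_ROWS = 10

GRADE_BINS = (
    (20.0, "Very Poor"),
    (40.0, "Poor"),
    (60.0, "Moderate"),
    (80.0, "Good"),
    (100.0, "Excellent"),
)


@dataclass(frozen=True)
class SynthModel:
    """Fitted Gaussian copula: empirical marginals + normal-score correlation."""

    feature_names: tuple[str, ...]
    marginals: tuple[np.ndarray, ...]  # sorted observed values per feature
    correlation: np.ndarray
    condition: str | None = None


@dataclass(frozen=True)
class SyntheticQualityReport:
    field_correlation_stability: float
    deep_structure_stability: float
    field_distribution_stability: float
    overall: float
    grade: str

    def to_dict(self) -> dict:
        return {
            "field_correlation_stability": self.field_correlation_stability,
            "deep_structure_stability": self.deep_structure_stability,
            "field_distribution_stability": self.field_distribution_stability,
            "overall": self.overall,
            "grade": self.grade,
        }


def _nearest_psd_correlation(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    corr = (corr + corr.T) / 2
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
    return corr


def fit_synthesizer(
    table: pd.DataFrame,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    condition: str | None = None,
) -> SynthModel:
    """Fit the Gaussian copula to a feature table (>= 10 rows).

    Fitting is deterministic; ``seed`` is accepted for interface symmetry
    with sampling.  Constant columns get zero dependence by convention.
    """
    if feature_cols is None:
        feature_cols = [
            c
            for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c])
            and c not in ("subject_id", "rating")
        ]
    n = len(table)
    if n < MIN_FIT_ROWS:
        raise ValueError(f"need at least {MIN_FIT_ROWS} rows to fit, got {n}")
    x = table[feature_cols].to_numpy(dtype=float)
    d = x.shape[1]
    # normal scores via mid-ranks
    z = np.empty_like(x)
    for j in range(d):
        ranks = sp_stats.rankdata(x[:, j], method="average")
        z[:, j] = sp_stats.norm.ppf((ranks - 0.5) / n)
    sd = z.std(axis=0)
    nondeg = sd > 0
    corr = np.eye(d)
    if nondeg.sum() >= 2:
        sub = np.corrcoef(z[:, nondeg], rowvar=False)
        corr[np.ix_(nondeg, nondeg)] = sub
    corr = _nearest_psd_correlation(np.nan_to_num(corr, nan=0.0))
    np.fill_diagonal(corr, 1.0)
    marginals = tuple(np.sort(x[:, j]) for j in range(d))
    return SynthModel(tuple(feature_cols), marginals, corr, condition)


def sample_synthetic(model: SynthModel, n_rows: int, seed: int = 0) -> pd.DataFrame:
    """Draw synthetic rows: correlated normals -> uniforms -> inverse ECDF."""
    rng = np.random.default_rng(seed)
    d = len(model.feature_names)
    chol = np.linalg.cholesky(model.correlation + 1e-10 * np.eye(d))
    z = rng.standard_normal((n_rows, d)) @ chol.T
    u = sp_stats.norm.cdf(z)
    out = np.empty((n_rows, d))
    for j in range(d):
        out[:, j] = np.quantile(model.marginals[j], u[:, j], method="linear")
    return pd.DataFrame(out, columns=list(model.feature_names))


# ---------------------------------------------------------------------------
# quality scores
# ---------------------------------------------------------------------------

def _shared_feature_matrix(
    orig: pd.DataFrame, synth: pd.DataFrame, feature_cols: list[str] | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if feature_cols is None:
        feature_cols = [
            c
            for c in orig.columns
            if c in synth.columns and pd.api.types.is_numeric_dtype(orig[c])
            and c not in ("subject_id", "rating")
        ]
    if not feature_cols:
        raise ValueError("no shared numeric feature columns")
    return (
        orig[feature_cols].to_numpy(dtype=float),
        synth[feature_cols].to_numpy(dtype=float),
        feature_cols,
    )


def _corr_with_nan_for_constant(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[~np.isfinite(corr)] = np.nan
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return corr


def field_correlation_stability(
    orig: pd.DataFrame, synth: pd.DataFrame, feature_cols: list[str] | None = None
) -> float:
    """100 * (1 - mean |pairwise r difference| / 2) over feature pairs.

    Pairs involving a constant column contribute difference 0.
    """
    xo, xs, cols = _shared_feature_matrix(orig, synth, feature_cols)
    d = len(cols)
    if d < 2:
        return 100.0
    ro = _corr_with_nan_for_constant(xo)
    rs = _corr_with_nan_for_constant(xs)
    iu = np.triu_indices(d, k=1)
    diff = np.abs(ro[iu] - rs[iu])
    diff = np.nan_to_num(diff, nan=0.0)
    return float(np.clip(100.0 * (1.0 - diff.mean() / 2.0), 0.0, 100.0))


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 JSD between two probability vectors (equal mixture weights)."""
    p = np.asarray(p, dtype=float) + _SMOOTH
    q = np.asarray(q, dtype=float) + _SMOOTH
    p /= p.sum()
    q /= q.sum()
    m = 0.5 * (p + q)
    h = lambda v: float(-(v * np.log2(v)).sum())
    return max(h(m) - 0.5 * h(p) - 0.5 * h(q), 0.0)


def histogram_jsd(a: np.ndarray, b: np.ndarray, bins: int = N_BINS) -> float:
    """Base-2 JSD between histograms of two samples on shared equal-width bins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return jensen_shannon_divergence(pa / a.size, pb / b.size)


def field_distribution_stability(
    orig: pd.DataFrame, synth: pd.DataFrame, feature_cols: list[str] | None = None
) -> float:
    """100 * (1 - mean per-column base-2 JSD on 20 shared bins)."""
    xo, xs, cols = _shared_feature_matrix(orig, synth, feature_cols)
    jsds = [histogram_jsd(xo[:, j], xs[:, j]) for j in range(len(cols))]
    return float(np.clip(100.0 * (1.0 - float(np.mean(jsds))), 0.0, 100.0))


def deep_structure_stability(
    orig: pd.DataFrame,
    synth: pd.DataFrame,
    feature_cols: list[str] | None = None,
    max_components: int = 5,
    explained_variance: float = 0.95,
) -> float:
    """PCA on the standardized original, both tables projected, per-component
    distributional (base-2 JSD) comparison: 100 * (1 - mean JSD)."""
    xo, xs, cols = _shared_feature_matrix(orig, synth, feature_cols)
    if xo.shape[0] < 2 or xs.shape[0] < 2:
        raise ValueError("need at least 2 rows in each table")
    mu = xo.mean(axis=0)
    sd = xo.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    zo = (xo - mu) / sd_safe
    zs = (xs - mu) / sd_safe
    n_max = min(max_components, zo.shape[0] - 1, zo.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full")
    proj_o = pca.fit_transform(zo)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, explained_variance) + 1)
    n_keep = min(max(n_keep, 1), n_max)
    proj_s = pca.transform(zs)
    jsds = [
        histogram_jsd(proj_o[:, k], proj_s[:, k]) for k in range(n_keep)
    ]
    return float(np.clip(100.0 * (1.0 - float(np.mean(jsds))), 0.0, 100.0))


def grade_for(score: float) -> str:
    for upper, grade in GRADE_BINS:
        if score < upper:
            return grade
    return GRADE_BINS[-1][1]


def overall_quality(fcs: float, dss: float, fds: float) -> SyntheticQualityReport:
    """Arithmetic mean of the three stability scores, with its quality grade."""
    for name, v in (
        ("field_correlation_stability", fcs),
        ("deep_structure_stability", dss),
        ("field_distribution_stability", fds),
    ):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} out of [0, 100]: {v}")
    overall = (fcs + dss + fds) / 3.0
    return SyntheticQualityReport(fcs, dss, fds, overall, grade_for(overall))


def quality_report(
    orig: pd.DataFrame, synth: pd.DataFrame, feature_cols: list[str] | None = None
) -> SyntheticQualityReport:
    """All three stability scores plus the overall grade for one table pair."""
    return overall_quality(
        field_correlation_stability(orig, synth, feature_cols),
        deep_structure_stability(orig, synth, feature_cols),
        field_distribution_stability(orig, synth, feature_cols),
    )


def augment_feature_table(
    table: pd.DataFrame,
    n_synthetic_subjects: int,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    condition_col: str = "condition",
    label_col: str = "label",
) -> tuple[pd.DataFrame, dict[str, SynthModel]]:
    """Fit one copula per condition and append synthetic subjects.

    Synthetic subjects are split evenly across conditions, receive fresh
    negative subject ids (no collision with originals in subject-grouped
    splits) and a label drawn from that condition's empirical label
    distribution.  Returns (combined table, per-condition models).
    """
    conditions = sorted(table[condition_col].unique())
    per_cond = n_synthetic_subjects // len(conditions)
    remainder = n_synthetic_subjects - per_cond * len(conditions)
    models: dict[str, SynthModel] = {}
    synth_frames = [table.copy()]
    next_id = -1
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    for i, cond in enumerate(conditions):
        rows = table[table[condition_col] == cond]
        model = fit_synthesizer(rows, seed=seed, feature_cols=feature_cols,
                                condition=cond)
        models[cond] = model
        n_rows = per_cond + (1 if i < remainder else 0)
        sampled = sample_synthetic(
            model, n_rows, seed=int(rng.integers(2**31))
        )
        sampled.insert(0, "subject_id", np.arange(next_id, next_id - n_rows, -1))
        sampled.insert(1, condition_col, cond)
        if label_col in rows.columns:
            labels = rows[label_col].to_numpy()
            sampled[label_col] = rng.choice(labels, size=n_rows, replace=True)
        next_id -= n_rows
        synth_frames.append(sampled)
    combined = pd.concat(synth_frames, ignore_index=True)
    return combined, models
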