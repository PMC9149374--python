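"""High-level feature catalog for MWL index series, and three-stage selection.

The catalog extracts exactly 210 features from a per-window index time
series, 70 per domain:

* **statistical** — moments, robust location/scale, quantiles, ECDF values
  at 10 evenly spaced points, 10-bin histogram frequencies;
* **temporal** — differences, trend, Hjorth parameters, run lengths, peak
  structure, entropy measures, autocorrelation at lags 1-30;
* **spectral** — centroid/spread/shape of the power spectrum, roll-off and
  cumulative-energy frequencies, relative band energies, low-order FFT
  magnitudes, multiscale (Haar moving-average) detail energies, and the
  human-range energy ratio (0.6-2.5 Hz band over total).

Degenerate inputs never produce NaN: a constant series has variance,
peak-to-peak and entropies of 0, autocorrelation 1 at every lag, and all
spectral-distribution features 0.

Selection follows three stages: one-way ANOVA F ranking of each feature
against the binary workload label; iterative halving of the feature count
(210 -> 105 -> 52 -> 26 -> 13 -> 7), scored by Monte-Carlo accuracy of a
fixed learner and stopped at the first drop; and a greedy Pearson
multicollinearity prune at |r| > 0.5 in descending-F order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .indexes import IndexSeries

N_FEATURES = 210
N_PER_DOMAIN = 70
_EPS = 1e-12

ACF_MAX_LAG = 30
HUMAN_RANGE_BAND = (0.6, 2.5)
R_THRESHOLD_DEFAULT = 0.5
HALVING_MIN_FEATURES = 7


# ---------------------------------------------------------------------------
# per-series context: shared intermediates computed once
# ---------------------------------------------------------------------------

class _Context:
    def __init__(self, x: np.ndarray, fs: float):
        self.x = x = np.asarray(x, dtype=float)
        self.fs = fs
        self.n = n = x.size
        self.mean = x.mean()
        self.std = x.std()
        self.constant = np.ptp(x) == 0
        self.sorted = np.sort(x)
        self.diffs = np.diff(x)
        self.diffs2 = np.diff(x, n=2)
        self.centered = x - self.mean
        # autocorrelation, lags 0..ACF_MAX_LAG; constant series -> 1 everywhere
        if self.constant:
            self.acf = np.ones(ACF_MAX_LAG + 1)
        else:
            c = np.correlate(self.centered, self.centered, mode="full")[n - 1 :]
            self.acf = c[: ACF_MAX_LAG + 1] / c[0]
            if self.acf.size < ACF_MAX_LAG + 1:
                self.acf = np.pad(self.acf, (0, ACF_MAX_LAG + 1 - self.acf.size))
        # 10-bin histogram probabilities
        counts, edges = np.histogram(x, bins=10)
        self.hist_probs = counts / n
        self.hist_centers = 0.5 * (edges[:-1] + edges[1:])
        # Hann-tapered periodogram of the whole series, DC excluded
        freqs, psd = sp_signal.periodogram(x, fs=fs, window="hann")
        self.freqs = freqs[1:]
        self.psd = psd[1:]
        self.total_power = float(self.psd.sum())
        # FFT magnitudes (DC excluded)
        self.fft_mag = np.abs(np.fft.rfft(x))[1:]


# ---------------------------------------------------------------------------
# statistical domain (70)
# ---------------------------------------------------------------------------

def _std_moment(x: np.ndarray, k: int) -> float:
    """Biased standardized k-th central moment; 0 for a constant series."""
    m = x.mean()
    s = x.std()
    if s == 0:
        return 0.0
    return float(np.mean(((x - m) / s) ** k))


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log2(p)).sum())


def _statistical(c: _Context) -> dict[str, float]:
    x, n = c.x, c.n
    q = lambda p: float(np.quantile(c.sorted, p))
    out: dict[str, float] = {
        "mean": c.mean,
        "median": float(np.median(x)),
        "std": c.std,
        "var": c.std**2,
        "skewness": _std_moment(x, 3),
        "kurtosis": _std_moment(x, 4) - 3.0 if not c.constant else 0.0,
        "min": float(x.min()),
        "max": float(x.max()),
        "peak_to_peak": float(np.ptp(x)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "iqr": q(0.75) - q(0.25),
        "mad_median": float(np.median(np.abs(x - np.median(x)))),
        "mad_mean": float(np.mean(np.abs(c.centered))),
        "coeff_variation": 0.0 if c.mean == 0 else c.std / abs(c.mean),
        "sem": c.std / math.sqrt(n),
        "trimmed_mean_10": float(sp_stats.trim_mean(x, 0.1)),
        "mean_abs": float(np.mean(np.abs(x))),
        "median_abs": float(np.median(np.abs(x))),
        "max_abs": float(np.max(np.abs(x))),
        "min_abs": float(np.min(np.abs(x))),
        "energy": float(np.sum(x**2)),
        "std_moment_5": 0.0 if c.std == 0 else float(np.mean((c.centered / c.std) ** 5)),
        "std_moment_6": 0.0 if c.std == 0 else float(np.mean((c.centered / c.std) ** 6)),
        "hist_mode": float(c.hist_centers[np.argmax(c.hist_probs)]),
        "range_q95_q05": q(0.95) - q(0.05),
        "range_q90_q10": q(0.90) - q(0.10),
        "robust_cv": 0.0
        if np.median(x) == 0
        else (q(0.75) - q(0.25)) / abs(float(np.median(x))),
        "log_geo_mean_abs": float(np.mean(np.log(np.abs(x) + _EPS))),
        "hist_entropy": _entropy_bits(c.hist_probs),
    }
    for p in [0.01] + [round(0.05 * k, 2) for k in range(1, 20)] + [0.99]:
        out[f"quantile_{int(p * 100):02d}"] = q(p)
    # ECDF at 10 evenly spaced points of the value range
    lo, hi = x.min(), x.max()
    points = np.linspace(lo, hi, 10)
    for i, pt in enumerate(points):
        out[f"ecdf_{i}"] = float(np.searchsorted(c.sorted, pt, side="right") / n)
    for i, p_i in enumerate(c.hist_probs):
        out[f"hist_bin_{i}"] = float(p_i)
    return out


# ---------------------------------------------------------------------------
# temporal domain (70)
# ---------------------------------------------------------------------------

def _sign_changes(v: np.ndarray) -> int:
    s = np.sign(v)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def _permutation_entropy(x: np.ndarray, order: int = 3) -> float:
    n = x.size
    if n < order + 1 or np.ptp(x) == 0:
        return 0.0
    patterns = {p: 0 for p in permutations(range(order))}
    windows = np.lib.stride_tricks.sliding_window_view(x, order)
    ranks = np.argsort(np.argsort(windows, axis=1), axis=1)
    for r in ranks:
        patterns[tuple(r)] += 1
    probs = np.array([v for v in patterns.values() if v > 0], dtype=float)
    probs /= probs.sum()
    return _entropy_bits(probs) / math.log2(math.factorial(order))


def _temporal(c: _Context) -> dict[str, float]:
    x, n, d = c.x, c.n, c.diffs
    t = np.arange(n)
    if c.constant:
        slope, intercept = 0.0, c.mean
    else:
        slope, intercept = np.polyfit(t, x, 1)
    std_d = d.std() if d.size else 0.0
    mobility = 0.0 if c.std == 0 else std_d / c.std
    std_d2 = c.diffs2.std() if c.diffs2.size else 0.0
    mobility_d = 0.0 if std_d == 0 else std_d2 / std_d
    complexity = 0.0 if mobility == 0 else mobility_d / mobility
    above = x > c.mean
    below = x < c.mean
    peaks, _ = sp_signal.find_peaks(x)
    troughs, _ = sp_signal.find_peaks(-x)
    abs_sum = np.sum(np.abs(x))
    first_zero = next(
        (lag for lag in range(1, ACF_MAX_LAG + 1) if c.acf[lag] < 0), ACF_MAX_LAG + 1
    )
    diff_counts, _ = np.histogram(d, bins=10) if d.size else (np.array([]), None)
    out: dict[str, float] = {
        "mean_crossing_rate": _sign_changes(c.centered) / max(n - 1, 1),
        "zero_crossing_count": float(_sign_changes(x)),
        "trend_slope": float(slope),
        "trend_intercept": float(intercept),
        "mean_abs_diff": float(np.mean(np.abs(d))) if d.size else 0.0,
        "median_abs_diff": float(np.median(np.abs(d))) if d.size else 0.0,
        "max_abs_diff": float(np.max(np.abs(d))) if d.size else 0.0,
        "min_abs_diff": float(np.min(np.abs(d))) if d.size else 0.0,
        "mean_diff": float(np.mean(d)) if d.size else 0.0,
        "median_diff": float(np.median(d)) if d.size else 0.0,
        "sum_abs_diff": float(np.sum(np.abs(d))) if d.size else 0.0,
        "std_diff": float(std_d),
        "mean_abs_second_diff": float(np.mean(np.abs(c.diffs2)))
        if c.diffs2.size
        else 0.0,
        "std_second_diff": float(std_d2),
        "hjorth_mobility": float(mobility),
        "hjorth_complexity": float(complexity),
        "auc": float(np.trapezoid(x, dx=1.0 / c.fs)),
        "time_centroid": 0.0 if abs_sum == 0 else float(np.sum(t * np.abs(x)) / abs_sum),
        "count_above_mean": float(above.sum()),
        "count_below_mean": float(below.sum()),
        "longest_run_above_mean": float(_longest_run(above)),
        "longest_run_below_mean": float(_longest_run(below)),
        "first_loc_max": float(np.argmax(x) / n),
        "first_loc_min": float(np.argmin(x) / n),
        "last_loc_max": float((n - 1 - np.argmax(x[::-1])) / n),
        "last_loc_min": float((n - 1 - np.argmin(x[::-1])) / n),
        "n_peaks": float(peaks.size),
        "n_troughs": float(troughs.size),
        "mean_peak_distance": float(np.mean(np.diff(peaks))) if peaks.size >= 2 else 0.0,
        "turning_points": float(_sign_changes(d)) if d.size else 0.0,
        "slope_endpoints": float((x[-1] - x[0]) / max(n - 1, 1)),
        "cid_ce": float(np.sqrt(np.sum(d**2))) if d.size else 0.0,
        "time_reversal_asymmetry": float(np.mean(x[2:] ** 2 * x[1:-1] - x[1:-1] * x[:-2] ** 2))
        if n >= 3
        else 0.0,
        "c3_lag1": float(np.mean(x[2:] * x[1:-1] * x[:-2])) if n >= 3 else 0.0,
        "acf_first_zero": float(first_zero),
        "acf_sum_10": float(c.acf[1:11].sum()),
        "permutation_entropy": _permutation_entropy(x),
        "binned_entropy_diff": _entropy_bits(diff_counts / d.size) if d.size else 0.0,
        "ratio_beyond_1sigma": float(np.mean(np.abs(c.centered) > c.std))
        if c.std > 0
        else 0.0,
        "ratio_beyond_2sigma": float(np.mean(np.abs(c.centered) > 2 * c.std))
        if c.std > 0
        else 0.0,
    }
    for lag in range(1, ACF_MAX_LAG + 1):
        out[f"acf_lag_{lag}"] = float(c.acf[lag])
    return out


# ---------------------------------------------------------------------------
# spectral domain (70)
# ---------------------------------------------------------------------------

def _spectral(c: _Context) -> dict[str, float]:
    f, p = c.freqs, c.psd
    total = c.total_power
    degenerate = total <= _EPS or f.size == 0

    def dist_moment(k: int, centroid: float, spread: float) -> float:
        if degenerate or spread == 0:
            return 0.0
        return float(np.sum(((f - centroid) / spread) ** k * p) / total)

    if degenerate:
        centroid = spread = 0.0
        probs = np.zeros_like(p)
        cumsum = np.zeros_like(p)
    else:
        probs = p / total
        centroid = float(np.sum(f * probs))
        spread = float(np.sqrt(np.sum((f - centroid) ** 2 * probs)))
        cumsum = np.cumsum(p)

    def rolloff(frac: float) -> float:
        if degenerate:
            return 0.0
        idx = np.searchsorted(cumsum, frac * total)
        return float(f[min(idx, f.size - 1)])

    if degenerate:
        slope = decrease = 0.0
    else:
        slope = float(np.polyfit(f, p, 1)[0])
        k = np.arange(1, p.size)
        decrease = (
            float(np.sum((p[1:] - p[0]) / k) / p[1:].sum()) if p[1:].sum() > 0 else 0.0
        )
    flatness = (
        0.0
        if degenerate
        else float(np.exp(np.mean(np.log(p + _EPS))) / np.mean(p + _EPS))
    )
    sel_human = (f >= HUMAN_RANGE_BAND[0]) & (f < HUMAN_RANGE_BAND[1])
    nyq = c.fs / 2
    low = p[f <= nyq / 2].sum()
    high = p[f > nyq / 2].sum()
    psd_peaks, _ = sp_signal.find_peaks(p)
    out: dict[str, float] = {
        "spectral_centroid": centroid,
        "spectral_spread": spread,
        "spectral_skewness": dist_moment(3, centroid, spread),
        "spectral_kurtosis": dist_moment(4, centroid, spread),
        "spectral_slope": slope,
        "spectral_decrease": decrease,
        "spectral_rolloff_85": rolloff(0.85),
        "spectral_rolloff_95": rolloff(0.95),
        "spectral_flatness": flatness,
        "spectral_entropy": 0.0
        if degenerate
        else _entropy_bits(probs) / max(math.log2(probs.size), 1.0),
        "median_frequency": rolloff(0.5),
        "peak_frequency": 0.0 if degenerate else float(f[np.argmax(p)]),
        "max_psd": float(p.max()) if p.size else 0.0,
        "total_power": total,
        "mean_psd": float(p.mean()) if p.size else 0.0,
        "std_psd": float(p.std()) if p.size else 0.0,
        "psd_value_skew": 0.0 if degenerate else _std_moment(p, 3),
        "psd_value_kurtosis": 0.0
        if degenerate or np.ptp(p) == 0
        else _std_moment(p, 4) - 3.0,
        "spectral_crest": 0.0 if degenerate else float(p.max() / p.mean()),
        "human_range_energy": 0.0
        if degenerate or not sel_human.any()
        else float(p[sel_human].sum() / total),
        "power_ratio_low_high": 0.0 if high <= _EPS else float(low / high),
        "fundamental_frequency": float(f[psd_peaks[0]]) if psd_peaks.size else 0.0,
        "n_spectral_peaks": float(psd_peaks.size),
    }
    for i, frac in enumerate(np.arange(0.1, 1.0, 0.1), start=1):
        out[f"freq_at_energy_{i * 10}"] = rolloff(frac)
    edges = np.linspace(0, nyq, 11)
    for i in range(10):
        sel = (f > edges[i]) & (f <= edges[i + 1])
        out[f"band_energy_{i}"] = 0.0 if degenerate else float(p[sel].sum() / total)
    for k in range(1, 25):
        out[f"fft_mag_{k}"] = float(c.fft_mag[k - 1]) if k - 1 < c.fft_mag.size else 0.0
    # Haar-style multiscale detail energy: residual of a 2^L moving average
    energy = float(np.sum(c.x**2))
    for level in range(1, 5):
        width = 2**level
        if c.n >= width and energy > _EPS:
            smooth = np.convolve(c.x, np.ones(width) / width, mode="same")
            out[f"multiscale_detail_{level}"] = float(
                np.sum((c.x - smooth) ** 2) / energy
            )
        else:
            out[f"multiscale_detail_{level}"] = 0.0
    return out


# ---------------------------------------------------------------------------
# catalog assembly
# ---------------------------------------------------------------------------

def _catalog_names() -> tuple[list[str], dict[str, str]]:
    probe = _Context(np.arange(16, dtype=float) + 1.0, fs=1.0)
    names: list[str] = []
    domains: dict[str, str] = {}
    for domain, fn in (
        ("statistical", _statistical),
        ("temporal", _temporal),
        ("spectral", _spectral),
    ):
        feats = fn(probe)
        assert len(feats) == N_PER_DOMAIN, (domain, len(feats))
        for name in feats:
            tagged = f"{domain}__{name}"
            names.append(tagged)
            domains[tagged] = domain
    assert len(names) == N_FEATURES
    return names, domains


FEATURE_NAMES, FEATURE_DOMAINS = _catalog_names()


def extract_features(
    series: IndexSeries | np.ndarray, fs: float | None = None
) -> pd.Series:
    """Extract the frozen 210-feature vector from one index time series.

    ``fs`` is the index sampling rate (1/window_s); inferred from an
    IndexSeries, required for a bare array only if not 1 Hz.
    """
    if isinstance(series, IndexSeries):
        x = series.values
        fs = 1.0 / series.window_s
    else:
        x = np.asarray(series, dtype=float)
        fs = 1.0 if fs is None else fs
    if x.size < 8:
        raise ValueError(f"series too short for feature extraction: {x.size} < 8")
    c = _Context(x, fs)
    values: dict[str, float] = {}
    for domain, fn in (
        ("statistical", _statistical),
        ("temporal", _temporal),
        ("spectral", _spectral),
    ):
        for name, v in fn(c).items():
            values[f"{domain}__{name}"] = v
    vec = pd.Series(values, index=FEATURE_NAMES, dtype=float)
    if not np.isfinite(vec.to_numpy()).all():
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise FloatingPointError(f"non-finite feature values: {bad}")
    return vec


# ---------------------------------------------------------------------------
# ANOVA-F ranking
# ---------------------------------------------------------------------------

def anova_f(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """One-way ANOVA F statistic (two groups): MS_between / MS_within.

    Zero within-group variance with unequal group means returns +inf; with
    equal means, 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n = a.size + b.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    grand = (a.sum() + b.sum()) / n
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    if ssw == 0:
        return math.inf if ssb > 0 else 0.0
    return float((ssb / 1.0) / (ssw / (n - 2)))


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the three-stage feature selection."""

    ranked: tuple[tuple[str, float], ...]  # (feature, F) descending
    k_opt: int
    selected: tuple[str, ...]  # top-k_opt
    pruned: tuple[str, ...]  # after multicollinearity filter
    accuracy_path: tuple[tuple[int, float], ...]  # (n_features, mean accuracy)


def rank_features(
    table: pd.DataFrame,
    label_col: str = "label",
    feature_cols: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Rank features by descending ANOVA F against the binary label.

    Ties (and the all-zero case) are broken by catalog order; the sort is
    stable.
    """
    labels = table[label_col]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {classes}")
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c in set(FEATURE_NAMES)]
    mask_a = (labels == classes[0]).to_numpy()
    scores = []
    for col in feature_cols:
        v = table[col].to_numpy(dtype=float)
        scores.append((col, anova_f(v[mask_a], v[~mask_a])))
    return sorted(scores, key=lambda kv: -kv[1])


def halving_schedule(n_features: int, floor: int = HALVING_MIN_FEATURES) -> list[int]:
    """Feature counts evaluated by the halving search: n, n//2, ... down to
    the floor (for 210: 210, 105, 52, 26, 13, 7)."""
    counts = [n_features]
    while counts[-1] > floor:
        counts.append(max(floor, counts[-1] // 2))
    return counts


def iterative_halving(
    table: pd.DataFrame,
    learner_id: str = "L-R",
    split_plan=None,
    label_col: str = "label",
    ranked: list[tuple[str, float]] | None = None,
) -> SelectionResult:
    """Halve the feature count while Monte-Carlo accuracy keeps improving.

    Each count k is scored as the mean accuracy of ``learner_id`` over the
    split plan using the top-k ranked features; the first count whose score
    is below the previous one stops the search and the previous count is
    k_opt.
    """
    from .evaluation import make_splits, monte_carlo_evaluate

    if ranked is None:
        ranked = rank_features(table, label_col=label_col)
    if len(ranked) < 2:
        raise ValueError("need at least 2 features to run the halving search")
    if split_plan is None:
        split_plan = make_splits(table, seed=0)
    names = [name for name, _ in ranked]
    path: list[tuple[int, float]] = []
    k_opt = len(names)
    prev_acc = -np.inf
    for k in halving_schedule(len(names)):
        metrics = monte_carlo_evaluate(
            table, names[:k], learners=(learner_id,), split_plan=split_plan
        )
        acc = float(metrics["accuracy"].mean())
        path.append((k, acc))
        if acc < prev_acc:
            break
        k_opt = k
        prev_acc = acc
    selected = tuple(names[:k_opt])
    pruned = prune_multicollinear(table, list(selected))
    return SelectionResult(
        ranked=tuple(ranked),
        k_opt=k_opt,
        selected=selected,
        pruned=tuple(pruned),
        accuracy_path=tuple(path),
    )


def prune_multicollinear(
    table: pd.DataFrame,
    selected: list[str],
    r_threshold: float = R_THRESHOLD_DEFAULT,
) -> list[str]:
    """Greedy multicollinearity filter in the given (descending-F) order.

    A feature is dropped when its |Pearson r| with any already-retained
    feature exceeds the threshold.  Constant columns correlate 0 with
    everything by convention.
    """
    retained: list[str] = []
    data = {c: table[c].to_numpy(dtype=float) for c in selected}
    for cand in selected:
        v = data[cand]
        keep = True
        for kept in retained:
            w = data[kept]
            if np.ptp(v) == 0 or np.ptp(w) == 0:
                continue
            r = np.corrcoef(v, w)[0, 1]
            if np.isfinite(r) and abs(r) > r_threshold:
                keep = False
                break
        if keep:
            retained.append(cand)
    return retained
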