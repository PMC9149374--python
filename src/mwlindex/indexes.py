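"""Windowed band powers, electrode clusters and mental-workload index series.

A mental-workload (MWL) index is a per-window scalar built from EEG band
powers: either the band power of one electrode cluster, or a ratio of two
cluster powers.  Four canonical clusters are used — three frontal theta
clusters of decreasing extent and one parietal alpha cluster:

========  =====  ========================  ===========
cluster   band   electrodes                aggregation
========  =====  ========================  ===========
c1-theta  theta  AF3 AF4 F3 F4 F7 F8       average
c2-theta  theta  F3 F4                     average
c3-theta  theta  F3 F4 F7 F8               average
c-alpha   alpha  P7 P8                     average
========  =====  ========================  ===========

The alpha-to-theta ratios are ``at-k = c-alpha / ck-theta`` and the
theta-to-alpha ratios their reciprocals ``ta-k = ck-theta / c-alpha``,
giving ten index configurations in total (four single-cluster, six ratio).

Per 1-s non-overlapping window, band power is the sum of Hann-tapered
periodogram ordinates whose frequency falls in the half-open band
[f_lo, f_hi); the DC bin is always excluded and cluster powers are floored
at 1e-12 uV^2 before any division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import Recording

POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi})")


THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    band: BandDefinition
    electrodes: tuple[str, ...]
    aggregation: str = "Average"


C1_THETA = ClusterSpec("c1-theta", THETA, ("AF3", "AF4", "F3", "F4", "F7", "F8"))
C2_THETA = ClusterSpec("c2-theta", THETA, ("F3", "F4"))
C3_THETA = ClusterSpec("c3-theta", THETA, ("F3", "F4", "F7", "F8"))
C_ALPHA = ClusterSpec("c-alpha", ALPHA, ("P7", "P8"))

CLUSTERS: dict[str, ClusterSpec] = {
    c.name: c for c in (C1_THETA, C2_THETA, C3_THETA, C_ALPHA)
}


@dataclass(frozen=True)
class IndexDefinition:
    """One MWL index: a cluster power or a ratio of two cluster powers."""

    id: str
    numerator: ClusterSpec
    denominator: ClusterSpec | None = None

    @property
    def is_ratio(self) -> bool:
        return self.denominator is not None


def index_catalog() -> list[IndexDefinition]:
    """The ten MWL index configurations."""
    theta_clusters = (C1_THETA, C2_THETA, C3_THETA)
    catalog = [
        IndexDefinition("c1-theta", C1_THETA),
        IndexDefinition("c2-theta", C2_THETA),
        IndexDefinition("c3-theta", C3_THETA),
        IndexDefinition("c-alpha", C_ALPHA),
    ]
    for k, ck in enumerate(theta_clusters, start=1):
        catalog.append(IndexDefinition(f"at-{k}", C_ALPHA, ck))
    for k, ck in enumerate(theta_clusters, start=1):
        catalog.append(IndexDefinition(f"ta-{k}", ck, C_ALPHA))
    return catalog


INDEX_IDS: tuple[str, ...] = tuple(d.id for d in index_catalog())


def get_index(index_id: str) -> IndexDefinition:
    for d in index_catalog():
        if d.id == index_id:
            return d
    raise KeyError(f"unknown index id {index_id!r}; known: {INDEX_IDS}")


@dataclass(frozen=True)
class IndexSeries:
    subject_id: int
    condition: str
    index_id: str
    values: np.ndarray
    window_s: float


def segment_windows(rec: Recording, window_s: float = 1.0) -> np.ndarray:
    """Split into non-overlapping windows: (n_windows, win_len, n_channels).

    The trailing partial window is dropped.
    """
    win_len = int(round(rec.fs * window_s))
    if win_len < 2:
        raise ValueError(f"window of {window_s}s is under 2 samples at fs={rec.fs}")
    n_windows = rec.n_samples // win_len
    if n_windows < 1:
        raise ValueError("recording shorter than one window")
    trimmed = rec.samples[: n_windows * win_len]
    return trimmed.reshape(n_windows, win_len, rec.samples.shape[1])


def _periodogram(windows: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered periodogram along axis 1 of (n_windows, win_len, n_ch)."""
    freqs, psd = signal.periodogram(windows, fs=fs, window="hann", axis=1)
    return freqs, psd


def band_power(window_signal: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Band power of one single-channel window: sum of periodogram ordinates
    with frequency in [f_lo, f_hi), DC excluded."""
    x = np.asarray(window_signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    if band.f_lo >= fs / 2:
        raise ValueError(f"band {band.name} lies above Nyquist ({fs/2} Hz)")
    freqs, psd = signal.periodogram(x, fs=fs, window="hann")
    sel = (freqs >= band.f_lo) & (freqs < band.f_hi) & (freqs > 0)
    return float(psd[sel].sum())


def cluster_power(
    window: np.ndarray, cluster: ClusterSpec, fs: float, channel_names: tuple[str, ...]
) -> float:
    """Mean band power over a cluster's electrodes for one window (time x ch)."""
    missing = [e for e in cluster.electrodes if e not in channel_names]
    if missing:
        raise KeyError(f"cluster {cluster.name} electrodes missing: {missing}")
    idx = [channel_names.index(e) for e in cluster.electrodes]
    powers = [band_power(window[:, j], fs, cluster.band) for j in idx]
    return float(np.mean(powers))


def _cluster_power_series(
    rec: Recording, window_s: float
) -> dict[str, np.ndarray]:
    """Per-window band power for each canonical cluster, vectorized."""
    windows = segment_windows(rec, window_s)
    freqs, psd = _periodogram(windows, rec.fs)
    out: dict[str, np.ndarray] = {}
    for cluster in CLUSTERS.values():
        missing = [e for e in cluster.electrodes if e not in rec.channel_names]
        if missing:
            raise KeyError(f"cluster {cluster.name} electrodes missing: {missing}")
        idx = [rec.channel_names.index(e) for e in cluster.electrodes]
        band = cluster.band
        sel = (freqs >= band.f_lo) & (freqs < band.f_hi) & (freqs > 0)
        # sum over band bins, mean over cluster electrodes
        out[cluster.name] = psd[:, sel, :][:, :, idx].sum(axis=1).mean(axis=1)
    return out


def compute_index(
    rec: Recording, idx: IndexDefinition | str, window_s: float = 1.0
) -> IndexSeries:
    """Compute one MWL index time series for a recording."""
    if isinstance(idx, str):
        idx = get_index(idx)
    powers = _cluster_power_series(rec, window_s)
    num = np.maximum(powers[idx.numerator.name], POWER_FLOOR)
    if idx.denominator is None:
        values = num
    else:
        den = np.maximum(powers[idx.denominator.name], POWER_FLOOR)
        values = num / den
    return IndexSeries(rec.subject_id, rec.condition, idx.id, values, window_s)


def compute_all_indexes(
    rec: Recording, window_s: float = 1.0
) -> dict[str, IndexSeries]:
    """All ten index series from one pass over the windowed periodograms."""
    powers = _cluster_power_series(rec, window_s)
    floored = {k: np.maximum(v, POWER_FLOOR) for k, v in powers.items()}
    out: dict[str, IndexSeries] = {}
    for d in index_catalog():
        if d.denominator is None:
            values = floored[d.numerator.name]
        else:
            values = floored[d.numerator.name] / floored[d.denominator.name]
        out[d.id] = IndexSeries(rec.subject_id, rec.condition, d.id, values, window_s)
    return out
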