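"""Synthetic STEW-shaped EEG recordings and workload ratings.

The STEW corpus ("Simultaneous Task EEG Workload") records 48 subjects on a
14-channel consumer headset at 128 Hz for 150 s, once at rest and once while
performing the SIMKAP multitasking battery, with a single 1-9 self-reported
mental-effort rating per subject and condition.  This module emulates that
exact shape together with the physiology the band-ratio analysis relies on:
task load raises frontal theta (4-8 Hz) power and suppresses parietal alpha
(8-12 Hz) power relative to rest, and ratings skew high under task.

Signals are built from a pink-noise floor plus theta- and alpha-band-limited
Gaussian noise with fixed channel topographies, so spectral estimates carry
realistic variance rather than the degenerate spectra of pure sinusoids.
Optionally, ocular-artifact-like transients ("blinks") can be injected on
frontal channels with a ground-truth sample mask, giving the denoising stage
something measurable to remove.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import signal

# STEW channel order (Emotiv EPOC montage, 10-20 labels).
STEW_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

CONDITIONS: tuple[str, ...] = ("Rest", "Simkap")

# Topography weights: frontal channels carry the theta oscillation, the
# parietal/occipital channels carry alpha; every channel keeps a small
# weight so no column is a pure noise floor.
_FRONTAL = {"AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6"}
_PARIETAL = {"P7", "P8", "O1", "O2"}
_BASE_WEIGHT = 0.3

THETA_BAND = (4.0, 8.0)
ALPHA_BAND = (8.0, 12.0)

# Blink transients land on the channels nearest the eyes.
_BLINK_CHANNELS = {"AF3": 1.0, "AF4": 1.0, "F7": 0.6, "F8": 0.6}


@dataclass(frozen=True)
class Recording:
    """One subject x condition multichannel EEG matrix.

    ``samples`` is time x channels in microvolts; rows = ``fs * duration``.
    """

    subject_id: int
    condition: str
    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = STEW_CHANNELS

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"samples must be time x {len(self.channel_names)} channels, "
                f"got shape {self.samples.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None
        return self.samples[:, i]

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class RatingRecord:
    """Self-reported mental-effort rating (1-9 Likert) for one condition."""

    subject_id: int
    condition: str
    rating: int

    def __post_init__(self) -> None:
        if not 1 <= self.rating <= 9:
            raise ValueError(f"rating must be in 1..9, got {self.rating}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the source recordings' geometry (48 subjects, 128 Hz,
    150 s) and a task-load effect strong enough to separate the rating
    classes: Simkap doubles frontal theta power, halves parietal alpha
    power, and shifts the mean rating up by four points.
    """

    n_subjects: int = 48
    fs: float = 128.0
    duration_s: float = 150.0
    theta_task_gain: float = 2.0
    alpha_task_gain: float = 0.5
    background_exponent: float = 1.0
    blink_rate_hz: float = 0.1
    subject_scale_sigma: float = 0.4
    rating_effect: float = 4.0
    rating_sigma: float = 1.2
    rest_rating_mean: float = 3.0
    noise_scale_uv: float = 10.0
    oscillation_scale_uv: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.theta_task_gain < 1:
            raise ValueError("theta_task_gain must be >= 1")
        if not 0 < self.alpha_task_gain <= 1:
            raise ValueError("alpha_task_gain must be in (0, 1]")
        if self.blink_rate_hz < 0:
            raise ValueError("blink_rate_hz must be >= 0")


def _substream(seed: int, *keys: int) -> np.random.Generator:
    """Independent per-(subject, condition, purpose) stream off one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent Gaussian noise via spectral shaping, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Gaussian noise band-passed to ``band``, unit variance."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _channel_weights(channel_names: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
    theta_w = np.array(
        [1.0 if ch in _FRONTAL else _BASE_WEIGHT for ch in channel_names]
    )
    alpha_w = np.array(
        [1.0 if ch in _PARIETAL else _BASE_WEIGHT for ch in channel_names]
    )
    return theta_w, alpha_w


def generate_recording(
    cfg: GeneratorConfig, subject_id: int, condition: str
) -> Recording:
    """Synthesize one subject x condition recording.

    Each channel is an independent pink-noise floor plus shared theta and
    alpha band-limited oscillations scaled by the channel's topography
    weight.  Under Simkap the theta oscillation's power is multiplied by
    ``theta_task_gain`` (amplitude by its square root) and the alpha
    oscillation's power by ``alpha_task_gain``.  A per-subject log-normal
    amplitude gain (sigma ``subject_scale_sigma``, shared by both of a
    subject's conditions) models the large between-subject spread of
    absolute EEG amplitudes; band ratios are invariant to it, absolute band
    powers are not.  Deterministic given (seed, subject_id, condition).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    n = int(round(cfg.fs * cfg.duration_s))
    cond_code = CONDITIONS.index(condition)
    rng = _substream(cfg.seed, subject_id, cond_code, 0)

    theta_w, alpha_w = _channel_weights(STEW_CHANNELS)
    theta_amp = cfg.oscillation_scale_uv
    alpha_amp = cfg.oscillation_scale_uv
    if condition == "Simkap":
        theta_amp *= np.sqrt(cfg.theta_task_gain)
        alpha_amp *= np.sqrt(cfg.alpha_task_gain)

    # One oscillatory source per band, mixed over channels by topography;
    # per-channel independent band noise is added so channels decorrelate.
    theta_src = _band_noise(rng, n, cfg.fs, THETA_BAND)
    alpha_src = _band_noise(rng, n, cfg.fs, ALPHA_BAND)

    samples = np.empty((n, len(STEW_CHANNELS)))
    for j in range(len(STEW_CHANNELS)):
        floor = _pink_noise(rng, n, cfg.background_exponent) * cfg.noise_scale_uv
        theta_local = _band_noise(rng, n, cfg.fs, THETA_BAND)
        alpha_local = _band_noise(rng, n, cfg.fs, ALPHA_BAND)
        samples[:, j] = (
            floor
            + theta_amp * theta_w[j] * 0.5 * (theta_src + theta_local)
            + alpha_amp * alpha_w[j] * 0.5 * (alpha_src + alpha_local)
        )
    # between-subject amplitude spread: same gain for both conditions
    if cfg.subject_scale_sigma > 0:
        scale_rng = _substream(cfg.seed, subject_id, 3)
        samples *= np.exp(cfg.subject_scale_sigma * scale_rng.standard_normal())
    return Recording(subject_id, condition, samples, cfg.fs)


def inject_blinks(
    rec: Recording, blink_rate_hz: float, seed: int
) -> tuple[Recording, np.ndarray]:
    """Add eye-blink-like transients; returns (recording, sample mask).

    Events arrive as a Poisson process at ``blink_rate_hz``.  Each event is
    a smooth ~400 ms positive deflection (Hann pulse, sub-4 Hz energy) of
    roughly 150 uV on AF3/AF4 with reduced weight on F7/F8.  The boolean
    mask marks samples covered by any injected event.
    """
    if blink_rate_hz < 0:
        raise ValueError("blink_rate_hz must be >= 0")
    n = rec.n_samples
    mask = np.zeros(n, dtype=bool)
    if blink_rate_hz == 0:
        return rec, mask

    rng = _substream(seed, 1)
    n_events = rng.poisson(blink_rate_hz * rec.duration_s)
    if n_events == 0:
        return rec, mask

    width = max(int(round(0.4 * rec.fs)), 4)
    pulse = signal.windows.hann(width) * 150.0
    samples = rec.samples.copy()
    ch_idx = {
        rec.channel_names.index(ch): w
        for ch, w in _BLINK_CHANNELS.items()
        if ch in rec.channel_names
    }
    starts = rng.integers(0, max(n - width, 1), size=n_events)
    amplitudes = rng.uniform(0.7, 1.3, size=n_events)
    for start, amp in zip(starts, amplitudes):
        stop = min(start + width, n)
        seg = pulse[: stop - start] * amp
        for j, w in ch_idx.items():
            samples[start:stop, j] += w * seg
        mask[start:stop] = True
    return rec.with_samples(samples), mask


def generate_rating(
    cfg: GeneratorConfig, subject_id: int, condition: str
) -> RatingRecord:
    """Draw one 1-9 rating: truncated discretized Gaussian, shifted under task."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    cond_code = CONDITIONS.index(condition)
    rng = _substream(cfg.seed, subject_id, cond_code, 1)
    mean = cfg.rest_rating_mean + (cfg.rating_effect if condition == "Simkap" else 0.0)
    raw = rng.normal(mean, cfg.rating_sigma)
    rating = int(np.clip(np.rint(raw), 1, 9))
    return RatingRecord(subject_id, condition, rating)


def generate_dataset(
    cfg: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[list[Recording], list[RatingRecord]]:
    """Generate the full cohort: one recording and rating per subject x condition.

    Blinks are injected at ``cfg.blink_rate_hz``.  If ``out_dir`` is given the
    recordings and ratings are also written in the STEW text dialect.
    """
    recordings: list[Recording] = []
    ratings: list[RatingRecord] = []
    for subject_id in range(1, cfg.n_subjects + 1):
        for condition in CONDITIONS:
            rec = generate_recording(cfg, subject_id, condition)
            if cfg.blink_rate_hz > 0:
                blink_seed = int(
                    np.random.SeedSequence(
                        [cfg.seed, subject_id, CONDITIONS.index(condition), 2]
                    ).generate_state(1)[0] % (2**31)
                )
                rec, _ = inject_blinks(rec, cfg.blink_rate_hz, blink_seed)
            recordings.append(rec)
            ratings.append(generate_rating(cfg, subject_id, condition))
    if out_dir is not None:
        write_stew_dataset(recordings, ratings, out_dir)
    return recordings, ratings


# ---------------------------------------------------------------------------
# STEW-dialect I/O: whitespace-delimited text matrices, one file per
# subject x condition; ratings as a CSV of (subject_id, condition, rating).
# ---------------------------------------------------------------------------

def _stew_filename(subject_id: int, condition: str) -> str:
    return f"sub{subject_id:02d}_{condition.lower()}.txt"


def write_stew_recording(rec: Recording, path: str | Path) -> None:
    try:
        np.savetxt(path, rec.samples, fmt="%.6f", delimiter=" ")
    except OSError as exc:
        raise OSError(f"failed to write recording to {path}: {exc}") from exc


def read_stew_recording(
    path: str | Path,
    subject_id: int | None = None,
    condition: str | None = None,
    fs: float = 128.0,
) -> Recording:
    """Read one whitespace-delimited STEW matrix (rows x 14 channels).

    Subject/condition default to values parsed from a ``subNN_condition``
    filename when not given.
    """
    path = Path(path)
    if subject_id is None or condition is None:
        m = re.match(r"sub(\d+)_(\w+)", path.stem)
        if m is None:
            raise ValueError(
                f"cannot infer subject/condition from filename {path.name!r}; "
                "pass them explicitly"
            )
        subject_id = subject_id if subject_id is not None else int(m.group(1))
        if condition is None:
            condition = m.group(2).capitalize()
    try:
        samples = np.loadtxt(path)
    except OSError as exc:
        raise OSError(f"failed to read recording from {path}: {exc}") from exc
    return Recording(subject_id, condition, np.atleast_2d(samples), fs)


def write_stew_dataset(
    recordings: list[Recording],
    ratings: list[RatingRecord],
    out_dir: str | Path,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_stew_recording(rec, out_dir / _stew_filename(rec.subject_id, rec.condition))
    with open(out_dir / "ratings.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "condition", "rating"])
        for r in ratings:
            writer.writerow([r.subject_id, r.condition, r.rating])


def read_stew_dataset(
    in_dir: str | Path, fs: float = 128.0
) -> tuple[list[Recording], list[RatingRecord]]:
    in_dir = Path(in_dir)
    recordings = [
        read_stew_recording(p, fs=fs) for p in sorted(in_dir.glob("sub*_*.txt"))
    ]
    ratings: list[RatingRecord] = []
    ratings_path = in_dir / "ratings.csv"
    if ratings_path.exists():
        with open(ratings_path, newline="") as fh:
            for row in csv.DictReader(fh):
                ratings.append(
                    RatingRecord(
                        int(row["subject_id"]), row["condition"], int(row["rating"])
                    )
                )
    return recordings, ratings
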