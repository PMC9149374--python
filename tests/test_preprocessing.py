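"""Denoising pipeline: re-reference, high-pass, ICA, component screening."""

import numpy as np
import pytest
from scipy import signal

from mwlindex import (
    GeneratorConfig,
    Recording,
    component_statistics,
    decompose_ica,
    denoise,
    flag_components,
    generate_recording,
    highpass,
    inject_blinks,
    rereference_average,
)
from mwlindex.preprocessing import ComponentSet, hurst_rs


def _toy_recording(samples: np.ndarray, fs: float = 128.0) -> Recording:
    names = tuple(f"C{i}" for i in range(samples.shape[1]))
    return Recording(1, "Rest", samples, fs, channel_names=names)


class TestRereference:
    def test_two_channel_row(self):
        rec = _toy_recording(np.array([[2.0, 4.0]]))
        out = rereference_average(rec)
        np.testing.assert_allclose(out.samples, [[-1.0, 1.0]])

    def test_idempotent(self, rest_recording):
        once = rereference_average(rest_recording)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-12)

    def test_row_means_vanish(self):
        rng = np.random.default_rng(0)
        rec = _toy_recording(rng.standard_normal((256, 14)))
        out = rereference_average(rec)
        assert np.abs(out.samples.mean(axis=1)).max() < 1e-9

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_average(_toy_recording(np.zeros((10, 1))))


class TestHighpass:
    def test_dc_rejection(self):
        rec = _toy_recording(np.full((1280, 2), 100.0))
        out = highpass(rec)
        assert np.sqrt(np.mean(out.samples**2)) < 100.0 * 1e-6

    def test_10hz_passband_response(self):
        """Measured passband amplitude matches the designed filter response."""
        fs, f0 = 128.0, 10.0
        t = np.arange(int(10 * fs)) / fs
        rec = _toy_recording(np.column_stack([np.sin(2 * np.pi * f0 * t)] * 2), fs)
        out = highpass(rec, 1.0)
        sos = signal.butter(4, 1.0, btype="highpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[f0], fs=fs)
        expected = np.abs(h[0]) ** 2  # forward-backward: squared magnitude
        mid = out.samples[len(t) // 4 : -len(t) // 4, 0]
        measured = np.max(np.abs(mid))
        assert abs(measured - expected) < 0.05
        assert abs(measured - 1.0) < 0.05

    def test_stopband_attenuation_exceeds_20db(self):
        fs, f0 = 128.0, 0.1
        t = np.arange(int(60 * fs)) / fs
        rec = _toy_recording(np.column_stack([np.sin(2 * np.pi * f0 * t)] * 2), fs)
        out = highpass(rec, 1.0)
        mid = out.samples[len(t) // 4 : -len(t) // 4, 0]
        assert np.max(np.abs(mid)) < 10 ** (-20 / 20)

    def test_cutoff_at_nyquist_rejected(self):
        rec = _toy_recording(np.zeros((256, 2)), fs=128.0)
        with pytest.raises(ValueError):
            highpass(rec, 64.0)


class TestICA:
    def test_roundtrip_identity(self, rest_recording):
        comp = decompose_ica(rest_recording, seed=0)
        recon = comp.reconstruct()
        err = np.linalg.norm(recon - rest_recording.samples) / np.linalg.norm(
            rest_recording.samples
        )
        assert err < 1e-6

    def test_recovers_known_sources(self):
        """2-channel mix of a sinusoid and uniform noise separates cleanly."""
        rng = np.random.default_rng(1)
        n = 4000
        t = np.arange(n) / 128.0
        s1 = np.sin(2 * np.pi * 7.0 * t)
        s2 = rng.uniform(-1, 1, n)
        sources = np.column_stack([s1, s2])
        mixing = np.array([[1.0, 0.6], [0.4, 1.0]])
        rec = _toy_recording(sources @ mixing.T)
        comp = decompose_ica(rec, n_components=2, seed=0)
        corr = np.corrcoef(sources.T, comp.sources.T)[:2, 2:]
        # each true source matches one component up to order/sign
        assert sorted(np.abs(corr).max(axis=1) > 0.95) == [True, True]

    def test_same_seed_identical_up_to_sign(self, rest_recording):
        a = decompose_ica(rest_recording, seed=3)
        b = decompose_ica(rest_recording, seed=3)
        np.testing.assert_allclose(np.abs(a.unmixing), np.abs(b.unmixing), atol=1e-8)

    def test_too_many_components_rejected(self, rest_recording):
        with pytest.raises(ValueError):
            decompose_ica(rest_recording, n_components=15)


class TestComponentStatistics:
    @staticmethod
    def _component_set(sources: np.ndarray, fs: float = 128.0) -> ComponentSet:
        k = sources.shape[1]
        return ComponentSet(
            sources=sources,
            mixing=np.eye(k),
            unmixing=np.eye(k),
            mean=np.zeros(k),
            fs=fs,
        )

    def test_white_noise_hurst_near_half(self):
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(19200)
            assert 0.4 <= hurst_rs(x) <= 0.6

    def test_random_walk_hurst_near_one(self):
        walk = np.cumsum(np.random.default_rng(1).standard_normal(19200))
        assert hurst_rs(walk) > 0.8

    def test_z_columns_standardized(self):
        rng = np.random.default_rng(2)
        stats_ = component_statistics(self._component_set(rng.standard_normal((4096, 6))))
        z = stats_.z_matrix()
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_spike_train_dominates_gradient_median(self):
        n = 4096
        t = np.arange(n) / 128.0
        comps = [np.sin(2 * np.pi * f * t) for f in (3.0, 5.0, 8.0, 11.0)]
        spikes = np.zeros(n)
        spikes[::2] = 100.0  # alternating spikes: every first difference is huge
        comps.append(spikes)
        stats_ = component_statistics(self._component_set(np.column_stack(comps)))
        assert np.argmax(np.abs(stats_.z_gradient_median)) == 4

    def test_constant_component_conventions(self):
        rng = np.random.default_rng(3)
        sources = rng.standard_normal((4096, 4))
        sources[:, 0] = 5.0
        stats_ = component_statistics(self._component_set(sources))
        assert stats_.spectral_kurtosis[0] == 0.0
        assert stats_.hurst[0] == 0.5
        assert stats_.gradient_median[0] == 0.0
        assert np.isfinite(stats_.z_matrix()).all()


class TestFlagging:
    @staticmethod
    def _stats_with_z(z_hurst: np.ndarray):
        k = z_hurst.size
        zeros = np.zeros(k)
        from mwlindex.preprocessing import ComponentStats

        return ComponentStats(
            spectral_kurtosis=zeros, spectral_slope=zeros, hurst=zeros,
            gradient_median=zeros, z_spectral_kurtosis=zeros,
            z_spectral_slope=zeros, z_hurst=z_hurst, z_gradient_median=zeros,
            flagged=np.zeros(k, dtype=bool), z_threshold=np.inf,
        )

    def test_no_flags_within_threshold(self):
        stats_ = flag_components(self._stats_with_z(np.array([1.0, -2.0, 2.5])))
        assert stats_.flagged.sum() == 0

    def test_single_outlier_flagged(self):
        stats_ = flag_components(self._stats_with_z(np.array([0.0, 4.0, -1.0])))
        assert list(stats_.flagged) == [False, True, False]

    def test_flag_count_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(14) * 2
        base = self._stats_with_z(z)
        counts = [flag_components(base, thr).flagged.sum() for thr in (1.0, 2.0, 3.0, 4.0)]
        assert counts == sorted(counts, reverse=True)


class TestDenoise:
    def test_blink_components_flagged_and_energy_reduced(self):
        """High-rate blink injection: flags fire and sub-4 Hz frontal energy
        drops in >= 90% of seeds."""
        cfg = GeneratorConfig(n_subjects=1, duration_s=60.0, seed=20,
                              blink_rate_hz=0.0)
        flagged_runs = 0
        reduced_runs = 0
        n_seeds = 20
        frontal = ("AF3", "AF4", "F7", "F8")

        def low_freq_power(rec):
            total = 0.0
            for ch in frontal:
                f, p = signal.welch(rec.channel(ch), fs=rec.fs, nperseg=512)
                total += p[(f > 0) & (f < 4.0)].sum()
            return total

        for seed in range(n_seeds):
            rec = generate_recording(cfg, 1, "Rest")
            dirty, _ = inject_blinks(rec, 1.0, seed=seed)
            clean, report = denoise(dirty, seed=seed)
            if report.n_components_removed >= 1:
                flagged_runs += 1
            if low_freq_power(clean) < low_freq_power(dirty):
                reduced_runs += 1
        assert flagged_runs >= int(0.9 * n_seeds)
        assert reduced_runs >= int(0.9 * n_seeds)

    def test_blink_removal_reduces_af3_variance(self):
        cfg = GeneratorConfig(n_subjects=1, duration_s=60.0, seed=21,
                              blink_rate_hz=0.0)
        rec = generate_recording(cfg, 1, "Rest")
        dirty, _ = inject_blinks(rec, 1.0, seed=5)
        clean, report = denoise(dirty, seed=5)
        assert report.n_components_removed >= 1
        assert clean.channel("AF3").var() < dirty.channel("AF3").var()

    def test_artifact_free_recording_preserved(self):
        """Denoising clean data is near-lossless: >= 90% of (seed, channel)
        pairs keep input/output correlation above 0.9 (the z +/- 3 rule
        occasionally flags a clean outlier component, so per-seed
        losslessness cannot be absolute)."""
        cfg = GeneratorConfig(n_subjects=1, duration_s=60.0, seed=30,
                              blink_rate_hz=0.0)
        rec = generate_recording(cfg, 1, "Rest")
        corrs = []
        for seed in range(5):
            clean, _ = denoise(rec, seed=seed)
            corrs.extend(
                np.corrcoef(rec.samples[:, j], clean.samples[:, j])[0, 1]
                for j in range(rec.samples.shape[1])
            )
        assert np.mean(np.asarray(corrs) > 0.9) >= 0.9

    def test_report_bookkeeping(self, rest_recording):
        _, report = denoise(rest_recording, seed=2)
        assert report.n_components_removed == report.stats.flagged.sum()
        assert report.n_components_removed == len(report.removed_indices)
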