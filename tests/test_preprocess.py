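"""Filtering, resampling, re-referencing and robust-PCA behavior."""

import numpy as np
import pytest

from eegnets.core import EEGRecording, make_montage
from eegnets.preprocess import (
    bandpass,
    clean_recording,
    downsample,
    notch,
    rereference_average,
    robust_pca,
)


def _rec(data, rate=256):
    return EEGRecording(data=data, rate=rate, montage=make_montage(),
                        subject_id="S1", condition="active")


def _sine_rec(freq, rate, seconds=4.0):
    t = np.arange(int(seconds * rate)) / rate
    return _rec(np.tile(np.sin(2 * np.pi * freq * t), (64, 1)), rate)


def _amplitude_at(x, freq, rate):
    """Fourier-coefficient amplitude of a sinusoid at a known frequency."""
    t = np.arange(x.size) / rate
    return 2 * abs(np.mean(x * np.exp(-2j * np.pi * freq * t)))


class TestDownsample:
    def test_halves_sample_count(self):
        rec = _rec(np.random.default_rng(0).standard_normal((64, 1001)), rate=512)
        out = downsample(rec, 256)
        assert out.rate == 256
        assert out.n_samples == 1001 // 2

    def test_identity_when_rate_matches(self):
        rec = _rec(np.random.default_rng(0).standard_normal((64, 100)))
        assert downsample(rec, 256) is rec

    def test_non_integer_ratio_rejected(self):
        rec = _rec(np.zeros((64, 100)), rate=256)
        with pytest.raises(ValueError):
            downsample(rec, 200)

    def test_in_band_tone_survives(self):
        rec = _sine_rec(10.0, 512)
        out = downsample(rec, 256)
        # spectral peak stays at 10 Hz after decimation
        spec = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 256)
        assert abs(freqs[spec.argmax()] - 10.0) <= freqs[1]
        assert _amplitude_at(out.data[0], 10.0, 256) == pytest.approx(1.0, rel=0.05)

    def test_markers_rescaled(self):
        rec = EEGRecording(np.zeros((64, 1000)), 512, make_montage(), "S1",
                           "active", segment_markers=(100, 500, 900))
        out = downsample(rec, 256)
        assert out.segment_markers == (50, 250, 450)


class TestRereference:
    def test_common_mode_removed(self):
        rec = _rec(np.full((64, 50), 7.3))
        assert np.allclose(rereference_average(rec).data, 0.0)

    def test_idempotent(self, rng):
        rec = _rec(rng.standard_normal((64, 100)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-14)

    def test_column_means_vanish(self, rng):
        out = rereference_average(_rec(rng.standard_normal((64, 100))))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12


class TestBandpass:
    def test_dc_rejected(self):
        rec = _rec(np.full((64, 2048), 5.0))
        out = bandpass(rec, 1.0, 70.0)
        assert np.sqrt((out.data**2).mean()) < 0.01 * 5.0

    def test_passband_tone_preserved(self):
        rec = _sine_rec(10.0, 256, seconds=8)
        out = bandpass(rec, 1.0, 70.0)
        mid = out.data[0][256:-256]  # avoid edge transients
        ref = rec.data[0][256:-256]
        assert _amplitude_at(mid, 10.0, 256) == pytest.approx(
            _amplitude_at(ref, 10.0, 256), rel=0.10)

    def test_subsonic_tone_attenuated(self):
        rec = _sine_rec(0.1, 256, seconds=40)
        out = bandpass(rec, 1.0, 70.0)
        assert _amplitude_at(out.data[0], 0.1, 256) < 0.10

    def test_invalid_edges_rejected(self):
        rec = _rec(np.zeros((64, 100)))
        with pytest.raises(ValueError):
            bandpass(rec, 70.0, 1.0)
        with pytest.raises(ValueError):
            bandpass(rec, 1.0, 200.0)

    def test_zero_phase(self):
        """A filtered in-band sinusoid stays aligned with the original."""
        rec = _sine_rec(10.0, 256, seconds=8)
        out = bandpass(rec, 1.0, 70.0)
        a, b = rec.data[0], out.data[0]
        xc = np.correlate(a - a.mean(), b - b.mean(), "full")
        assert abs(xc.argmax() - (a.size - 1)) == 0


class TestNotch:
    def test_line_frequency_suppressed(self):
        rec = _sine_rec(60.0, 256, seconds=8)
        out = notch(rec, 60.0)
        assert _amplitude_at(out.data[0][256:-256], 60.0, 256) < 0.1

    def test_neighbors_preserved(self):
        rec = _sine_rec(10.0, 256, seconds=8)
        out = notch(rec, 60.0)
        assert _amplitude_at(out.data[0], 10.0, 256) == pytest.approx(1.0, rel=0.05)

    def test_zero_signal_passthrough(self):
        out = notch(_rec(np.zeros((64, 512))), 60.0)
        assert np.allclose(out.data, 0.0)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            notch(_rec(np.zeros((64, 100))), 200.0)


class TestRobustPCA:
    def test_zero_matrix(self):
        res = robust_pca(np.zeros((10, 20)))
        assert np.all(res.low_rank == 0) and np.all(res.sparse == 0)
        assert res.converged

    def test_low_rank_plus_spikes_separated(self, rng):
        """A rank-2 matrix with 1% gross outliers is recovered to 1e-3."""
        L = np.outer(rng.standard_normal(64), rng.standard_normal(2000))
        L += np.outer(rng.standard_normal(64), rng.standard_normal(2000))
        S = np.zeros_like(L)
        idx = rng.choice(L.size, size=L.size // 100, replace=False)
        S.flat[idx] = rng.choice([-10.0, 10.0], size=idx.size)
        res = robust_pca(L + S)
        assert np.linalg.norm(res.low_rank - L) / np.linalg.norm(L) < 1e-3

    def test_sparse_input_yields_small_low_rank(self, rng):
        M = np.zeros((64, 1000))
        idx = rng.choice(M.size, size=M.size // 100, replace=False)
        M.flat[idx] = rng.standard_normal(idx.size) * 5
        res = robust_pca(M)
        assert np.linalg.norm(res.low_rank) < 0.1 * np.linalg.norm(M)

    def test_exact_split_invariant(self, rng):
        M = rng.standard_normal((32, 200))
        res = robust_pca(M, tol=1e-7)
        assert np.linalg.norm(M - res.low_rank - res.sparse) / np.linalg.norm(M) <= 1e-6

    def test_nonfinite_rejected(self):
        M = np.zeros((4, 4))
        M[0, 0] = np.nan
        with pytest.raises(ValueError):
            robust_pca(M)


class TestCleaningChain:
    def test_chain_approximately_idempotent(self, small_group):
        """Re-cleaning already-clean data changes it by < 5% RMS."""
        rec = small_group[0]
        once = clean_recording(rec, rpca=False)
        twice = clean_recording(once, rpca=False)
        trim = slice(512, -512)
        num = np.sqrt(((twice.data - once.data)[:, trim] ** 2).mean())
        den = np.sqrt((once.data[:, trim] ** 2).mean())
        assert num / den < 0.05

    def test_chain_removes_injected_spikes(self, tiny_protocol):
        from eegnets.synthetic import default_networks, inject_artifacts, simulate_group

        rec = simulate_group(2, default_networks(2), tiny_protocol, seed=5)[0][0]
        dirty = inject_artifacts(rec, spike_rate=12.0, amplitude=30.0, seed=4)
        clean = clean_recording(dirty, rpca=True)
        ref = clean_recording(rec, rpca=False)
        # rPCA pulls the gross transients out of the kept low-rank part
        assert np.abs(clean.data).max() < 0.7 * np.abs(dirty.data).max()
        assert clean.data.std() == pytest.approx(ref.data.std(), rel=0.25)
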