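"""Beat extraction: R detection, template choice, sliding-correlation oracle,
alignment and the 1/sqrt(n) averaging law."""

import numpy as np
import pytest

from zfecg import (
    BeatSet,
    BeatTemplate,
    auto_template,
    bandpass,
    detect_r_peaks,
    ensemble_average,
    rr_intervals,
    template_search,
)
from zfecg.beats import extract_windows, sliding_normalized_correlation
from zfecg.simulate import BeatMorphology, synth_beat

from conftest import make_recording

FS = 2000.0


def naive_sliding_correlation(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Independent O(n*m) oracle: Pearson r of the template against every
    window, computed directly per lag."""
    m = t.size
    wins = np.lib.stride_tricks.sliding_window_view(x, m)
    wz = wins - wins.mean(axis=1, keepdims=True)
    tz = t - t.mean()
    denom = np.linalg.norm(wz, axis=1) * np.linalg.norm(tz)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = wz @ tz / denom
    r[~np.isfinite(r)] = 0.0
    return r


def periodic_trace(n_beats=20, rr_s=0.5, noise_sd=0.0, seed=0, invert=False):
    """Strictly periodic noiseless-by-default beat train, plus truth times."""
    m = BeatMorphology()
    beat = synth_beat(m, FS)
    n = int((n_beats + 1) * rr_s * FS)
    x = np.zeros(n)
    r_truth = []
    for k in range(n_beats):
        start = int(round((0.25 + k * rr_s) * FS))
        if start + beat.samples.size > n:
            break
        x[start : start + beat.samples.size] += beat.samples
        r_truth.append((start + beat.r_index) / FS)
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    if invert:
        x = -x
    return x, np.asarray(r_truth)


class TestDetectRPeaks:
    def test_noiseless_120bpm_gives_expected_peak_times(self):
        x, truth = periodic_trace(n_beats=20, rr_s=0.5)
        times = detect_r_peaks(x, FS)
        assert times.size == truth.size
        np.testing.assert_allclose(times, truth, atol=1.0 / FS + 1e-12)

    def test_inverted_polarity_auto_detected(self):
        x, truth = periodic_trace(n_beats=20, rr_s=0.5, invert=True)
        times = detect_r_peaks(x, FS, polarity="auto")
        np.testing.assert_allclose(times, truth, atol=1.0 / FS + 1e-12)

    def test_noisy_peaks_within_2ms_of_windowed_argmax_oracle(self):
        """At SNR >= 5 every detected peak lies within 2 ms of the argmax
        inside the corresponding ground-truth beat window."""
        cfg, trace, truth = make_recording("wildtype", duration_s=20.0, seed=5)
        filt = bandpass(trace)
        x = filt.data[:, 1]
        times = detect_r_peaks(x, FS)
        assert times.size == len(truth.r_times)
        for det, t_true in zip(times, truth.r_times):
            lo = int((t_true - 0.05) * FS)
            hi = int((t_true + 0.05) * FS)
            oracle = (lo + np.argmax(x[lo:hi])) / FS
            assert abs(det - oracle) <= 0.002

    def test_flat_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = detect_r_peaks(np.zeros(4000), FS)
        assert out.size == 0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.ones(100), FS, threshold=-1.0)


class TestAutoTemplate:
    def test_window_length_in_samples(self):
        x, r = periodic_trace(n_beats=10, rr_s=0.7)
        tpl = auto_template(x, FS, r, window_ms=650.0)
        assert tpl.waveform.size == 1300

    def test_periodic_recording_template_correlates_one_with_all(self):
        x, r = periodic_trace(n_beats=10, rr_s=0.7)
        tpl = auto_template(x, FS, r, window_ms=600.0)
        corr = sliding_normalized_correlation(x, tpl.waveform)
        peaks = np.sort(corr)[-10:]
        assert np.all(peaks > 1 - 1e-9)

    def test_artifact_corrupted_beat_never_selected(self):
        """Mean-correlation ranking (verified against the brute-force
        pairwise matrix) must avoid the one corrupted beat."""
        x, r = periodic_trace(n_beats=8, rr_s=0.7)
        bad = 3
        lo = int((r[bad] - 0.1) * FS)
        x = x.copy()
        x[lo : lo + 200] += np.random.default_rng(0).normal(0, 2.0, 200)
        tpl = auto_template(x, FS, r, window_ms=600.0)
        # oracle: brute-force mean pairwise correlation
        wins, kept, r_idx = extract_windows(x, FS, r, 0.18, 0.42)
        z = wins - wins.mean(axis=1, keepdims=True)
        zn = z / np.linalg.norm(z, axis=1, keepdims=True)
        mean_corr = (zn @ zn.T).sum(axis=1) - 1.0
        assert np.argmax(mean_corr) != bad
        start_of_bad = int(round(r[bad] * FS)) - r_idx
        assert not np.array_equal(
            tpl.waveform, x[start_of_bad : start_of_bad + wins.shape[1]]
        )

    def test_fewer_than_three_beats_rejected(self):
        x, r = periodic_trace(n_beats=2, rr_s=0.7)
        with pytest.raises(ValueError, match="3"):
            auto_template(x, FS, r[:2], window_ms=600.0)


class TestTemplateSearch:
    def test_correlations_match_naive_oracle_to_1e9(self):
        """FFT-based sliding correlation agrees with the direct per-lag
        computation to 1e-9 on a noisy 10 s fixture."""
        cfg, trace, _ = make_recording("wildtype", duration_s=10.0, seed=8)
        x = bandpass(trace).data[:, 1]
        r_times = detect_r_peaks(x, FS)
        tpl = auto_template(x, FS, r_times, 500.0)
        fast = sliding_normalized_correlation(x, tpl.waveform)
        slow = naive_sliding_correlation(x, tpl.waveform)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_reported_beat_correlations_match_recomputation(self):
        cfg, trace, _ = make_recording("wildtype", duration_s=10.0, seed=8)
        x = bandpass(trace).data[:, 1]
        tpl = auto_template(x, FS, detect_r_peaks(x, FS), 500.0)
        bs = template_search(x, FS, tpl)
        assert bs.n_beats > 0
        t = tpl.waveform - tpl.waveform.mean()
        for beat, c in zip(bs.beats, bs.correlation):
            bz = beat - beat.mean()
            direct = bz @ t / (np.linalg.norm(bz) * np.linalg.norm(t))
            assert c == pytest.approx(direct, abs=1e-12)
            assert c >= 0.8

    def test_periodic_recording_recovers_all_interior_beats(self):
        x, r = periodic_trace(n_beats=20, rr_s=0.5)
        tpl = auto_template(x, FS, r, 500.0)
        bs = template_search(x, FS, tpl, min_corr=0.9)
        assert abs(bs.n_beats - r.size) <= 2  # edge-truncated beats excluded
        np.testing.assert_allclose(np.diff(bs.r_times), 0.5, atol=2.0 / FS)

    def test_alignment_index_is_max_deflection_for_every_beat(self):
        cfg, trace, _ = make_recording("wildtype", duration_s=15.0, seed=9)
        x = bandpass(trace).data[:, 1]
        tpl = auto_template(x, FS, detect_r_peaks(x, FS), 500.0)
        bs = template_search(x, FS, tpl)
        for beat in bs.beats:
            assert int(np.argmax(beat - np.median(beat))) == bs.alignment_index

    def test_avb_template_extracts_only_conducted_beats(self):
        """With a normal-conduction template on a 2:1 AV-block recording the
        extracted beat count equals the QRS count, not the P count."""
        cfg, trace, truth = make_recording("avb_2to1", duration_s=30.0, seed=10)
        x = bandpass(trace).data[:, 1]
        r_times = detect_r_peaks(x, FS)
        tpl = auto_template(x, FS, r_times, 600.0)
        bs = template_search(x, FS, tpl)
        assert abs(bs.n_beats - len(truth.r_times)) <= 1
        assert bs.n_beats < len(truth.p_times)

    def test_no_match_warns_and_returns_empty(self):
        tpl = BeatTemplate(np.sin(np.linspace(0, 6, 200)), FS, 50)
        with pytest.warns(UserWarning):
            bs = template_search(
                np.random.default_rng(0).normal(size=4000), FS, tpl, min_corr=0.999
            )
        assert bs.n_beats == 0


class TestEnsembleAverage:
    def _beatset(self, beats):
        n = beats.shape[0]
        return BeatSet(
            beats=beats,
            r_times=np.arange(n) * 0.5 + 0.1,
            alignment_index=10,
            correlation=np.ones(n),
            fs_hz=FS,
        )

    def test_identical_beats_average_to_any_beat_with_zero_sd(self):
        beat = synth_beat(BeatMorphology(), FS).samples
        bs = self._beatset(np.tile(beat, (5, 1)))
        avg = ensemble_average(bs)
        np.testing.assert_allclose(avg.mean, beat, atol=1e-12)
        np.testing.assert_allclose(avg.sd, 0.0, atol=1e-12)

    def test_single_beat_average_is_that_beat(self):
        beat = synth_beat(BeatMorphology(), FS).samples
        avg = ensemble_average(self._beatset(beat[None, :]))
        np.testing.assert_allclose(avg.mean, beat)
        assert avg.n_beats == 1

    def test_empty_beatset_rejected(self):
        bs = BeatSet(np.empty((0, 10)), np.empty(0), 5, np.empty(0), FS)
        with pytest.raises(ValueError):
            ensemble_average(bs)

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_residual_noise_follows_inverse_sqrt_n(self, n):
        """Monte-Carlo over 500 replicates: the residual SD of the average of
        n noisy copies is sigma/sqrt(n) within 20 %."""
        clean = synth_beat(BeatMorphology(), FS).samples[:400]
        sigma = 0.2
        rng = np.random.default_rng(1234 + n)
        ratios = np.empty(500)
        for i in range(500):
            beats = clean + rng.normal(0, sigma, (n, clean.size))
            avg = ensemble_average(self._beatset(beats))
            ratios[i] = np.std(avg.mean - clean)
        assert np.mean(ratios) == pytest.approx(sigma / np.sqrt(n), rel=0.2)


class TestRRIntervals:
    def test_arithmetic(self):
        rr, mean_rr, hr = rr_intervals(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(rr, [0.5, 0.5])
        assert mean_rr == 0.5
        assert hr == pytest.approx(120.0)

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            rr_intervals(np.array([0.2]))

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            rr_intervals(np.array([0.5, 0.2]))
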