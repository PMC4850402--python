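"""Delineation and interval measurement: landmark definitions, Bazett,
absence contract, amplitude invariances, round-trip accuracy."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfecg import (
    Fiducials,
    analyze_trace,
    bazett_qtc,
    delineate,
    measure_intervals,
    r_amplitude,
)
from zfecg.beats import AverageBeat
from zfecg.simulate import BeatMorphology, preset, synth_beat

from conftest import make_recording

FS = 2000.0


def beat_from_morphology(m: BeatMorphology, scale=1.0, offset=0.0) -> AverageBeat:
    bw = synth_beat(m, FS)
    return AverageBeat(
        mean=scale * bw.samples + offset,
        sd=np.zeros_like(bw.samples),
        n_beats=1,
        fs_hz=FS,
        r_index=bw.r_index,
    )


class TestDelineate:
    def test_noiseless_wildtype_intervals_within_1ms_of_truth(self):
        m = BeatMorphology()
        fid = delineate(beat_from_morphology(m))
        assert fid.r_onset_ms - fid.p_onset_ms == pytest.approx(m.pr_ms, abs=1.0)
        assert fid.s_nadir_ms - fid.r_onset_ms == pytest.approx(m.qrs_ms, abs=1.0)
        assert fid.t_end_ms - fid.r_onset_ms == pytest.approx(m.qt_ms, abs=1.0)

    def test_zero_t_amplitude_reports_t_absent(self):
        fid = delineate(beat_from_morphology(BeatMorphology(t_amplitude=0.0)))
        assert fid.t_end_ms is None and fid.t_peak_ms is None
        rep = measure_intervals([fid], rr_ms=508.0)
        assert rep.qt_ms is None and rep.qtc_ms is None

    def test_flat_beat_returns_all_absent_without_exception(self):
        flat = AverageBeat(
            mean=np.zeros(1000), sd=np.zeros(1000), n_beats=1, fs_hz=FS, r_index=300
        )
        fid = delineate(flat)
        assert all(
            v is None for v in dataclasses.asdict(fid).values()
        )

    def test_injury_beat_shows_st_depression_and_inverted_t(self):
        m = preset("injury_acute").morphology
        fid = delineate(beat_from_morphology(m))
        assert fid.st_deviation_mv < 0
        assert fid.t_amplitude_mv < 0
        assert fid.t_end_ms is not None

    def test_inverted_polarity_beat_gives_negative_r_of_equal_magnitude(self):
        m = BeatMorphology()
        pos = r_amplitude(beat_from_morphology(m))
        neg = r_amplitude(beat_from_morphology(m, scale=-1.0))
        assert neg == pytest.approx(-pos, rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.05, 50.0, allow_nan=False))
    def test_amplitude_scale_changes_no_timing_output(self, scale):
        m = BeatMorphology()
        ref = delineate(beat_from_morphology(m))
        fid = delineate(beat_from_morphology(m, scale=scale))
        for name in ("p_onset_ms", "r_onset_ms", "r_peak_ms",
                     "s_nadir_ms", "t_peak_ms", "t_end_ms"):
            assert getattr(fid, name) == pytest.approx(
                getattr(ref, name), abs=1e-6
            )

    def test_dc_offset_does_not_change_r_amplitude(self):
        m = BeatMorphology()
        base = r_amplitude(beat_from_morphology(m))
        shifted = r_amplitude(beat_from_morphology(m, offset=0.2))
        assert shifted == pytest.approx(base, rel=0.01)
        assert base == pytest.approx(m.r_amplitude, rel=0.01)

    def test_landmark_ordering_holds_on_presets(self):
        for name in ("wildtype", "bre_longqt", "injury_acute",
                      "hyperkalemia_early", "hyperkalemia_severe"):
            fid = delineate(beat_from_morphology(preset(name).morphology))
            fid.validate()  # raises on an impossible ordering


class TestMeasureIntervals:
    def _fid(self, **kw):
        base = dict(
            p_onset_ms=100.0, p_peak_ms=115.0, r_onset_ms=163.5, r_peak_ms=177.5,
            s_nadir_ms=198.5, t_peak_ms=380.0, t_end_ms=445.5,
            r_amplitude_mv=1.0, t_amplitude_mv=0.3, st_deviation_mv=0.0,
        )
        base.update(kw)
        return Fiducials(**base)

    def test_intervals_from_fiducials(self):
        rep = measure_intervals([self._fid()], rr_ms=508.4745)
        assert rep.pr_ms == pytest.approx(63.5)
        assert rep.qrs_ms == pytest.approx(35.0)
        assert rep.qt_ms == pytest.approx(282.0)
        assert rep.qtc_ms == pytest.approx(282.0 / np.sqrt(0.5084745))
        assert rep.hr_bpm == pytest.approx(118.0, abs=0.01)

    def test_qt_averaged_only_when_t_on_both_probes(self):
        both = measure_intervals(
            [self._fid(), self._fid(t_end_ms=449.5, r_amplitude_mv=2.0)],
            rr_ms=500.0,
        )
        assert both.qt_source == "both_probes_mean"
        assert both.qt_ms == pytest.approx(284.0)

        single = measure_intervals(
            [self._fid(), self._fid(t_end_ms=None, r_amplitude_mv=2.0)],
            rr_ms=500.0,
        )
        assert single.qt_source == "single_probe"
        assert single.qt_ms == pytest.approx(282.0)

    def test_primary_channel_is_largest_r(self):
        rep = measure_intervals(
            [self._fid(), self._fid(r_amplitude_mv=2.0, s_nadir_ms=200.5)],
            rr_ms=500.0,
            channel_names=["probe1", "probe2"],
        )
        assert rep.channel_used == "probe2"
        assert rep.qrs_ms == pytest.approx(37.0)

    def test_impossible_ordering_rejected(self):
        bad = self._fid(t_end_ms=150.0, t_peak_ms=None)  # T end before S nadir
        with pytest.raises(ValueError, match="ordering"):
            measure_intervals([bad], rr_ms=500.0)

    def test_no_measurable_qrs_rejected(self):
        with pytest.raises(ValueError, match="QRS"):
            measure_intervals([Fiducials()], rr_ms=500.0)


class TestBazett:
    @pytest.mark.parametrize(
        "qt, rr, expected",
        [(400.0, 1.0, 400.0), (282.0, 0.25, 564.0), (300.0, 0.64, 375.0)],
    )
    def test_reference_values(self, qt, rr, expected):
        assert bazett_qtc(qt, rr) == pytest.approx(expected)

    def test_identity_at_rr_one_second(self):
        for qt in (250.0, 320.0, 414.0):
            assert bazett_qtc(qt, 1.0) == qt

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            bazett_qtc(0.0, 1.0)
        with pytest.raises(ValueError):
            bazett_qtc(300.0, 0.0)


class TestRoundTrip:
    """Full-pipeline parameter recovery on noisy preset recordings."""

    @pytest.mark.parametrize(
        "name", ["wildtype", "bre_longqt", "injury_acute", "hyperkalemia_early"]
    )
    def test_intervals_recovered_within_5ms_over_100_seeds(self, name):
        """All defined intervals recovered within +-5 ms of the generator
        parameters across 100 seeds at the default noise level (SNR ~ 10);
        the mean bias and SD stay well inside that band."""
        errs = {"pr": [], "qrs": [], "qt": []}
        for seed in range(100):
            cfg, trace, _ = make_recording(name, duration_s=30.0, seed=seed)
            rep = analyze_trace(trace).report
            m = cfg.morphology
            if rep.pr_ms is not None:
                errs["pr"].append(rep.pr_ms - m.pr_ms)
            errs["qrs"].append(rep.qrs_ms - m.qrs_ms)
            if rep.qt_ms is not None:
                errs["qt"].append(rep.qt_ms - m.qt_ms)
        for key, vals in errs.items():
            vals = np.asarray(vals)
            assert vals.size >= 95, f"{key}: too many absent measurements"
            assert np.max(np.abs(vals)) <= 5.0, (
                f"{key}: max |error| {np.max(np.abs(vals)):.2f} ms "
                f"(bias {vals.mean():.2f}, sd {vals.std():.2f})"
            )

    def test_noiseless_pipeline_recovers_truth_within_one_sample(self):
        """On a noiseless, jitter-free wild-type recording the pipeline
        (no filtering needed without noise) is exact to one sample period."""
        cfg, trace, _ = make_recording("wildtype", duration_s=20.0, noiseless=True)
        rep = analyze_trace(trace, apply_filter=False).report
        m = cfg.morphology
        tol = 1000.0 / FS
        assert rep.pr_ms == pytest.approx(m.pr_ms, abs=tol)
        assert rep.qrs_ms == pytest.approx(m.qrs_ms, abs=tol)
        assert rep.qt_ms == pytest.approx(m.qt_ms, abs=tol)
        assert rep.hr_bpm == pytest.approx(cfg.rhythm.hr_bpm, abs=0.1)
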