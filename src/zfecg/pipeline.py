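"""High-level analysis pipelines: trace in, report out.

These functions wire the modules together in the order the method uses
them — band-pass, R-peak detection, template search, ensemble averaging,
delineation — and are what the CLI and batch tools call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import beats as _beats
from .beats import (
    AverageBeat,
    BeatSet,
    auto_template,
    detect_r_peaks,
    ensemble_average,
    extract_windows,
    rr_intervals,
    template_search,
)
from .delineate import (
    DelineateConfig,
    Fiducials,
    IntervalReport,
    delineate,
    measure_intervals,
)
from .io import Trace
from .preprocess import FilterSpec, bandpass, lowfreq_component
from .rhythm import (
    RhythmConfig,
    RhythmReport,
    VectorReport,
    classify_rhythm,
    detect_p_waves,
    match_pr_series,
    vector_ratio,
)

__all__ = ["AnalysisResult", "analyze_trace", "rhythm_report", "vector_report"]


@dataclass
class AnalysisResult:
    """Everything the interval pipeline produced, for inspection."""

    report: IntervalReport
    fiducials: list[Fiducials]
    average_beats: list[AverageBeat]
    beatset: BeatSet
    r_times: np.ndarray
    filtered: Trace
    params: dict = field(default_factory=dict)


def _pick_channel(trace: Trace) -> int:
    """Channel with the largest robust deflection (the posterior probe in
    the standard chest montage)."""
    best, best_amp = 0, -np.inf
    for k in range(trace.n_channels):
        x = trace.data[:, k]
        med = np.median(x)
        amp = float(np.percentile(np.abs(x - med), 99.7))
        if amp > best_amp:
            best, best_amp = k, amp
    return best


def _auto_window_ms(rr_mean_s: float) -> float:
    """Template window from the measured RR, clipped to 500-800 ms.

    Slightly more than one cycle, so that even a long-QT beat keeps an
    isoelectric tail after the T wave for baseline anchoring; the next
    beat's P wave only enters in the final ~10 % of the window, where the
    delineator's bump exclusion handles it.
    """
    return float(np.clip(1.1 * rr_mean_s * 1000.0, 500.0, 800.0))


def analyze_trace(
    trace: Trace,
    channel: str | int | None = None,
    filter_spec: FilterSpec | None = None,
    min_corr: float = _beats.DEFAULT_MIN_CORR,
    template_window_ms: float | None = None,
    r_fraction: float = 0.3,
    delineate_config: DelineateConfig | None = None,
    apply_filter: bool = True,
    restore_subband: bool = True,
) -> AnalysisResult:
    """Full interval pipeline on one recording.

    Band-pass every channel, detect R peaks on the analysis channel (the one
    given, else the largest-amplitude one), build a template automatically,
    extract and align matching beats, ensemble-average each channel at the same
    aligned windows, delineate each channel's average, and combine into an
    :class:`IntervalReport`.

    Detection and template matching run on the band-passed signal; the
    averaged beats used for measurement additionally carry the sub-band
    heart-rate harmonics restored from the raw trace (see
    :func:`zfecg.preprocess.lowfreq_component`), so the ensemble average is
    undistorted by the high-pass edge while mains and wander stay rejected.
    """
    filter_spec = filter_spec or FilterSpec()
    filt = bandpass(trace, filter_spec) if apply_filter else trace
    if apply_filter and restore_subband:
        meas_data = filt.data + lowfreq_component(trace, filter_spec).data
    else:
        meas_data = filt.data

    ch_idx = (
        _pick_channel(filt)
        if channel is None
        else (filt.channel_names.index(channel) if isinstance(channel, str) else channel)
    )
    x = filt.data[:, ch_idx]
    fs = filt.fs_hz

    r_times = detect_r_peaks(x, fs)
    if r_times.size < 2:
        raise ValueError("fewer than two R peaks detected; cannot analyze")
    rr, rr_mean_s, hr = rr_intervals(r_times)

    window_ms = template_window_ms or _auto_window_ms(rr_mean_s)
    template = auto_template(x, fs, r_times, window_ms, r_fraction)
    beatset = template_search(x, fs, template, min_corr=min_corr)
    if beatset.n_beats == 0:
        raise ValueError("template search extracted no beats")

    pre_s = beatset.alignment_index / fs
    post_s = (template.waveform.size - beatset.alignment_index) / fs
    avg_beats: list[AverageBeat] = []
    for k in range(filt.n_channels):
        wins, kept, _ = extract_windows(
            meas_data[:, k], fs, beatset.r_times, pre_s, post_s
        )
        sub = BeatSet(
            beats=wins,
            r_times=kept,
            alignment_index=beatset.alignment_index,
            correlation=np.ones(wins.shape[0]),
            fs_hz=fs,
        )
        avg_beats.append(ensemble_average(sub))

    dcfg = delineate_config
    if dcfg is None and apply_filter and restore_subband:
        # the averaged beats are already free of high-pass warping, so the
        # delineator's harmonic baseline model adds only extrapolation
        # noise; a constant baseline is the right model here
        dcfg = DelineateConfig(baseline_max_freq_hz=0.0)
    fids = [delineate(b, dcfg) for b in avg_beats]
    params = {
        "filter": filter_spec.describe() if apply_filter else "none",
        "min_corr": min_corr,
        "template_window_ms": window_ms,
        "channel_analyzed": filt.channel_names[ch_idx],
    }
    report = measure_intervals(
        fids,
        rr_ms=rr_mean_s * 1000.0,
        n_beats=beatset.n_beats,
        channel_names=filt.channel_names,
        params=params,
    )
    return AnalysisResult(
        report=report,
        fiducials=fids,
        average_beats=avg_beats,
        beatset=beatset,
        r_times=r_times,
        filtered=filt,
        params=params,
    )


def rhythm_report(
    trace: Trace,
    channel: str | int | None = None,
    filter_spec: FilterSpec | None = None,
    rhythm_config: RhythmConfig | None = None,
) -> RhythmReport:
    """Band-pass, detect R peaks and P waves, classify the rhythm.

    R detection runs on the band-passed channel; P detection runs with the
    sub-band heart-rate harmonics restored (wander and mains stay rejected),
    since the small P deflection is easily distorted by the high-pass edge.
    """
    cfg = rhythm_config or RhythmConfig()
    fspec = filter_spec or FilterSpec()
    filt = bandpass(trace, fspec)
    ch_idx = (
        _pick_channel(filt)
        if channel is None
        else (filt.channel_names.index(channel) if isinstance(channel, str) else channel)
    )
    x = filt.data[:, ch_idx]
    fs = filt.fs_hz
    from .beats import estimate_polarity

    pol = estimate_polarity(x)
    r_times = detect_r_peaks(x, fs)
    x_meas = x + lowfreq_component(trace, fspec).data[:, ch_idx]
    p_times = detect_p_waves(x_meas, fs, r_times, cfg, polarity=pol)
    pr = match_pr_series(p_times, r_times, cfg.pr_window_ms)
    return classify_rhythm(p_times, r_times, pr, cfg)


def vector_report(
    trace: Trace,
    filter_spec: FilterSpec | None = None,
    delineate_config: DelineateConfig | None = None,
) -> VectorReport:
    """Dual-probe cardiac-vector ratio from one two-channel recording."""
    if trace.n_channels != 2:
        raise ValueError("vector analysis needs a two-channel recording")
    res = analyze_trace(
        trace, filter_spec=filter_spec, delineate_config=delineate_config
    )
    return vector_ratio(res.average_beats, delineate_config)
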