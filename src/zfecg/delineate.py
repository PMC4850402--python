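"""Landmark delineation and interval measurement on averaged beats.

Zebrafish interval conventions (the Q wave is absent and the J point
unidentifiable, so human QRS-onset/J-point rules do not apply):

* PR  = P upstroke to R upstroke,
* QRS = R upstroke to the negative peak (nadir) of the S wave,
* QT  = R upstroke to the end of the T wave,
* QTc = QT / sqrt(RR) with RR in seconds (Bazett).

"Upstroke" is operationalized as the last crossing, before the peak, of 10 %
of the wave's amplitude above baseline; "T end" as the trailing crossing of
10 % of the T peak.  Crossings are located with sub-sample linear
interpolation.  A landmark whose wave fails the detectability test
(amplitude below 3x the baseline-noise SD, or below a small fraction of the
R amplitude) is reported absent, never as 0.

A zero-phase band-pass applied to a quasi-periodic beat train removes the
harmonics of the heart rate that fall below the low edge (for zebrafish,
the ~2 Hz fundamental sits under a 3 Hz edge).  On the ensemble average this
appears as a smooth sinusoidal baseline at the beat frequency.  Before
measuring, the delineator fits ``c + sum_k a_k cos(2 pi k t / RR) +
b_k sin(...)`` (k = 1, 2) to the isoelectric samples of the averaged beat
and subtracts it, which restores the in-band waveform essentially exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .beats import AverageBeat

__all__ = [
    "DelineateConfig",
    "Fiducials",
    "IntervalReport",
    "delineate",
    "measure_intervals",
    "bazett_qtc",
    "r_amplitude",
]


@dataclass
class DelineateConfig:
    """Tunable delineation parameters (defaults cover all zebrafish
    phenotypes this package models; see docs/methods.md)."""

    onset_fraction: float = 0.10   # "upstroke" / "T end" threshold
    s_search_ms: float = 100.0     # S nadir searched within this after R peak
    p_search_ms: float = 150.0     # P searched within this before R onset
    t_search_min_ms: float = 20.0  # T search window after S nadir ...
    t_search_max_ms: float = 400.0
    st_window_ms: tuple[float, float] = (10.0, 40.0)  # after S nadir
    noise_sd_mult: float = 3.0     # detectability: amplitude >= mult * noise SD
    min_amp_fraction: float = 0.02  # ... and >= this fraction of |R|
    baseline_max_freq_hz: float = 3.5  # model beat harmonics below this
    pre_p_ms: float = 130.0        # pre-P isoelectric segment ends here before R
    n_passes: int = 3              # mask / baseline-fit / re-delineate rounds


@dataclass
class Fiducials:
    """Landmark times (ms from beat-window start) and amplitudes (mV).

    Every landmark is individually optional: ``None`` means the wave was not
    detectable.  Amplitudes are referenced to the isoelectric baseline and
    signed (negative R amplitude for inverted-polarity beats, negative T
    amplitude for inverted T waves).
    """

    p_onset_ms: float | None = None
    p_peak_ms: float | None = None
    r_onset_ms: float | None = None
    r_peak_ms: float | None = None
    s_nadir_ms: float | None = None
    t_peak_ms: float | None = None
    t_end_ms: float | None = None
    r_amplitude_mv: float | None = None
    t_amplitude_mv: float | None = None
    st_deviation_mv: float | None = None

    def validate(self) -> None:
        """Enforce the physiological ordering of the present landmarks."""
        chain = [
            ("p_onset_ms", self.p_onset_ms),
            ("r_onset_ms", self.r_onset_ms),
            ("r_peak_ms", self.r_peak_ms),
            ("s_nadir_ms", self.s_nadir_ms),
            ("t_peak_ms", self.t_peak_ms),
            ("t_end_ms", self.t_end_ms),
        ]
        present = [(n, v) for n, v in chain if v is not None]
        for (n1, v1), (n2, v2) in zip(present, present[1:]):
            ok = v1 <= v2 if (n1, n2) == ("s_nadir_ms", "t_peak_ms") else v1 < v2
            if not ok:
                raise ValueError(
                    f"impossible landmark ordering: {n1}={v1:.3f} ms not "
                    f"before {n2}={v2:.3f} ms"
                )


@dataclass
class IntervalReport:
    """The per-recording interval set in the units used for reporting
    (intervals ms, heart rate bpm)."""

    hr_bpm: float | None = None
    rr_ms: float | None = None
    pr_ms: float | None = None
    qrs_ms: float | None = None
    qt_ms: float | None = None
    qtc_ms: float | None = None
    n_beats_averaged: int | None = None
    channel_used: str | None = None
    qt_source: str | None = None  # "both_probes_mean" or "single_probe"
    params: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# helpers


def _interp_crossing(y: np.ndarray, i_below: int, thr: float) -> float:
    """Sub-sample index where y crosses ``thr`` between i_below and i_below+1."""
    y0, y1 = y[i_below], y[i_below + 1]
    if y1 == y0:
        return float(i_below)
    return i_below + (thr - y0) / (y1 - y0)


def _last_rising_crossing(y: np.ndarray, peak: int, thr: float, lo: int) -> float | None:
    """Last index before ``peak`` where ``y`` rises through ``thr``."""
    i = peak
    while i > lo:
        if y[i - 1] < thr <= y[i]:
            return _interp_crossing(y, i - 1, thr)
        i -= 1
    return None

def _first_falling_crossing(y: np.ndarray, peak: int, thr: float, hi: int) -> float | None:
    """First index after ``peak`` where ``y`` falls through ``thr``."""
    for i in range(peak, min(hi, y.size - 1)):
        if y[i] >= thr > y[i + 1]:
            return _interp_crossing(y, i, thr)
    return None


def _white_noise_sd(beat: AverageBeat) -> float:
    """Broadband residual noise of the averaged beat (first-difference MAD,
    insensitive to the waveform and to slow baseline components)."""
    d = np.diff(beat.mean)
    if d.size == 0:
        return 0.0
    mad = float(np.median(np.abs(d - np.median(d))))
    return 1.4826 * mad / math.sqrt(2.0)


def _noise_sd(beat: AverageBeat) -> float:
    """Residual noise SD used for the wave-detectability tests.

    The dispersion envelope / sqrt(n) additionally captures slow
    interference (e.g. baseline wander) that survives averaging; the larger
    of the two estimates decides whether a small wave is trustworthy.
    """
    est = [_white_noise_sd(beat)]
    if beat.n_beats > 1 and np.any(beat.sd > 0):
        est.append(float(np.median(beat.sd)) / math.sqrt(beat.n_beats))
    return max(est)


def _fit_baseline(
    x: np.ndarray,
    fs: float,
    rr_s: float | None,
    iso_mask: np.ndarray,
    max_freq_hz: float,
) -> np.ndarray:
    """Baseline model evaluated over the whole window.

    Constant plus, when the beat period is known and enough isoelectric
    samples exist, sinusoids at the harmonics of the beat rate that fall
    below ``max_freq_hz`` — exactly the components a high-pass with an edge
    above the heart rate strips from a quasi-periodic beat train.  The fit
    is lightly ridge-regularized and falls back to a constant when the
    fitted curve swings far beyond what the isoelectric samples support
    (an ill-conditioned extrapolation, e.g. on unfiltered data).
    """
    n = x.size
    if not iso_mask.any():
        return np.full(n, np.median(x))
    const = float(np.median(x[iso_mask]))
    n_harm = 0
    if rr_s is not None and rr_s > 0 and iso_mask.sum() >= 30:
        n_harm = int(math.floor(max_freq_hz * rr_s))
    if n_harm == 0:
        return np.full(n, const)
    t = np.arange(n) / fs
    cols = [np.ones(n)]
    for k in range(1, n_harm + 1):
        w = 2 * np.pi * k / rr_s
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    design = np.column_stack(cols)
    a = design[iso_mask]
    y = x[iso_mask]
    # ridge on the harmonic coefficients only
    alpha = 1e-3 * a.shape[0]
    ata = a.T @ a + alpha * np.diag([0.0] + [1.0] * (design.shape[1] - 1))
    coef = np.linalg.solve(ata, a.T @ y)
    model = design @ coef
    # clamp: the model must not swing far beyond the isoelectric evidence
    iso_ptp = float(np.ptp(x[iso_mask]))
    if np.ptp(model) > 3.0 * iso_ptp + 1e-12:
        return np.full(n, const)
    return model


# --------------------------------------------------------------------------
# the delineator


def _most_prominent_extremum(seg: np.ndarray) -> int:
    """Index of the most prominent bump of either sign in ``seg``; falls back
    to the absolute extremum when no interior peak exists."""
    best_idx, best_prom = None, 0.0
    for sgn in (1.0, -1.0):
        pk, props = sps.find_peaks(sgn * seg, prominence=0.0)
        if pk.size:
            j = int(np.argmax(props["prominences"]))
            if props["prominences"][j] > best_prom:
                best_prom = float(props["prominences"][j])
                best_idx = int(pk[j])
    if best_idx is None:
        return int(np.argmax(np.abs(seg)))
    return best_idx


def _delineate_once(
    y: np.ndarray,
    fs: float,
    cfg: DelineateConfig,
    noise_sd: float,
    r_hint: int | None = None,
) -> Fiducials:
    """Single delineation pass on a baseline-corrected, polarity-agnostic beat."""
    n = y.size
    ms = 1000.0 / fs

    def to_ms(idx: float) -> float:
        return idx * ms

    def samp(t_ms: float) -> int:
        return int(round(t_ms / ms))

    # R: extremum of the dominant polarity.  When the beat is R-aligned
    # (``r_hint`` from the upstream alignment index) search near that index —
    # a tall peaked T wave may otherwise rival the global extremum.
    if r_hint is not None and 0 <= r_hint < n:
        lo = max(0, r_hint - samp(40.0))
        hi = min(n, r_hint + samp(40.0) + 1)
    else:
        lo, hi = 0, n
    seg = y[lo:hi]
    pol = 1 if abs(np.max(seg)) >= abs(np.min(seg)) else -1
    z = pol * y
    r_peak = lo + int(np.argmax(z[lo:hi]))
    r_amp = float(z[r_peak])
    floor = cfg.min_amp_fraction * abs(r_amp)
    min_amp = max(cfg.noise_sd_mult * noise_sd, floor)
    if r_amp <= 0 or r_amp < cfg.noise_sd_mult * noise_sd:
        return Fiducials()

    fid = Fiducials(r_peak_ms=to_ms(r_peak), r_amplitude_mv=pol * r_amp)

    # R onset: last pre-peak rising crossing of 10 % of the R amplitude
    r_on = _last_rising_crossing(z, r_peak, cfg.onset_fraction * r_amp, 0)
    if r_on is None:
        return fid
    fid.r_onset_ms = to_ms(r_on)

    # S nadir: minimum within the post-R search window
    s_hi = min(n, r_peak + samp(cfg.s_search_ms) + 1)
    if r_peak + 1 < s_hi:
        seg = z[r_peak + 1 : s_hi]
        s_idx = r_peak + 1 + int(np.argmin(seg))
        s_depth = -float(z[s_idx])
        if s_depth >= min_amp:
            fid.s_nadir_ms = to_ms(s_idx)

    # P: most prominent bump in the window before the R onset
    p_lo = max(0, samp(fid.r_onset_ms - cfg.p_search_ms))
    p_hi = max(p_lo, int(math.floor(r_on)))
    if p_hi - p_lo >= 4:
        seg = z[p_lo:p_hi]
        pk, props = sps.find_peaks(seg, prominence=min_amp)
        if pk.size:
            best = pk[int(np.argmax(props["prominences"]))]
            p_peak = p_lo + int(best)
            p_amp = float(z[p_peak])
            if p_amp >= min_amp:
                fid.p_peak_ms = to_ms(p_peak)
                p_on = _last_rising_crossing(
                    z, p_peak, cfg.onset_fraction * p_amp, p_lo
                )
                if p_on is not None:
                    fid.p_onset_ms = to_ms(p_on)

    # T: most prominent bump of either polarity after the S nadir (raw
    # extrema are unreliable when slow interference survives averaging).
    # The wide, low-amplitude T has a shallow trailing slope, so its peak
    # and end are measured on a Savitzky-Golay-smoothed copy: quadratic
    # fitting suppresses residual noise without biasing a smooth curve.
    if fid.s_nadir_ms is not None:
        s_idx = samp(fid.s_nadir_ms)
        t_lo = s_idx + samp(cfg.t_search_min_ms)
        t_hi = min(n, s_idx + samp(cfg.t_search_max_ms) + 1)
        if t_hi - t_lo >= 4:
            win = min(samp(25.0) | 1, 2 * ((t_hi - t_lo - 1) // 2) + 1)
            ys = sps.savgol_filter(y, win, 2) if win >= 5 else y
            seg = ys[t_lo:t_hi]
            t_idx = t_lo + _most_prominent_extremum(seg)
            t_amp = float(ys[t_idx])
            if abs(t_amp) >= min_amp:
                fid.t_peak_ms = to_ms(t_idx)
                fid.t_amplitude_mv = t_amp
                zt = np.sign(t_amp) * ys
                t_end = _first_falling_crossing(
                    zt, t_idx, cfg.onset_fraction * abs(t_amp), n
                )
                if t_end is not None:
                    fid.t_end_ms = to_ms(t_end)

        # ST deviation over a fixed early post-S window (no J point exists)
        st_lo = s_idx + samp(cfg.st_window_ms[0])
        st_hi = s_idx + samp(cfg.st_window_ms[1])
        if 0 <= st_lo < st_hi <= n:
            fid.st_deviation_mv = float(np.mean(y[st_lo:st_hi]))

    return fid


def delineate(
    beat: AverageBeat, config: DelineateConfig | None = None
) -> Fiducials:
    """Locate P/R/S/T landmarks on an averaged (or single) beat.

    Two passes: a first delineation referenced to the pre-P median locates
    the beat; its landmarks define the isoelectric samples used to fit and
    subtract the harmonic baseline model; the corrected beat is then
    delineated again.  A flat or undetectable beat yields a
    :class:`Fiducials` with every landmark absent — never an exception.
    """
    cfg = config or DelineateConfig()
    x = np.asarray(beat.mean, dtype=float)
    n = x.size
    fs = beat.fs_hz
    if n < 8 or not np.any(np.isfinite(x)) or np.ptp(x) == 0:
        return Fiducials()
    ms = 1000.0 / fs
    noise_sd = _noise_sd(beat)

    # pass 1: constant baseline from the window head (pre-P region)
    head = max(4, beat.r_index - int(round(cfg.pre_p_ms * fs / 1000.0)))
    head = min(head, n)
    y = x - float(np.median(x[:head]))
    fid = _delineate_once(y, fs, cfg, noise_sd, beat.r_index)
    if fid.r_peak_ms is None:
        return fid

    for _ in range(max(0, cfg.n_passes - 1)):
        # isoelectric mask: everything clear of the beat's own waves ...
        lo_ms = fid.p_onset_ms - 20.0 if fid.p_onset_ms is not None else (
            fid.r_onset_ms - 30.0 if fid.r_onset_ms is not None
            else fid.r_peak_ms - 40.0
        )
        hi_ms = fid.t_end_ms + 40.0 if fid.t_end_ms is not None else (
            (fid.s_nadir_ms if fid.s_nadir_ms is not None else fid.r_peak_ms)
            + 100.0
        )
        iso = np.ones(n, dtype=bool)
        iso[max(0, int(lo_ms / ms)) : min(n, int(hi_ms / ms) + 1)] = False
        # ... and of any prominent narrow bump (neighbouring beat's waves,
        # non-conducted or sub-threshold P waves) leaking into the window;
        # the guard uses the broadband noise estimate so that slow
        # interference does not hide genuine bumps from the exclusion
        r_amp = abs(fid.r_amplitude_mv or np.ptp(x))
        guard = max(5.0 * _white_noise_sd(beat), 0.03 * r_amp)
        pad = int(round(50.0 / ms))
        for sgn in (1.0, -1.0):
            pk, _ = sps.find_peaks(
                sgn * y, prominence=guard, width=(None, int(round(80.0 / ms)))
            )
            for p in pk:
                iso[max(0, p - pad) : min(n, p + pad)] = False
        edge = max(1, int(2.0 / ms))
        iso[:edge] = False
        iso[n - edge :] = False

        baseline = _fit_baseline(
            x, fs, beat.rr_mean_s, iso, cfg.baseline_max_freq_hz
        )
        y = x - baseline
        fid = _delineate_once(y, fs, cfg, noise_sd, beat.r_index)
        if fid.r_peak_ms is None:
            return fid

    # drop any landmark that breaks the physiological ordering rather than
    # report an impossible set
    try:
        fid.validate()
    except ValueError:
        fid = replace(fid, t_peak_ms=None, t_end_ms=None, t_amplitude_mv=None)
        try:
            fid.validate()
        except ValueError:
            fid = replace(fid, p_onset_ms=None, p_peak_ms=None)
    return fid


# --------------------------------------------------------------------------
# intervals


def bazett_qtc(qt_ms: float, rr_s: float) -> float:
    """Heart-rate corrected QT by the Bazett formula: QT / sqrt(RR[s])."""
    if not qt_ms > 0:
        raise ValueError("qt_ms must be positive")
    if not rr_s > 0:
        raise ValueError("rr_s must be positive")
    return qt_ms / math.sqrt(rr_s)


def r_amplitude(beat: AverageBeat, config: DelineateConfig | None = None) -> float:
    """Signed, baseline-referenced R amplitude (mV) of an averaged beat."""
    fid = delineate(beat, config)
    if fid.r_amplitude_mv is None:
        raise ValueError("no detectable R wave on this beat")
    return fid.r_amplitude_mv


def measure_intervals(
    fiducials: list[Fiducials],
    rr_ms: float,
    n_beats: int | None = None,
    channel_names: list[str] | None = None,
    params: dict | None = None,
) -> IntervalReport:
    """Combine per-channel fiducials into the interval report.

    PR and QRS come from the primary channel (largest |R| amplitude).  QT is
    averaged over the channels on which the T wave is identifiable when that
    holds on at least two probes (``qt_source = "both_probes_mean"``);
    otherwise the single measurable probe is used and marked.  QTc is
    computed from QT by Bazett.
    """
    if not fiducials:
        raise ValueError("no fiducials supplied")
    if not rr_ms > 0:
        raise ValueError("rr_ms must be positive")
    for f in fiducials:
        f.validate()
    names = channel_names or [f"ch{i}" for i in range(len(fiducials))]

    measurable = [
        i
        for i, f in enumerate(fiducials)
        if f.r_onset_ms is not None and f.s_nadir_ms is not None
    ]
    if not measurable:
        raise ValueError("no channel with a measurable QRS complex")
    primary = max(
        measurable, key=lambda i: abs(fiducials[i].r_amplitude_mv or 0.0)
    )
    fp = fiducials[primary]

    pr = (
        fp.r_onset_ms - fp.p_onset_ms if fp.p_onset_ms is not None else None
    )
    qrs = fp.s_nadir_ms - fp.r_onset_ms

    qt_by_channel = [
        f.t_end_ms - f.r_onset_ms
        for f in fiducials
        if f.t_end_ms is not None and f.r_onset_ms is not None
    ]
    if len(qt_by_channel) >= 2:
        qt, qt_source = float(np.mean(qt_by_channel)), "both_probes_mean"
    elif len(qt_by_channel) == 1:
        qt, qt_source = qt_by_channel[0], "single_probe"
    else:
        qt, qt_source = None, None

    qtc = bazett_qtc(qt, rr_ms / 1000.0) if qt is not None else None
    return IntervalReport(
        hr_bpm=60000.0 / rr_ms,
        rr_ms=rr_ms,
        pr_ms=pr,
        qrs_ms=qrs,
        qt_ms=qt,
        qtc_ms=qtc,
        n_beats_averaged=n_beats,
        channel_used=names[primary],
        qt_source=qt_source,
        params=params or {},
    )
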