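"""Beat-to-beat rhythm classification, cardiac-vector ratio, QT-RR regression.

Rhythm labels follow the patterns seen in zebrafish hyperkalemia: fixed 2:1
second-degree AV block (two P waves per conducted QRS at a regular PP
interval) and a Wenckebach-like pattern (PR lengthening from beat to beat,
then an asystolic pause of between two and three baseline RR intervals, the
PR being longest just before and shortest just after the pause).

The cardiac-vector readout is the ratio of baseline-referenced R amplitudes
between the posterior and anterior chest probes; in the intact fish the
ventricular vector points posterior and the ratio is about 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .beats import AverageBeat
from .delineate import DelineateConfig, delineate

__all__ = [
    "RhythmConfig",
    "RhythmReport",
    "VectorReport",
    "QTRRFit",
    "detect_p_waves",
    "match_pr_series",
    "classify_rhythm",
    "vector_ratio",
    "qt_rr_regression",
]


@dataclass
class RhythmConfig:
    """Classifier tolerance bands (conventions; configurable and logged)."""

    blank_pre_ms: float = 40.0        # QRS blanking before each R peak (the
                                      # R upstroke is only ~10-25 ms pre-peak;
                                      # the P peak can sit 55-60 ms pre-peak)
    blank_post_ms: float = 60.0       # minimum QRS blanking after each R
    t_blank_max_ms: float = 400.0     # post-R blanking covering the T wave
    p_prominence_frac: float = 0.08   # P prominence floor, fraction of R
    p_min_width_ms: float = 5.0       # accepted P bump width at half prominence
    p_max_width_ms: float = 45.0      # rejects the broader T wave
    avb_ratio_band: tuple[float, float] = (1.8, 2.2)
    normal_ratio_band: tuple[float, float] = (0.9, 1.1)
    cv_max: float = 0.10              # regularity bound for PP / PR series
    pause_factor: float = 1.5         # RR > factor * median RR marks a pause
    pause_multiple_band: tuple[float, float] = (2.0, 3.0)
    min_group_fraction: float = 0.8   # Wenckebach groups that must conform
    pr_window_ms: tuple[float, float] = (250.0, 15.0)  # P search before R


@dataclass
class RhythmReport:
    label: str = "unclassified"  # normal | avb_2to1 | mobitz_like | unclassified
    n_p: int = 0
    n_qrs: int = 0
    p_to_qrs_ratio: float | None = None
    pr_series_ms: list = field(default_factory=list)
    pauses: list = field(default_factory=list)  # (start_s, duration_s, rr_multiple)
    params: dict = field(default_factory=dict)


@dataclass
class VectorReport:
    amp_probe1_mv: float
    amp_probe2_mv: float
    ratio_2_over_1: float | None
    r_polarity: list  # per-channel +1 / -1


@dataclass
class QTRRFit:
    slope: float      # ms per s
    intercept: float  # ms
    r: float          # Pearson correlation coefficient
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("QT-RR regression needs n >= 3")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient outside [-1, 1]")


# --------------------------------------------------------------------------
# P-wave detection


def detect_p_waves(
    x: np.ndarray,
    fs_hz: float,
    qrs_times: np.ndarray,
    config: RhythmConfig | None = None,
    polarity: int = 1,
) -> np.ndarray:
    """P-peak times (s) on a band-passed channel, outside QRS blanking.

    Candidates are prominence-tested bumps whose width at half prominence is
    narrower than a T wave; a blanking window around each detected R
    (``blank_pre_ms`` before the peak, through the T wave after it) is
    excluded.  May return an empty array (e.g. loss of P waves in severe
    hyperkalemia).
    """
    cfg = config or RhythmConfig()
    x = np.asarray(x, dtype=float)
    qrs_times = np.asarray(qrs_times, dtype=float)
    y = polarity * (x - np.median(x))
    # P-matched Gaussian smoothing: suppresses in-band noise extremes while
    # barely attenuating a P-width bump
    sig = 0.005 * fs_hz
    half_k = int(round(3 * sig))
    if half_k >= 1:
        kern = np.exp(-0.5 * (np.arange(-half_k, half_k + 1) / sig) ** 2)
        kern /= kern.sum()
        y = np.convolve(y, kern, mode="same")
    # running-median detrend: narrow bumps (P) survive, the slow baseline
    # left by the high-pass edge on a beat train does not
    med_k = int(round(0.120 * fs_hz)) | 1
    if y.size > med_k:
        y = y - sps.medfilt(y, med_k)

    blank = np.zeros(x.size, dtype=bool)
    pre = int(round(cfg.blank_pre_ms * fs_hz / 1000.0))
    # post-R blanking additionally covers the T wave (it would otherwise be
    # the most prominent non-QRS bump); capped at 3/4 of the beat period so
    # diastolic P waves stay visible
    post_ms = cfg.t_blank_max_ms
    if qrs_times.size >= 2:
        post_ms = min(post_ms, 0.75 * float(np.median(np.diff(qrs_times))) * 1000.0)
    post = int(round(max(post_ms, cfg.blank_post_ms) * fs_hz / 1000.0))
    for t in qrs_times:
        c = int(round(t * fs_hz))
        blank[max(0, c - pre) : min(x.size, c + post + 1)] = True

    if not (~blank).any():
        return np.empty(0)
    # first-difference MAD: insensitive to the beat waveform and to any slow
    # baseline component left after filtering
    d = np.diff(y[~blank])
    sd = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    r_amp = float(np.percentile(np.abs(y), 99.9)) if y.size else 0.0
    prom = max(6.0 * sd, cfg.p_prominence_frac * r_amp)
    if prom <= 0:
        return np.empty(0)

    wmin = cfg.p_min_width_ms * fs_hz / 1000.0
    wmax = cfg.p_max_width_ms * fs_hz / 1000.0
    # wlen localizes the prominence bases: a ripple on a residual baseline
    # slope must stand out from its own neighbourhood, not from a distant
    # valley
    peaks, _ = sps.find_peaks(
        y, prominence=prom, width=(wmin, wmax), wlen=int(round(0.25 * fs_hz))
    )
    peaks = peaks[~blank[peaks]]
    # guard against zero-phase filter transients at the recording edges
    edge = int(round(0.25 * fs_hz))
    peaks = peaks[(peaks >= edge) & (peaks < x.size - edge)]
    return peaks / fs_hz


def match_pr_series(
    p_times: np.ndarray,
    qrs_times: np.ndarray,
    window_ms: tuple[float, float] = (250.0, 15.0),
) -> list:
    """Per-QRS PR interval (ms, peak-to-peak), None when no P precedes.

    For each R, the latest P within ``(r - window[0], r - window[1])`` ms is
    taken as its conducted P wave.
    """
    p_times = np.asarray(p_times, dtype=float)
    out: list = []
    for r in np.asarray(qrs_times, dtype=float):
        lo, hi = r - window_ms[0] / 1000.0, r - window_ms[1] / 1000.0
        cand = p_times[(p_times > lo) & (p_times < hi)]
        out.append(float((r - cand[-1]) * 1000.0) if cand.size else None)
    return out


# --------------------------------------------------------------------------
# classification


def _cv(values: np.ndarray) -> float:
    """Robust coefficient of variation (MAD-based, insensitive to a single
    spurious event in an otherwise regular series)."""
    values = np.asarray(values, dtype=float)
    med = np.median(values) if values.size else 0.0
    if values.size < 2 or med == 0:
        return np.inf
    mad = np.median(np.abs(values - med))
    return float(1.4826 * mad / med)


def classify_rhythm(
    p_times: np.ndarray,
    qrs_times: np.ndarray,
    pr_series_ms: list | None = None,
    config: RhythmConfig | None = None,
) -> RhythmReport:
    """Classify the rhythm from event times.

    Rules (tolerance bands in :class:`RhythmConfig`):

    * ``avb_2to1``  — P:QRS count ratio ~2 with regular PP intervals;
    * ``mobitz_like`` — recurring groups of strictly increasing PR intervals
      separated by pauses of 2-3 baseline RR, post-pause PR below pre-pause;
    * ``normal``    — P:QRS ratio ~1, regular PR, no pauses;
    * ``unclassified`` otherwise (including < 5 QRS complexes).
    """
    cfg = config or RhythmConfig()
    p_times = np.asarray(p_times, dtype=float)
    qrs_times = np.asarray(qrs_times, dtype=float)
    n_p, n_qrs = p_times.size, qrs_times.size
    if pr_series_ms is None:
        pr_series_ms = match_pr_series(p_times, qrs_times, cfg.pr_window_ms)

    report = RhythmReport(
        n_p=int(n_p),
        n_qrs=int(n_qrs),
        p_to_qrs_ratio=(n_p / n_qrs) if n_qrs > 0 else None,
        pr_series_ms=list(pr_series_ms),
        params={
            "avb_ratio_band": cfg.avb_ratio_band,
            "normal_ratio_band": cfg.normal_ratio_band,
            "cv_max": cfg.cv_max,
            "pause_multiple_band": cfg.pause_multiple_band,
        },
    )
    if n_qrs < 5:
        warnings.warn("fewer than 5 QRS complexes: rhythm left unclassified")
        return report

    rr = np.diff(qrs_times)
    med_rr = float(np.median(rr))
    pause_mask = rr > cfg.pause_factor * med_rr
    baseline_rr = float(np.median(rr[~pause_mask])) if (~pause_mask).any() else med_rr
    pauses = [
        (float(qrs_times[i]), float(rr[i]), float(rr[i] / baseline_rr))
        for i in np.nonzero(pause_mask)[0]
    ]
    report.pauses = pauses

    pr_known = np.asarray([v for v in pr_series_ms if v is not None], dtype=float)
    ratio = report.p_to_qrs_ratio

    # Wenckebach-like: grouped beats between pauses
    if len(pauses) >= 2:
        lo, hi = cfg.pause_multiple_band
        multiples_ok = all(lo < m < hi for (_, _, m) in pauses)
        pause_idx = np.nonzero(pause_mask)[0]
        groups = []
        bounds = [-1] + list(pause_idx) + [len(qrs_times) - 1]
        for a, b in zip(bounds, bounds[1:]):
            idx = range(a + 1, b + 1)
            prs = [pr_series_ms[i] for i in idx if pr_series_ms[i] is not None]
            if len(prs) >= 2:
                groups.append(prs)
        def increasing(g):
            return all(b > a for a, b in zip(g, g[1:]))
        inner = groups[1:-1] if len(groups) > 2 else groups
        if multiples_ok and inner:
            frac = np.mean([increasing(g) for g in inner])
            post_below_pre = [
                g2[0] < g1[-1] for g1, g2 in zip(groups, groups[1:])
            ]
            if (
                frac >= cfg.min_group_fraction
                and np.mean(post_below_pre) >= cfg.min_group_fraction
            ):
                report.label = "mobitz_like"
                return report

    # fixed-ratio 2:1 AV block
    if ratio is not None and cfg.avb_ratio_band[0] <= ratio <= cfg.avb_ratio_band[1]:
        pp = np.diff(p_times)
        if pp.size >= 2 and _cv(pp) < cfg.cv_max and not pauses:
            report.label = "avb_2to1"
            return report

    # normal sinus rhythm
    if (
        ratio is not None
        and cfg.normal_ratio_band[0] <= ratio <= cfg.normal_ratio_band[1]
        and pr_known.size >= 2
        and _cv(pr_known) < cfg.cv_max
        and not pauses
    ):
        report.label = "normal"
    return report


# --------------------------------------------------------------------------
# cardiac vector and QT-RR


def vector_ratio(
    avg_beats: list[AverageBeat], config: DelineateConfig | None = None
) -> VectorReport:
    """Dual-probe R-amplitude ratio (|probe2| / |probe1|) with polarity.

    Requires exactly two channels with a measurable R wave.  The ratio is
    magnitude-based so a negative-going R (dorsal montage, or post-injury
    vector shift on probe 2) keeps its geometry information in
    ``r_polarity`` without flipping the ratio's sign.
    """
    if len(avg_beats) != 2:
        raise ValueError("vector_ratio needs exactly two channels")
    amps = []
    for k, beat in enumerate(avg_beats):
        fid = delineate(beat, config)
        if fid.r_amplitude_mv is None:
            raise ValueError(f"no measurable R wave on channel {k + 1}")
        amps.append(fid.r_amplitude_mv)
    a1, a2 = amps
    return VectorReport(
        amp_probe1_mv=a1,
        amp_probe2_mv=a2,
        ratio_2_over_1=(abs(a2) / abs(a1)) if a1 != 0 else None,
        r_polarity=[1 if a >= 0 else -1 for a in amps],
    )


def qt_rr_regression(qt_ms: np.ndarray, rr_s: np.ndarray) -> QTRRFit:
    """Ordinary least-squares QT (ms) on RR (s) across recordings."""
    qt_ms = np.asarray(qt_ms, dtype=float)
    rr_s = np.asarray(rr_s, dtype=float)
    if qt_ms.shape != rr_s.shape or qt_ms.ndim != 1:
        raise ValueError("qt_ms and rr_s must be 1-D arrays of equal length")
    n = qt_ms.size
    if n < 3:
        raise ValueError("QT-RR regression needs at least 3 recordings")
    if np.ptp(rr_s) == 0:
        raise ValueError("RR values are all identical: regression degenerate")
    fit = stats.linregress(rr_s, qt_ms)
    return QTRRFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n=n,
    )
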