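"""R-peak detection, template-search beat extraction, ensemble averaging.

The extraction pipeline mirrors semi-automatic template search as used in
electrophysiology practice: a complete heart-beat cycle (distinct P, R and T
waves, 500-800 ms of signal) serves as the reference waveform; windows of the
recording whose normalized cross-correlation with the template exceeds a
threshold are extracted, re-aligned on the highest-amplitude deflection (the
R wave) and averaged per sample.  Uncorrelated noise in the average falls as
1/sqrt(n_beats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "BeatTemplate",
    "BeatSet",
    "AverageBeat",
    "detect_r_peaks",
    "estimate_polarity",
    "auto_template",
    "template_search",
    "sliding_normalized_correlation",
    "extract_windows",
    "ensemble_average",
    "rr_intervals",
]

DEFAULT_REFRACTORY_S = 0.200  # ~300 bpm ceiling, safely above zebrafish rates
DEFAULT_MIN_CORR = 0.8


@dataclass
class BeatTemplate:
    """A reference heart-beat cycle used for template search."""

    waveform: np.ndarray
    fs_hz: float
    r_index: int
    window_ms: float = field(init=False)

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 1 or self.waveform.size < 8:
            raise ValueError("template waveform must be a 1-D sample sequence")
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("template contains non-finite samples")
        if not 0 <= self.r_index < self.waveform.size:
            raise ValueError("r_index outside the template window")
        self.window_ms = self.waveform.size * 1000.0 / self.fs_hz


@dataclass
class BeatSet:
    """Extracted beats aligned on the R peak.

    ``beats`` is (n_beats, window) in mV; ``r_times`` are the R-peak times in
    seconds; every beat's maximum-deflection sample sits at
    ``alignment_index``; ``correlation`` holds each beat's template match.
    """

    beats: np.ndarray
    r_times: np.ndarray
    alignment_index: int
    correlation: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.beats = np.atleast_2d(np.asarray(self.beats, dtype=float))
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.n_beats:
            if not np.all(np.diff(self.r_times) > 0):
                raise ValueError("r_times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return 0 if self.beats.size == 0 else self.beats.shape[0]


@dataclass
class AverageBeat:
    """Ensemble-averaged beat with a per-sample dispersion envelope."""

    mean: np.ndarray
    sd: np.ndarray
    n_beats: int
    fs_hz: float
    r_index: int
    rr_mean_s: float | None = None  # carried along for baseline modelling

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same length")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


# --------------------------------------------------------------------------
# R-peak detection


def estimate_polarity(x: np.ndarray) -> int:
    """Sign of the dominant deflection (+1 chest montage, -1 dorsal)."""
    med = np.median(x)
    return 1 if (np.max(x) - med) >= (med - np.min(x)) else -1


def _robust_peak_amplitude(y: np.ndarray, fs_hz: float, refractory_s: float) -> float:
    """Median height of the prominent local maxima of ``y``."""
    coarse = 0.3 * float(np.max(y))
    if coarse <= 0:
        return 0.0
    idx, props = sps.find_peaks(
        y, height=coarse, distance=max(1, int(refractory_s * fs_hz))
    )
    if idx.size == 0:
        return float(np.max(y))
    return float(np.median(props["peak_heights"]))


def detect_r_peaks(
    x: np.ndarray,
    fs_hz: float,
    threshold: float | str = "auto",
    polarity: int | str = "auto",
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> np.ndarray:
    """Detect R-peak times (seconds) by threshold search.

    Peaks are local maxima of the dominant-deflection signal above the
    threshold, separated by a refractory period.  ``threshold="auto"`` uses
    half of a robust peak-amplitude estimate (the median height of the
    prominent maxima).  A sharpness veto then rejects candidates whose local
    slope is far below that of the steepest candidates: the R deflection is
    the narrowest wave of the beat, so this keeps tall-but-broad peaked T
    waves (hyperkalemia) out of the R series even when they rival the R
    amplitude.  Returns an empty array, with a warning, when nothing crosses
    the threshold.
    """
    x = np.asarray(x, dtype=float)
    pol = estimate_polarity(x) if polarity == "auto" else int(polarity)
    y = pol * (x - np.median(x))
    if threshold == "auto":
        amp = _robust_peak_amplitude(y, fs_hz, refractory_s)
        thr = 0.5 * amp
    else:
        thr = float(threshold)
        if thr <= 0:
            raise ValueError("threshold must be positive")
    if thr <= 0:
        warnings.warn("flat signal: no R peaks found")
        return np.empty(0)
    idx, _ = sps.find_peaks(
        y, height=thr, distance=max(1, int(refractory_s * fs_hz))
    )
    if idx.size == 0:
        warnings.warn("no R peaks found above threshold")
        return np.empty(0)
    if idx.size >= 4:
        d = np.abs(np.gradient(y))
        w = max(1, int(round(0.030 * fs_hz)))
        sharp = np.array(
            [d[max(0, i - w) : i + w + 1].max() for i in idx]
        )
        ref = np.percentile(sharp, 75)
        idx = idx[sharp >= 0.45 * ref]
    return idx / fs_hz


# --------------------------------------------------------------------------
# templates and template search


def extract_windows(
    x: np.ndarray,
    fs_hz: float,
    center_times: np.ndarray,
    pre_s: float,
    post_s: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cut windows around ``center_times``; edge-truncated windows dropped.

    Returns ``(windows, kept_center_times, center_index)``.
    """
    x = np.asarray(x, dtype=float)
    pre = int(round(pre_s * fs_hz))
    post = int(round(post_s * fs_hz))
    rows, kept = [], []
    for t in np.asarray(center_times, dtype=float):
        c = int(round(t * fs_hz))
        if c - pre < 0 or c + post > x.size:
            continue
        rows.append(x[c - pre : c + post])
        kept.append(t)
    if not rows:
        return np.empty((0, pre + post)), np.empty(0), pre
    return np.vstack(rows), np.asarray(kept), pre


def auto_template(
    x: np.ndarray,
    fs_hz: float,
    r_times: np.ndarray,
    window_ms: float = 650.0,
    r_fraction: float = 0.3,
) -> BeatTemplate:
    """Pick the candidate beat that best agrees with all the others.

    Each detected beat becomes a candidate window (R peak at ``r_fraction``
    of the window); the one maximizing its mean Pearson correlation with all
    other candidates is returned as the template.  Requires at least three
    detected beats — with fewer, select a template manually.
    """
    r_times = np.asarray(r_times, dtype=float)
    win_s = window_ms / 1000.0
    pre_s = r_fraction * win_s
    windows, kept, r_idx = extract_windows(
        x, fs_hz, r_times, pre_s, win_s - pre_s
    )
    if windows.shape[0] < 3:
        raise ValueError(
            "need >= 3 complete beats for automatic template selection; "
            "provide a manual BeatTemplate instead"
        )
    z = windows - windows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    norms[norms == 0] = np.inf
    zn = z / norms[:, None]
    corr = zn @ zn.T
    mean_corr = (corr.sum(axis=1) - 1.0) / (corr.shape[0] - 1)
    best = int(np.argmax(mean_corr))
    return BeatTemplate(waveform=windows[best], fs_hz=fs_hz, r_index=r_idx)


def sliding_normalized_correlation(
    x: np.ndarray, template: np.ndarray
) -> np.ndarray:
    """Pearson correlation of ``template`` with every window of ``x``.

    FFT-accelerated; returns one value per valid lag
    (``len(x) - len(template) + 1``).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(template, dtype=float)
    m = t.size
    tz = t - t.mean()
    t_ss = float(tz @ tz)
    if t_ss == 0:
        raise ValueError("template has zero variance")
    num = sps.fftconvolve(x, tz[::-1], mode="valid")
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    win_sum = c1[m:] - c1[:-m]
    win_ss = (c2[m:] - c2[:-m]) - win_sum**2 / m
    win_ss = np.maximum(win_ss, 0.0)
    denom = np.sqrt(win_ss * t_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def template_search(
    x: np.ndarray,
    fs_hz: float,
    template: BeatTemplate,
    min_corr: float = DEFAULT_MIN_CORR,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> BeatSet:
    """Extract every beat matching ``template`` and align on the R wave.

    Sliding normalized cross-correlation against the template; local maxima
    with correlation >= ``min_corr`` are accepted (overlapping candidates
    resolved in favour of the higher correlation), then each window is
    re-cut so its maximum-deflection sample sits at the template's
    ``r_index``.  The stored correlation of each beat is recomputed at its
    final, re-aligned lag.
    """
    if not -1.0 <= min_corr <= 1.0:
        raise ValueError("min_corr must lie in [-1, 1]")
    x = np.asarray(x, dtype=float)
    t = template.waveform
    m = t.size
    if x.size < m:
        warnings.warn("trace shorter than template: no beats extracted")
        return BeatSet(
            np.empty((0, m)), np.empty(0), template.r_index, np.empty(0), fs_hz
        )
    r = sliding_normalized_correlation(x, t)
    cand, _ = sps.find_peaks(r, height=min_corr)
    if cand.size == 0:
        warnings.warn("no windows matched the template at this threshold")
        return BeatSet(
            np.empty((0, m)), np.empty(0), template.r_index, np.empty(0), fs_hz
        )
    # overlap resolution: greedy, best correlation first
    order = cand[np.argsort(r[cand])[::-1]]
    taken = np.zeros(x.size + m, dtype=bool)
    accepted = []
    min_sep = max(int(refractory_s * fs_hz), 1)
    for lag in order:
        if taken[lag]:
            continue
        taken[max(0, lag - min_sep + 1) : lag + min_sep] = True
        accepted.append(int(lag))
    accepted.sort()

    pol = estimate_polarity(t)
    rows, times, corrs = [], [], []
    for lag in accepted:
        win = x[lag : lag + m]
        peak = int(np.argmax(pol * (win - np.median(win))))
        start = lag + peak - template.r_index
        if start < 0 or start + m > x.size:
            continue  # beat would run past the recording edge
        win = x[start : start + m]
        wz = win - win.mean()
        denom = np.linalg.norm(wz) * np.linalg.norm(t - t.mean())
        c = float(wz @ (t - t.mean()) / denom) if denom else 0.0
        if c < min_corr:
            continue  # realignment moved the window off the match
        rows.append(win)
        times.append((start + template.r_index) / fs_hz)
        corrs.append(c)

    if not rows:
        warnings.warn("all matched beats were edge-truncated")
        return BeatSet(
            np.empty((0, m)), np.empty(0), template.r_index, np.empty(0), fs_hz
        )
    # realignment can merge neighbours onto the same R: deduplicate
    beats = np.vstack(rows)
    times = np.asarray(times)
    corrs = np.asarray(corrs)
    uniq: dict[float, int] = {}
    for i, tt in enumerate(times):
        j = uniq.get(tt)
        if j is None or corrs[i] > corrs[j]:
            uniq[tt] = i
    keep = sorted(uniq.values(), key=lambda i: times[i])
    return BeatSet(
        beats=beats[keep],
        r_times=times[keep],
        alignment_index=template.r_index,
        correlation=corrs[keep],
        fs_hz=fs_hz,
    )


# --------------------------------------------------------------------------
# averaging and RR statistics


def ensemble_average(beatset: BeatSet) -> AverageBeat:
    """Per-sample mean and standard deviation across the aligned beats."""
    if beatset.n_beats < 1:
        raise ValueError("cannot average an empty beat set")
    mean = beatset.beats.mean(axis=0)
    if beatset.n_beats == 1:
        sd = np.zeros_like(mean)
    else:
        sd = beatset.beats.std(axis=0, ddof=1)
    rr_mean = None
    if beatset.r_times.size >= 2:
        rr_mean = float(np.mean(np.diff(beatset.r_times)))
    return AverageBeat(
        mean=mean,
        sd=sd,
        n_beats=beatset.n_beats,
        fs_hz=beatset.fs_hz,
        r_index=beatset.alignment_index,
        rr_mean_s=rr_mean,
    )


def rr_intervals(r_times: np.ndarray) -> tuple[np.ndarray, float, float]:
    """RR intervals (s), their mean (s) and the heart rate (bpm).

    RR_i is the time between consecutive R peaks; HR = 60 / mean(RR).
    """
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size < 2:
        raise ValueError("need at least two R peaks to measure RR intervals")
    rr = np.diff(r_times)
    if np.any(rr <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    mean_rr = float(rr.mean())
    return rr, mean_rr, 60.0 / mean_rr
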