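"""Parametric simulator of adult zebrafish surface ECG.

Each beat is a sum of smooth unimodal kernels (Gaussian bumps) for the P, R,
S and T waves — zebrafish ECG has no Q wave and no identifiable J point, so
none is modelled.  Component centres are placed so that the analytic
landmarks used by the delineator (10 %-amplitude upstrokes, S nadir, trailing
10 % T end) reproduce the configured PR / QRS / QT intervals exactly:

* R upstroke  = R centre - r_width/2          (widths are full widths at 10 %)
* P upstroke  = R upstroke - PR
* S nadir     = S centre = R upstroke + QRS
* T end       = T centre + t_width/2 = R upstroke + QT

Rhythms cover normal sinus rhythm with RR jitter, fixed-ratio 2:1
atrioventricular block (two P waves per conducted QRS), and a Wenckebach-like
pattern (progressively lengthening PR over 3-4 beats, then an asystolic pause
of 2-3 baseline RR intervals).  Dual-probe geometry is modelled as per-channel
gain and polarity applied to the same underlying cardiac signal — the
posterior probe of the chest montage sees roughly twice the amplitude, the
dorsal montage sees a negative-going signal.  Noise terms: 50 Hz mains,
sub-Hz baseline wander, and broadband (white) muscle noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Trace

__all__ = [
    "BeatMorphology",
    "RhythmScript",
    "NoiseSpec",
    "SimConfig",
    "BeatWave",
    "GroundTruth",
    "synth_beat",
    "synth_recording",
    "preset",
    "PRESET_NAMES",
]

# Full width at 10 % of peak for a Gaussian = FW10 = 2*sqrt(2*ln 10)*sigma
_FW10 = 2.0 * math.sqrt(2.0 * math.log(10.0))


def _sigma(width_ms: float) -> float:
    """Gaussian sigma (ms) from full width at 10 % amplitude (ms)."""
    return width_ms / _FW10


@dataclass
class BeatMorphology:
    """Amplitudes/widths of the P, R, S, T bumps plus the timing intervals.

    Widths are full widths at 10 % of peak amplitude, in ms; amplitudes in mV
    (S negative by convention, T may be negative for inverted T waves).
    ``st_offset`` adds a flat plateau between the S wave and the T wave to
    model ST-segment deviation (negative = depression).
    """

    p_amplitude: float = 0.15
    p_width: float = 30.0
    r_amplitude: float = 1.0
    r_width: float = 28.0
    s_amplitude: float = -0.4
    s_width: float = 20.0
    t_amplitude: float = 0.3
    t_width: float = 120.0
    pr_ms: float = 63.5
    qrs_ms: float = 35.0
    qt_ms: float = 282.0
    st_offset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_width", "r_width", "s_width", "t_width"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.pr_ms > 0:
            raise ValueError("pr_ms must be > 0")
        if not self.qrs_ms > 0:
            raise ValueError("qrs_ms must be > 0")
        if not self.qt_ms > self.qrs_ms:
            raise ValueError("qt_ms must exceed qrs_ms")
        if self.qrs_ms <= self.r_width / 2:
            raise ValueError(
                "qrs_ms must exceed half the R width so the S wave sits "
                "after the R centre"
            )

    # analytic landmark layout, all in ms relative to the R upstroke -------

    @property
    def r_center(self) -> float:
        return self.r_width / 2.0

    @property
    def s_center(self) -> float:
        return self.qrs_ms

    @property
    def p_center(self) -> float:
        return -self.pr_ms + self.p_width / 2.0

    @property
    def t_center(self) -> float:
        return self.qt_ms - self.t_width / 2.0

    def narrowest_width_ms(self) -> float:
        widths = [self.r_width, self.s_width]
        if self.p_amplitude != 0:
            widths.append(self.p_width)
        if self.t_amplitude != 0:
            widths.append(self.t_width)
        return min(widths)


@dataclass
class RhythmScript:
    """Beat scheduling: rate, RR jitter and conduction pattern.

    ``hr_bpm`` is the ventricular (QRS) rate.  For ``avb_2to1`` two P waves
    are emitted per conducted QRS at a regular PP interval of RR/2.  For
    ``mobitz_like``, groups of ``asystole_after_beats`` conducted beats carry
    the progressively increasing PR intervals of ``pr_sequence``, then an
    asystolic pause of ``asystole_rr_multiple`` x RR follows (no P waves are
    emitted during the pause).
    """

    kind: str = "normal"
    hr_bpm: float = 118.0
    rr_jitter_sd: float = 5.0  # ms
    pr_sequence: list[float] | None = None
    asystole_after_beats: int | None = None
    asystole_rr_multiple: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "avb_2to1", "mobitz_like", "custom"):
            raise ValueError(f"unknown rhythm kind {self.kind!r}")
        if not self.hr_bpm > 0:
            raise ValueError("hr_bpm must be > 0")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be >= 0")
        if self.kind == "mobitz_like":
            if self.pr_sequence is None:
                self.pr_sequence = [60.0, 85.0, 110.0]
            if not all(
                b > a for a, b in zip(self.pr_sequence, self.pr_sequence[1:])
            ):
                raise ValueError("pr_sequence must be strictly increasing")
            if self.asystole_after_beats is None:
                self.asystole_after_beats = len(self.pr_sequence)
            if self.asystole_after_beats not in (3, 4):
                raise ValueError("asystole_after_beats must be 3 or 4")
            if len(self.pr_sequence) != self.asystole_after_beats:
                raise ValueError(
                    "pr_sequence length must equal asystole_after_beats"
                )
            if self.asystole_rr_multiple is None:
                # midpoint of the open (2, 3) interval
                self.asystole_rr_multiple = 2.5
            if not 2.0 < self.asystole_rr_multiple < 3.0:
                raise ValueError(
                    "asystole_rr_multiple must lie strictly between 2 and 3"
                )

    @property
    def rr_s(self) -> float:
        return 60.0 / self.hr_bpm


@dataclass
class NoiseSpec:
    """Additive noise: mains interference, baseline wander, white noise.

    Mains and wander are sinusoids with independent random phase per channel;
    white noise is i.i.d. Gaussian per sample.  The wander frequency must sit
    below, and the mains frequency above, the analysis band so the band-pass
    stage can remove both.
    """

    powerline_hz: float = 50.0
    powerline_amplitude: float = 0.2
    wander_hz: float = 0.5
    wander_amplitude: float = 0.4
    white_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("powerline_amplitude", "wander_amplitude", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.wander_hz < 1.0:
            raise ValueError("wander_hz must be < 1 Hz (below the pass band)")
        if not self.powerline_hz > 40.0:
            raise ValueError(
                "powerline_hz must be above the 40 Hz band edge"
            )

    def is_silent(self) -> bool:
        return (
            self.powerline_amplitude == 0
            and self.wander_amplitude == 0
            and self.white_sd == 0
        )


def _quiet() -> NoiseSpec:
    return NoiseSpec(powerline_amplitude=0.0, wander_amplitude=0.0, white_sd=0.0)


@dataclass
class SimConfig:
    """Complete description of a synthetic recording."""

    morphology: BeatMorphology = field(default_factory=BeatMorphology)
    rhythm: RhythmScript = field(default_factory=RhythmScript)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    duration_s: float = 60.0
    fs_hz: float = 2000.0
    probe_gains: list[float] = field(default_factory=lambda: [1.0, 2.0])
    probe_polarity: list[int] = field(default_factory=lambda: [1, 1])
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not self.fs_hz >= 500:
            raise ValueError("fs_hz must be >= 500 Hz")
        if len(self.probe_gains) != len(self.probe_polarity):
            raise ValueError("probe_gains and probe_polarity length mismatch")
        if any(p not in (1, -1) for p in self.probe_polarity):
            raise ValueError("probe_polarity entries must be +1 or -1")

    @property
    def n_channels(self) -> int:
        return len(self.probe_gains)


# --------------------------------------------------------------------------
# single-beat synthesis


def _check_fs(morph: BeatMorphology, fs_hz: float) -> None:
    narrow = morph.narrowest_width_ms()
    if narrow * fs_hz / 1000.0 < 4.0:
        raise ValueError(
            f"sampling rate {fs_hz} Hz resolves the narrowest wave "
            f"({narrow} ms) with fewer than 4 samples"
        )


def _add_components(
    sig: np.ndarray, t_ms: np.ndarray, morph: BeatMorphology, r_upstroke_ms: float
) -> None:
    """Add one beat's P/R/S/T (+ST plateau) to ``sig``; times in ms."""

    def bump(amp: float, center: float, width: float) -> None:
        if amp == 0:
            return
        s = _sigma(width)
        lo = np.searchsorted(t_ms, center - 8 * s)
        hi = np.searchsorted(t_ms, center + 8 * s)
        x = t_ms[lo:hi] - center
        sig[lo:hi] += amp * np.exp(-0.5 * (x / s) ** 2)

    u = r_upstroke_ms
    bump(morph.p_amplitude, u + morph.p_center, morph.p_width)
    bump(morph.r_amplitude, u + morph.r_center, morph.r_width)
    bump(morph.s_amplitude, u + morph.s_center, morph.s_width)
    bump(morph.t_amplitude, u + morph.t_center, morph.t_width)
    if morph.st_offset != 0:
        # flat-topped plateau (super-Gaussian) spanning the early ST segment;
        # edge transitions kept gentle so the plateau stays inside the
        # analysis band and does not smear into the S trough when filtered
        center = u + morph.s_center + 35.0
        w = 55.0
        lo = np.searchsorted(t_ms, center - 2.5 * w)
        hi = np.searchsorted(t_ms, center + 2.5 * w)
        x = t_ms[lo:hi] - center
        sig[lo:hi] += morph.st_offset * np.exp(-((x / w) ** 4))


def _beat_truth(morph: BeatMorphology, r_upstroke_ms: float) -> dict:
    """Analytic landmark times (ms) for a beat with the given R upstroke."""
    u = r_upstroke_ms
    truth = {
        "r_onset_ms": u,
        "r_peak_ms": u + morph.r_center,
        "s_nadir_ms": u + morph.s_center,
        "p_onset_ms": u - morph.pr_ms if morph.p_amplitude != 0 else None,
        "p_peak_ms": u + morph.p_center if morph.p_amplitude != 0 else None,
        "t_peak_ms": u + morph.t_center if morph.t_amplitude != 0 else None,
        "t_end_ms": u + morph.qt_ms if morph.t_amplitude != 0 else None,
    }
    return truth


@dataclass
class BeatWave:
    """One synthesized beat with its analytic ground-truth landmarks."""

    samples: np.ndarray
    fs_hz: float
    fiducials: dict  # landmark name -> ms from window start (None if absent)
    r_index: int


def synth_beat(morphology: BeatMorphology, fs_hz: float = 2000.0) -> BeatWave:
    """Sample a single beat and return it with analytic fiducials.

    The window spans from before the P upstroke to after the T end with
    isoelectric margins on both sides.
    """
    _check_fs(morphology, fs_hz)
    m = morphology
    pre = m.pr_ms + m.p_width + 60.0  # before R upstroke
    post = m.qt_ms + m.t_width / 2.0 + 60.0
    n = int(round((pre + post) * fs_hz / 1000.0))
    t_ms = np.arange(n) * 1000.0 / fs_hz
    sig = np.zeros(n)
    _add_components(sig, t_ms, m, pre)
    truth = _beat_truth(m, pre)
    fid = {k: (None if v is None else v) for k, v in truth.items()}
    r_index = int(round(fid["r_peak_ms"] * fs_hz / 1000.0))
    return BeatWave(samples=sig, fs_hz=fs_hz, fiducials=fid, r_index=r_index)


# --------------------------------------------------------------------------
# full recordings


@dataclass
class GroundTruth:
    """Per-beat landmark times and rhythm annotations, in seconds."""

    beats: list[dict]          # per conducted beat: landmark name -> s (or None)
    r_times: list[float]       # R-peak times, s
    p_times: list[float]       # P-peak times (conducted and non-conducted), s
    rhythm: str
    pauses: list[dict] = field(default_factory=list)
    pr_ms: list[float] = field(default_factory=list)  # per conducted beat

    def to_json(self, path: str | Path) -> None:
        d = {
            "beats": self.beats,
            "events": {"r_times_s": self.r_times, "p_times_s": self.p_times},
            "labels": {"rhythm": self.rhythm, "pauses": self.pauses,
                       "pr_ms": self.pr_ms},
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")


def _schedule(config: SimConfig, rng: np.random.Generator):
    """Return (r_upstrokes_s, pr_ms_per_beat, extra_p_times_s, pauses)."""
    rhythm = config.rhythm
    m = config.morphology
    rr = rhythm.rr_s
    jit_s = rhythm.rr_jitter_sd / 1000.0
    # leave room for a full beat at both edges (and keep the first P clear
    # of analysis edge guards)
    lead = max((m.pr_ms + m.p_width + 80.0) / 1000.0, 0.4)
    tail = (m.qt_ms + m.t_width / 2.0 + 80.0) / 1000.0
    if rhythm.kind == "avb_2to1":
        # room for the non-conducted P preceding the first conducted beat
        lead += rr / 2.0
    t_start = lead
    t_stop = config.duration_s - tail

    upstrokes: list[float] = []
    pr_list: list[float] = []
    extra_p: list[float] = []
    pauses: list[dict] = []

    if rhythm.kind in ("normal", "custom", "avb_2to1"):
        k = 0
        while True:
            t = t_start + k * rr
            if t > t_stop:
                break
            if jit_s > 0:
                t += rng.normal(0.0, jit_s)
            if t_start - rr / 2 < t <= t_stop:
                upstrokes.append(t)
                pr_list.append(m.pr_ms)
                if rhythm.kind == "avb_2to1":
                    # non-conducted P midway between conducted ones: PP = RR/2
                    p_peak = t + m.p_center / 1000.0
                    extra_p.append(p_peak - rr / 2.0)
            k += 1
    elif rhythm.kind == "mobitz_like":
        seq = list(rhythm.pr_sequence)
        mult = float(rhythm.asystole_rr_multiple)
        t = t_start
        i_in_group = 0
        while t <= t_stop:
            jt = t + (rng.normal(0.0, jit_s) if jit_s > 0 else 0.0)
            if jt <= t_stop:
                upstrokes.append(jt)
                pr_list.append(seq[i_in_group])
            i_in_group += 1
            if i_in_group == len(seq):
                pause_len = mult * rr
                if jt + pause_len <= t_stop + rr:
                    pauses.append(
                        {
                            "start_s": jt,
                            "duration_s": pause_len,
                            "rr_multiple": mult,
                        }
                    )
                t = t + pause_len
                i_in_group = 0
            else:
                t = t + rr
    else:  # pragma: no cover - kinds validated upstream
        raise ValueError(rhythm.kind)
    return upstrokes, pr_list, extra_p, pauses


def synth_recording(config: SimConfig) -> tuple[Trace, GroundTruth]:
    """Generate a seeded multi-channel recording plus its ground truth.

    Channel ``k`` equals ``probe_polarity[k] * probe_gains[k] * clean + noise``
    with an independent noise realization per channel.  Identical config and
    seed give bit-identical output.
    """
    _check_fs(config.morphology, config.fs_hz)
    m = config.morphology
    fs = config.fs_hz
    rng = np.random.default_rng(config.seed)

    upstrokes, pr_list, extra_p, pauses = _schedule(config, rng)

    n = int(round(config.duration_s * fs))
    t_ms = np.arange(n) * 1000.0 / fs
    clean = np.zeros(n)

    beats: list[dict] = []
    r_times: list[float] = []
    p_times: list[float] = []
    for u_s, pr in zip(upstrokes, pr_list):
        morph = m if pr == m.pr_ms else dataclasses.replace(m, pr_ms=pr)
        _add_components(clean, t_ms, morph, u_s * 1000.0)
        truth_ms = _beat_truth(morph, u_s * 1000.0)
        beat = {
            k.replace("_ms", "_s"): (None if v is None else v / 1000.0)
            for k, v in truth_ms.items()
        }
        beat["pr_ms"] = pr if morph.p_amplitude != 0 else None
        beat["qrs_ms"] = m.qrs_ms
        beat["qt_ms"] = m.qt_ms if m.t_amplitude != 0 else None
        beats.append(beat)
        r_times.append(beat["r_peak_s"])
        if beat["p_peak_s"] is not None:
            p_times.append(beat["p_peak_s"])

    if m.p_amplitude != 0:
        for p_peak in extra_p:
            c = p_peak * 1000.0
            s = _sigma(m.p_width)
            lo = np.searchsorted(t_ms, c - 8 * s)
            hi = np.searchsorted(t_ms, c + 8 * s)
            clean[lo:hi] += m.p_amplitude * np.exp(
                -0.5 * ((t_ms[lo:hi] - c) / s) ** 2
            )
            p_times.append(p_peak)
    p_times.sort()

    data = np.empty((n, config.n_channels))
    t_s = t_ms / 1000.0
    for k, (gain, pol) in enumerate(zip(config.probe_gains, config.probe_polarity)):
        ch = pol * gain * clean
        ns = config.noise
        if ns.powerline_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            ch = ch + ns.powerline_amplitude * np.sin(
                2 * np.pi * ns.powerline_hz * t_s + phase
            )
        if ns.wander_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            ch = ch + ns.wander_amplitude * np.sin(
                2 * np.pi * ns.wander_hz * t_s + phase
            )
        if ns.white_sd > 0:
            ch = ch + rng.normal(0.0, ns.white_sd, n)
        data[:, k] = ch

    names = [f"probe{k + 1}" for k in range(config.n_channels)]
    trace = Trace(
        data=data,
        channel_names=names,
        fs_hz=fs,
        meta={
            "source": "zfecg.simulate",
            "seed": config.seed,
            "rhythm": config.rhythm.kind,
        },
    )
    truth = GroundTruth(
        beats=beats,
        r_times=r_times,
        p_times=p_times,
        rhythm=config.rhythm.kind,
        pauses=pauses,
        pr_ms=list(pr_list),
    )
    return trace, truth


# --------------------------------------------------------------------------
# presets
#
# Morphology timing parameters encode the reported in-vivo group means for
# adult zebrafish (wild type: HR 118 bpm, PR 63.5 ms, QRS 35.0 ms, QT 282 ms;
# breakdance long-QT mutant: HR 87.4 bpm, QT 414 ms).  Amplitudes and widths
# are conventions — the source recordings publish no absolute voltages — and
# are documented in docs/methods.md.


def _wildtype() -> SimConfig:
    return SimConfig(
        morphology=BeatMorphology(),
        rhythm=RhythmScript(kind="normal", hr_bpm=118.0, rr_jitter_sd=5.0),
    )


def _bre_longqt() -> SimConfig:
    return SimConfig(
        morphology=BeatMorphology(t_amplitude=0.25, t_width=150.0, qt_ms=414.0),
        rhythm=RhythmScript(kind="normal", hr_bpm=87.4, rr_jitter_sd=5.0),
    )


def _hyperkalemia_early() -> SimConfig:
    # lengthening PR, widened P wave, prolonged QRS, tall T
    return SimConfig(
        morphology=BeatMorphology(
            p_amplitude=0.12,
            p_width=50.0,
            r_width=30.0,
            s_width=20.0,
            t_amplitude=0.6,
            t_width=100.0,
            pr_ms=80.0,
            qrs_ms=55.0,
            qt_ms=300.0,
        ),
        rhythm=RhythmScript(kind="normal", hr_bpm=110.0, rr_jitter_sd=8.0),
    )


def _hyperkalemia_severe() -> SimConfig:
    # loss of P wave, widened QRS complex, peaked (tall) T wave
    return SimConfig(
        morphology=BeatMorphology(
            p_amplitude=0.0,
            r_amplitude=0.8,
            r_width=36.0,
            s_width=24.0,
            t_amplitude=0.8,
            t_width=100.0,
            pr_ms=80.0,
            qrs_ms=70.0,
            qt_ms=320.0,
        ),
        rhythm=RhythmScript(kind="normal", hr_bpm=100.0, rr_jitter_sd=10.0),
    )


def _avb_2to1() -> SimConfig:
    # 2:1 second-degree AV block: atrial rate 120/min, ventricular 60/min
    return SimConfig(
        morphology=BeatMorphology(),
        rhythm=RhythmScript(kind="avb_2to1", hr_bpm=60.0, rr_jitter_sd=2.0),
    )


def _mobitz_like() -> SimConfig:
    return SimConfig(
        morphology=BeatMorphology(),
        rhythm=RhythmScript(
            kind="mobitz_like",
            hr_bpm=120.0,
            rr_jitter_sd=2.0,
            pr_sequence=[60.0, 85.0, 110.0],
            asystole_after_beats=3,
            asystole_rr_multiple=2.5,
        ),
    )


def _injury_acute() -> SimConfig:
    # acute ventricular injury: ST depression, inverted T, prolonged QRS,
    # shortened PR
    return SimConfig(
        morphology=BeatMorphology(
            t_amplitude=-0.2,
            st_offset=-0.15,
            pr_ms=55.0,
            qrs_ms=45.0,
            qt_ms=280.0,
        ),
        rhythm=RhythmScript(kind="normal", hr_bpm=115.0, rr_jitter_sd=6.0),
    )


_PRESETS = {
    "wildtype": _wildtype,
    "bre_longqt": _bre_longqt,
    "hyperkalemia_early": _hyperkalemia_early,
    "hyperkalemia_severe": _hyperkalemia_severe,
    "avb_2to1": _avb_2to1,
    "mobitz_like": _mobitz_like,
    "injury_acute": _injury_acute,
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> SimConfig:
    """Return a fresh :class:`SimConfig` for a named condition.

    Valid names: wildtype, bre_longqt, hyperkalemia_early,
    hyperkalemia_severe, avb_2to1, mobitz_like, injury_acute.
    """
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: "
            + ", ".join(PRESET_NAMES)
        ) from None
    return builder()
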