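# Methods

## Signal model

A beat is modelled as a sum of smooth unimodal kernels, one per wave:

    s(t) = Σ_w a_w · exp(−(t − c_w)² / 2σ_w²),  w ∈ {P, R, S, T}

with an optional flat-topped (super-Gaussian, exponent 4) ST plateau between
the S and T waves for injury phenotypes.  Zebrafish ECG lacks a Q wave and
an identifiable J point, so neither is modelled, and the interval
definitions avoid both: PR = P upstroke → R upstroke, QRS = R upstroke →
S nadir, QT = R upstroke → T end, QTc = QT/√RR (Bazett, RR in seconds).

"Upstroke" and "T end" are operationalized as the 10 %-of-peak amplitude
crossing on the rising (P, R) or trailing (T) side.  Manual on-screen
measurement cannot be reproduced algorithmically, and a fixed fractional
threshold is the standard automatic surrogate; 10 % is low enough to sit on
the steep part of each deflection yet above realistic residual noise.  Wave
widths are parameterized as the full width at 10 % amplitude (FW10 =
2√(2 ln 10)·σ ≈ 4.29 σ), so a wave's configured width *is* the span between
its delineated onset and end.  Component centres are placed so that the
analytic landmarks reproduce the configured PR/QRS/QT exactly:

    R centre = R upstroke + r_width/2
    S centre = R upstroke + QRS          (the S nadir is the S centre)
    P centre = R upstroke − PR + p_width/2
    T centre = R upstroke + QT − t_width/2

The simulator and delineator share these definitions deliberately: on a
noiseless recording the pipeline recovers every interval to within one
sample period, which pins down the measurement conventions end to end.

## Simulated conditions

Preset timing parameters encode in-vivo group means for adult zebrafish:
wild type HR 118 bpm, PR 63.5 ms, QRS 35.0 ms, QT 282 ms; the *breakdance*
(erg) long-QT mutant HR 87.4 bpm, QT 414 ms with otherwise wild-type PR and
QRS.  Hyperkalemia presets are static morphologies — widened P and QRS with
tall T (early), lost P with widened QRS and peaked T (severe); the acute
injury preset has ST depression, inverted T, prolonged QRS and shortened PR.
Rhythm scripts: normal sinus rhythm with Gaussian RR jitter; fixed-ratio
2:1 AV block (two P waves per conducted QRS at a regular PP of RR/2); and a
Wenckebach-like pattern with strictly increasing PR over 3–4 beats followed
by an asystolic pause, drawn as 2.5 × RR by default (the midpoint of the
2–3 RR range that characterizes these pauses).

No absolute voltages are published for this preparation, so all amplitudes
are conventions: R 1.0 mV, S −0.4 mV, T 0.3 mV, P 0.15 mV on the anterior
probe.  Wave widths (P 30 ms, R 28 ms, S 20 ms, T 120–150 ms FW10) were
chosen to look physiological *and* to keep each wave's energy essentially
inside the 3–40 Hz analysis band: a much narrower R or S is visibly blunted
by the 40 Hz edge and its measured onset/nadir shifts by several
milliseconds, which would make the filtering stage — not the biology — the
dominant error source.

Probe geometry is a per-channel gain and sign applied to one underlying
cardiac signal: gains [1, 2] encode the ≈2× amplitude of the posterior
chest probe (the ventricular vector points posterior); polarity −1 encodes
the negative-going dorsal montage.  Noise terms per channel, each with an
independent random realization: 50 Hz mains (0.2 mV), 0.5 Hz sinusoidal
baseline wander (0.4 mV), and white noise with SD 0.1 mV — i.e. R-wave
SNR 10 on the anterior probe, a deliberately conservative level.

The generator does **not** emulate: electrode-contact artifacts, movement
transients, beat-to-beat morphology variability (e.g. respiratory
modulation), HRV structure beyond white RR jitter, the within-recording
progression of hyperkalemia, or drift of electrode impedance.  Passing
tests therefore demonstrate correctness of the measurement definitions and
robustness to stationary additive noise — not performance on artifacts a
live recording can produce.

## Filtering and the sub-band problem

The band-pass is a zero-phase (forward–backward) Butterworth, 3–40 Hz.
Zero phase is essential: every downstream quantity is a time measurement.
The design order is 12 per edge; with the forward–backward pass this holds
a full-scale 50 Hz tone below 0.3 % of its input RMS at 2 kHz sampling, so
mains interference as large as the R wave moves no fiducial by more than a
fraction of a sample.  A separate 50 Hz notch exists but is off by default;
the 40 Hz edge already covers mains.

A subtlety dominates accuracy here: the zebrafish heart rate (~1.5–2 Hz)
lies *below* the 3 Hz high-pass edge, so filtering a quasi-periodic beat
train removes the fundamental (and for slow hearts the second harmonic) of
the beat spectrum.  On the ensemble average this appears as a smooth
oscillation at the beat frequency that shifts threshold crossings by many
milliseconds — up to tens of ms for the QT of a long-QT beat.  The pipeline
therefore restores the sub-band exactly: the measurement signal is
`bandpass(x) + (HP₀.₈(x) − HP₃(x))`, where HP_f is the same-order zero-phase
high-pass at edge f.  The restored band (0.8–3 Hz) carries the heart-rate
harmonics; 50 Hz remains rejected (the restore path's transfer there is
~0), and 0.5 Hz wander remains rejected by the 0.8 Hz lower edge.  Beat
*detection* and template matching always run on the plain band-passed
signal.

The delineator additionally carries its own defence for averages that were
not sub-band restored: it fits `c + Σ_k a_k cos(2πkt/RR) + b_k sin(·)` over
the isoelectric samples (harmonics below 3.5 Hz only, ridge-regularized,
with a fallback to a constant when the fit would extrapolate far beyond the
isoelectric evidence) and subtracts it before measuring.  In the standard
pipeline, where restoration has already happened, the harmonic terms are
disabled and a constant baseline is used — the extra degrees of freedom
would only add extrapolation noise.

## Detection and measurement choices

- **R detection**: local maxima of the dominant-polarity signal above
  0.5 × a robust peak-amplitude estimate (median height of the prominent
  maxima), 200 ms refractory period (a ~300 bpm ceiling, far above
  zebrafish rates).  A sharpness veto drops candidates whose local slope is
  below 45 % of the 75th-percentile candidate slope: the R deflection is
  the narrowest wave, and this keeps peaked hyperkalemic T waves — which
  can rival the R in amplitude — out of the R series.  Polarity is
  estimated from the dominant deflection unless fixed.
- **Template search**: normalized (Pearson) cross-correlation at every lag,
  FFT-accelerated with running-sum normalization; acceptance threshold 0.8;
  overlap resolved greedily by descending correlation; each accepted window
  re-cut so its maximum deflection sits at the template's R index, and its
  correlation recomputed (and re-thresholded) at the final lag.  The
  automatic template is the candidate beat maximizing mean correlation with
  all other candidates.  The template window adapts to the measured RR
  (1.1 × RR, clipped to 500–800 ms): slightly more than one cycle, so even
  a long-QT beat retains an isoelectric tail for baseline anchoring.
- **Delineation**: R peak searched within ±40 ms of the alignment index
  (the average is R-aligned by construction); S nadir = minimum within
  100 ms after the R peak; P = most prominent bump within 150 ms before the
  R onset; T = most prominent bump of either sign in (S+20 ms, S+400 ms],
  measured on a 25 ms quadratic Savitzky–Golay smoothing (noise suppression
  with negligible bias on a smooth curve); ST deviation = mean level over
  (S+10 ms, S+40 ms) minus baseline, a fixed window because no J point
  exists.  The search spans cover QRS up to ~80 ms and QT up to ~450 ms,
  i.e. every phenotype modelled here.  A wave is reported *absent* (never
  zero) when its amplitude is below 3 × the residual-noise SD or below 2 %
  of the R amplitude; residual noise is the larger of a first-difference
  MAD estimate and the dispersion envelope /√n.  Landmark crossings are
  sub-sample linear interpolations; three mask → baseline-fit → re-delineate
  passes are run.
- **P detection on traces** (for rhythm counting): P-width Gaussian matched
  smoothing, running-median detrend (120 ms), prominence-tested peaks
  (floor: 8 % of the R amplitude or 6 × broadband noise) with a width gate
  of 5–45 ms at half prominence (a T wave is wider), outside a blanking
  window from 40 ms before each R through the T wave (min(400 ms, 0.75 RR)
  after the R), and clear of the first/last 250 ms (zero-phase edge
  transients).  The pre-R blank is 40 ms, not symmetric: the R upstroke is
  only ~10–25 ms before the peak while the zebrafish P peak sits ~55–60 ms
  before it.
- **Rhythm rules** (tolerance bands configurable and logged): 2:1 AV block
  when the P:QRS count ratio is in [1.8, 2.2] with regular PP (robust,
  MAD-based CV < 0.1) and no pauses; Wenckebach-like when ≥ 2 pauses of
  2–3 × baseline RR separate groups with strictly increasing PR and
  post-pause PR < pre-pause PR (≥ 80 % of groups must conform, which
  tolerates a single noisy PR without changing the label); normal when the
  ratio is in [0.9, 1.1] with regular PR and no pauses; otherwise
  unclassified.
- **Cardiac vector**: per-channel signed, baseline-referenced R amplitudes
  from the two probes' averaged beats; the ratio |probe 2|/|probe 1| is
  magnitude-based so a negative-going R (dorsal montage or post-injury
  vector shift) keeps its sign information in the polarity field without
  flipping the ratio.
- **QT–RR**: ordinary least squares of QT (ms) on RR (s) across recordings,
  with Pearson r; refused for n < 3 or zero RR variance.

## Verification strategy and problem sizes

Every stage is tested against an independent oracle: the sliding
correlation against a direct per-lag computation (agreement to 1e-9); the
filter against its designed frequency response; R detection against
windowed argmax inside ground-truth beat windows; template choice against
brute-force pairwise correlation ranking; averaging against the 1/√n law
(500 replicates at n = 4, 16, 64); baseline estimation against a
1000-draw Monte Carlo; QT–RR against 200-cohort parameter recovery.
Round-trip accuracy is characterized on 30-s recordings, 100 seeds per
preset, at the default noise level: all defined intervals recover within
±5 ms (typical bias < 1 ms, SD ≈ 0.3–1.3 ms; the shallow long-QT T end is
the widest case).  Headline round trips use 60-s recordings, the duration
the recording protocol itself uses; rhythm classification is exercised on
30-s recordings, 20 seeds per class, with zero confusion.  These sizes keep
the full suite in the low minutes on one CPU while leaving each check
comfortably powered.

## Known limitations

- The 10 %-crossing operationalization of "upstroke"/"T end" is one of
  several defensible conventions (tangent methods are another); absolute
  interval values shift by a few ms across conventions, which is within the
  between-laboratory spread this field reports.
- Measured QRS carries a small positive bias (≈ +0.7 ms) from residual
  band-edge smearing of the S trough; PR a small negative one for wide-P
  phenotypes.  Both are an order of magnitude below the recovery
  tolerances.
- The rhythm classifier covers only the patterns modelled here; ectopy,
  escape rhythms and fibrillation are out of scope.
- ST deviation is reported with the sign of the analysed channel; on an
  inverted-polarity montage it reflects the recorded, not the anatomical,
  direction.
- Vendor formats (ABF) and biosignal standards (WFDB) are not bundled;
  `zfecg.io.register_reader` is the adapter hook, and the delimited-text
  dialect is the canonical interchange format.
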