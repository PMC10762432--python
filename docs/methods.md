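# Methods

This note documents the models, parameters and numerical choices behind
`earbeat`, and what the synthetic experiments do and do not demonstrate.

## Cardiac source model

The cardiac source is a single equivalent current dipole **p**(t) =
(px, py, pz) in mA·m, defined on one 600 ms cycle sampled on the
half-open axis [−200, +400) ms around the R maximum, so that the cycle
holds exactly T = 0.6·fs samples (300 at the canonical 500 Hz). Each
component is a sum of five Gaussian bumps, one per PQRST wave, with
per-wave amplitude vector, centre and width. Default centres are
P = −160 ms, Q = −25 ms, R = 0, S = +25 ms, T = +220 ms with widths
22/9/11/9/40 ms and Lead-I amplitude ratios R:T:P ≈ 10:3:1 — a plausible
Lead-I morphology chosen once as a fixture, not a fit to any recording.
The R centre is pinned to 0 by construction and the Lead-I projection's
maximum verifiably falls at t = 0 within one sample.

The transverse components (py, pz) are kept small (≈3–6% of px per
wave). This is deliberate: the analytic forward model below gives the
vertical electrode pairs lead vectors whose y/z entries are up to 3×
their x entry, so a heart vector with large transverse components would
flip or decorrelate the head channels. A dominantly Lead-I-aligned dipole
with per-wave direction jitter preserves the two field facts the
generator must emulate — high positive correlation of all channels with
Lead I, and amplitude attenuation neck > ear > scalp with
cross-ear > single-ear — while still giving each channel slightly
different relative wave amplitudes (a few percent), as real sites show.

Beat times follow an i.i.d. truncated-normal RR model (truncation at
0.35 s, which also guarantees two R maxima can never fall in one 600 ms
window). No RR autocorrelation, respiratory modulation, ectopic beats or
pathological morphologies are modelled. Rendering tiles the projected
cycle at the beat times (overlap resolved by summation — physically,
superposition) and is exactly linear in the source.

Per-channel noise is additive and seeded: Gaussian broadband background,
a 50 Hz mains sinusoid with random phase, slow two-tone baseline wander
(default 0.25 Hz), and Poisson-scheduled 200 ms Hann-windowed EMG-like
bursts. Default levels grade the sites the way the hardware does: a
clean but mains-coupled wrist reference (broadband 0.02 mV), moderate
ear/neck noise, and the heaviest background on the scalp (0.03 mV
broadband, 8 bursts/min) where EEG and temporal-muscle EMG dominate.
Channels draw from independent child streams spawned in channel order,
so identical seeds give bit-identical recordings.

## Forward model

Volume conduction is approximated by a point dipole in an infinite
homogeneous medium: φ = **p**·**r**/(4πσ|**r**|³), with positions in mm,
moments in mA·m, σ in S/m (default 0.2) and potentials in mV; units are
converted once at this boundary. A channel's lead vector is the
difference of the point lead function at its two terminals, so terminal
swap negates the trace, superposition is exact, and doubling all
electrode distances scales every channel by 1/4.

The default geometry is a desk-scale fixture, not an anatomical
reconstruction: dipole at the origin, the left-ear cluster ~350 mm above
and ~100 mm posterior, wrists ±450 mm laterally. Within the left
scalp/ear/neck column all electrodes share one lateral and anterior
coordinate (the channels are vertically aligned); with helix–concha
separation L = 25 mm, scalp electrodes sit at helix + L/2 and
helix + 3L/2 and neck electrodes at concha − L/2 and concha − 3L/2. This
ordering of electrode–dipole distances (neck < ear < scalp) produces the
attenuation ordering through the dipole's 1/r² falloff alone. What the
homogeneous medium does *not* capture is tissue-resolved conduction —
notably the neck's impedance bottleneck — so the absolute simulated
amplitudes are not comparable to measured microvolt values and are never
treated as targets.

## Extraction chain

Filtering follows the acquisition protocol: third-order Butterworth
band-passes, 0.5–30 Hz for head/ear channels and 0.5–95 Hz for the
reference, plus a second-order IIR notch at 50 Hz with 5 Hz bandwidth
(Q = 10) on the reference. One source documents the reference low edge
as 0.5 Hz and another as 1 Hz; 0.5 Hz is adopted. All filters run
forward–backward (zero phase, effective order doubled) because the
pipeline compares wave *timings* across channels and causal group delay
would bias them. Downsampling (1200 → 300 Hz for the driving-style
experiment) is polyphase FIR resampling and by default precedes
filtering; a flag provides the reverse order. The first and last second
of each recording are excluded from beat selection against filter
transients.

R-peak detection is classic Pan–Tompkins on the filtered reference only:
5–15 Hz bandpass, derivative, squaring, 150 ms moving-window
integration, adaptive dual thresholds with signal/noise level tracking
(trained on the first 2 s), a 200 ms refractory period, and search-back
at 1.66× the running RR mean. Detections are then refined to the local
maximum of the filtered reference within ±50 ms (ties → earliest
sample); refinement is on by default and switchable.

Windows span [k − 0.2·fs, k + 0.4·fs) around each R sample k; incomplete
windows at the record edges are dropped. A median rhythm of ensemble
size N is the per-sample median of N consecutive windows (even N: mean
of the central pair); sliding one beat at a time, n rhythms yield n − N
medians — the counting convention is adopted from the protocol's own
worked example (100 rhythms, N = 2 → 98 medians), which fixes the slide
to one beat. The grand-median pools all windows. No beat-quality
rejection is applied before ensembling.

Delineation takes the R wave as the largest-magnitude extremum within
±40 ms of the window origin; its sign sets the polarity (ear channels
may invert; all downstream metrics are polarity-robust). Q and S are the
opposite-polarity extrema within 80 ms before/after R; P is the
same-polarity extremum in [−200, c_Q − 20] ms and T in [c_S + 40, +400) ms.
All window constants are overridable. A wave whose search interval is
empty is reported missing and excluded from the metrics with the divisor
reduced and the result flagged. Note that where waves overlap (Q and S
on the flanks of R), the extremum of the *summed* trace is displaced by
a few ms from the injected Gaussian centre; the delineator reports the
trace extremum, which is the only observable quantity.

## Metrics and aggregation

The amplitude-ratio metric is computed as the RMS of the four
R-normalized per-wave ratios, war = √(¼ Σⱼ ((aⱼ b_R)/(bⱼ a_R))²) — the
form whose self-comparison optimum is exactly 1. The timing metric
δwt = √(¼ Σⱼ ((cⱼ−c_R) − (dⱼ−d_R))²) uses peak timings only (no
onsets/offsets). Normalized variance pools squared errors over all
windows and samples under a single square root before dividing by the
grand-median's standard deviation; a per-window-RMSE variant is
available behind a flag (the two agree for i.i.d. noise). δnv compares
raw beat windows to the same channel's grand-median and is therefore
independent of N.

Reports aggregate in the order: mean over all sliding medians within a
subject, then mean over subjects, per channel and ensemble size.

## Synthetic experiments

"Subjects" are seeded parameter draws around the defaults: heart rate
uniform in 55–85 bpm, RR sd 5% of the mean, per-channel gain jitter
±20%, noise-level jitter ±30%. This emulates inter-subject variability
in the metric-vs-N curves without claiming to reproduce any cohort's
numbers: measured values from real recordings depend on electrode-skin
contact, motion and individual anatomy that the generator does not
model. What the passing experiments demonstrate is structural: the
median's convergence with N, the monotone quality ordering induced by
channel gain at fixed noise, and the detector's fidelity at realistic
SNR. Problem sizes used in the validation suite — 10-minute subjects for
the convergence experiment (~600–700 beats, covering the full N grid up
to 540) and five 6-minute subjects for the ordering experiment at
N = 240 — were chosen as the smallest runs that exercise every ensemble
size with a comfortable margin of beats.

For controlled attenuation studies the pipeline can replace the
geometric lead field by Lead-I-aligned vectors of prescribed magnitudes
(e.g. 4:2:1 for neck:ear:scalp) with one shared noise level; because all
clean traces are then exactly proportional, any metric separation is
attributable to gain alone.

## Numerical and degenerate-input conventions

- Ties in any extremum search resolve to the earliest sample.
- A zero-variance trace yields an empty peak set (detection) or an
  undefined-correlation error (metrics); a constant grand-median makes
  δnv undefined.
- Even-N medians are the mean of the two central order statistics.
- CSV I/O is full-precision and round-trips exactly; the WFDB-style
  writer (text header + int16 samples, format 16) is lossy only at the
  quantization step of 1/gain mV, with per-channel gain 30000/peak.
- Seeds: every stochastic component takes an explicit integer seed;
  derived seeds are drawn below 2³¹.

## Known limitations

- The homogeneous-medium forward model reproduces orderings, not
  absolute amplitudes; no tissue conductivities, anisotropy or bounded
  torso.
- Single-dipole source; multi-source cardiac models are out of scope.
- The delineation search windows are a re-specification bracketing
  physiological intervals; equivalence with any particular published
  peak-extraction implementation is not claimed.
- The RR model has no autocorrelation; ensemble-size results for
  strongly non-stationary rhythms (e.g. atrial fibrillation) are outside
  the generator's envelope.
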