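# earbeat

Feasibility analysis of ECG recorded from ear-worn ("hearable") electrodes.

Biopotential channels placed on the concha and helix of the ear — or on the
nearby scalp and neck — pick up a strongly attenuated projection of the
cardiac electrical source. `earbeat` provides a tested pipeline to answer
the question a wearable-ECG designer actually has: *how much ensemble
averaging does each electrode site need before its cardiac waveform is
equivalent to a Lead-I reference?*

The package contains:

- a **synthetic-data generator**: a single equivalent current dipole
  ("heart vector") **p**(t) whose three orthogonal components are
  superpositions of five Gaussian bumps (the P, Q, R, S, T waves) over a
  600 ms cycle, rendered into multichannel recordings with beat-to-beat RR
  variability and channel-specific noise (broadband background, 50 Hz
  mains, baseline wander, EMG-like bursts);
- an **analytic volume-conduction forward model**: electrode lead vectors
  ℓ in an infinite homogeneous medium, φ = **p**·**r**/(4πσ|**r**|³), so a
  channel's trace is ℓ·**p**(t) and the characteristic attenuation
  ordering neck > ear > scalp (and cross-ear > single-ear) emerges from
  electrode-dipole geometry;
- the **extraction chain**: zero-phase Butterworth band-passes (0.5–30 Hz
  head/ear, 0.5–95 Hz reference) and a 50 Hz notch; Pan–Tompkins R-peak
  detection on the wrist (Lead-I equivalent) reference; 600 ms beat
  windows (−200 ms to +400 ms around each R peak); sliding per-sample
  **median cardiac rhythms** at ensemble sizes
  N = 2, 8, 16, 32, 64, 120, 180, 240, 300, 420, 540 (n beats give
  n − N medians); PQRST peak delineation;
- four **similarity metrics** of a channel against the reference
  grand-median (the median over all available beats):

  - Pearson correlation r of the two traces (optimum 1),
  - wave amplitude ratio, the RMS of R-normalized per-wave amplitude
    ratios: war = √(¼ Σⱼ ((aⱼ·b_R)/(bⱼ·a_R))²), j ∈ {P, Q, S, T}
    (optimum 1),
  - wave timing error δwt = √(¼ Σⱼ ((cⱼ−c_R) − (dⱼ−d_R))²) in ms
    (optimum 0),
  - normalized variance δnv, the RMSE between all individual beat windows
    and the channel grand-median divided by the grand-median's standard
    deviation (optimum 0).

## Worked example

Score all four Experiment-style channels of one seeded 10-minute
synthetic subject across the full ensemble-size grid:

```python
import earbeat as eb
from earbeat.pipeline import ExperimentPlan, run_algorithm1, synthesize_subject

plan = ExperimentPlan(channels=["wrist", "scalp", "ear", "neck"],
                      duration_s=600.0, base_seed=7)
rec = synthesize_subject(plan, plan.subject_seeds()[0])
report = run_algorithm1(rec, plan)
print(report[report.N == 240][["channel", "N", "r", "war", "dwt_ms", "dnv"]]
      .round(3).to_string(index=False))
```

prints

```
channel   N     r   war  dwt_ms   dnv
  wrist 240 1.000 1.002   0.863 0.049
  scalp 240 0.983 1.262   5.589 1.902
    ear 240 0.991 1.226   5.639 1.048
   neck 240 0.995 1.014   3.857 0.480
```

The wrist reference scored against itself sits at the metric optima; at
ensemble size N = 240 the neck channel is closest to Lead-I quality, the
ear follows, and the noisy low-amplitude scalp channel trails — with its
correlation climbing from ≈0.60 at N = 2 to ≈0.99 at N = 540 as the
median suppresses noise. `dnv` is N-independent (it compares raw beat
windows to the grand-median) and grades the channels' raw noise burden.

The same chain is scriptable from the shell:

```bash
earbeat synth --out rec.csv --seed 17        # synthetic 4-channel recording
earbeat detect rec.csv --channel wrist --out rpeaks.csv
earbeat rhythms rec.csv --rpeaks rpeaks.csv --channel ear -N 240 --out medians.csv
earbeat delineate medians.csv --out waves.csv
earbeat run-expa --subjects 5 --out results/expa   # full experiment + plots
```

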