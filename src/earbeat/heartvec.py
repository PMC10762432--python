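"""Parametric heart-vector source and seeded multichannel recording synthesis.

The cardiac source is modelled as a single equivalent current dipole whose
three orthogonal moment components (px: left-right, py: front-back,
pz: below-above, in mA.m) evolve over one 600 ms cardiac cycle spanning
-200 ms to +400 ms around the R maximum. Each component is a superposition
of five Gaussian bumps, one per PQRST wave. Rendering a recording places
the projected cycle at beat times drawn from a truncated-normal RR model
and adds channel-specific noise: broadband Gaussian background, 50 Hz
powerline, slow baseline wander and intermittent EMG-like bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, ParameterError
from .io import Recording

__all__ = [
    "WAVES",
    "GaussianWaveParams",
    "HeartVector",
    "BeatSchedule",
    "ChannelNoise",
    "NoiseSpec",
    "synth_heart_vector",
    "synth_beat_schedule",
    "render_recording",
]

WAVES = ("P", "Q", "R", "S", "T")

#: RR floor (s): consecutive 600 ms windows cannot contain two R maxima.
RR_FLOOR = 0.35

#: Sampling rates accepted for rendered recordings (Hz).
RENDER_RATES = (300.0, 500.0, 1200.0)


@dataclass
class GaussianWaveParams:
    """Five-Gaussian-per-component parametrization of the heart vector.

    ``amplitudes[k]`` is the (x, y, z) moment amplitude of wave k in mA.m,
    ``centers_ms[k]`` its centre on the cycle axis (R fixed at 0 ms) and
    ``widths_ms[k]`` its Gaussian sigma in ms. Defaults give the rendered
    Lead-I projection a canonical morphology (P ~ -160 ms, Q ~ -25 ms,
    R = 0, S ~ +25 ms, T ~ +220 ms; R:T:P amplitudes ~ 10:3:1); they are
    fixture constants, not measurements.
    """

    amplitudes: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "P": (0.035, 0.002, -0.001),
            "Q": (-0.050, -0.004, 0.002),
            "R": (0.350, 0.020, -0.010),
            "S": (-0.070, -0.006, 0.003),
            "T": (0.105, 0.010, -0.005),
        }
    )
    centers_ms: dict[str, float] = field(
        default_factory=lambda: {"P": -160.0, "Q": -25.0, "R": 0.0, "S": 25.0, "T": 220.0}
    )
    widths_ms: dict[str, float] = field(
        default_factory=lambda: {"P": 22.0, "Q": 9.0, "R": 11.0, "S": 9.0, "T": 40.0}
    )

    def validate(self) -> None:
        for k in WAVES:
            if k not in self.amplitudes or k not in self.centers_ms or k not in self.widths_ms:
                raise ParameterError(f"missing parameters for wave {k}")
            if self.widths_ms[k] <= 0:
                raise ParameterError(f"width of wave {k} must be positive")
        c = [self.centers_ms[k] for k in WAVES]
        if not all(a < b for a, b in zip(c, c[1:])):
            raise ParameterError(f"wave centres must be strictly ordered P<Q<R<S<T, got {c}")
        if self.centers_ms["R"] != 0.0:
            raise ParameterError("the R centre defines the cycle origin and must be 0 ms")

    @classmethod
    def from_config(cls, section: dict) -> "GaussianWaveParams":
        return cls(
            amplitudes={k: tuple(v["amplitude"]) for k, v in section.items()},
            centers_ms={k: float(v["center_ms"]) for k, v in section.items()},
            widths_ms={k: float(v["width_ms"]) for k, v in section.items()},
        )


@dataclass
class HeartVector:
    """One sampled 600 ms heart-vector cycle.

    ``t`` is the time axis in ms, spanning the half-open interval
    [-200, +400) so that T = 0.6 * fs samples exactly; ``p`` is the
    3 x T dipole-moment matrix (mA.m), rows px, py, pz.
    """

    fs: float
    t: np.ndarray
    p: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.p.shape[1]

    @property
    def r_index(self) -> int:
        """Sample index of t = 0 (the R maximum)."""
        return int(round(0.2 * self.fs))


def cycle_axis(fs: float) -> np.ndarray:
    """Canonical cycle time axis in ms: [-200, +400), step 1000/fs."""
    n = round(0.6 * fs)
    return (np.arange(n) - round(0.2 * fs)) * 1000.0 / fs


def synth_heart_vector(params: GaussianWaveParams | None = None, fs: float = 500.0) -> HeartVector:
    """Evaluate the five-Gaussian heart-vector model on the canonical axis.

    Deterministic: no randomness is involved. Raises
    :class:`ParameterError` for unordered centres or non-positive widths,
    or fs < 250 Hz (below which the QRS bumps are undersampled).
    """
    params = params or GaussianWaveParams()
    params.validate()
    if fs < 250:
        raise ParameterError(f"fs = {fs} Hz too low; need >= 250 Hz")
    t = cycle_axis(fs)
    p = np.zeros((3, t.size))
    for k in WAVES:
        amp = np.asarray(params.amplitudes[k], dtype=float)
        bump = np.exp(-((t - params.centers_ms[k]) ** 2) / (2.0 * params.widths_ms[k] ** 2))
        p += amp[:, None] * bump[None, :]
    return HeartVector(fs=float(fs), t=t, p=p)


@dataclass
class BeatSchedule:
    """R-maximum onset times (s) with the RR model that generated them."""

    beat_times: np.ndarray
    rr_mean: float
    rr_sd: float
    seed: int

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= RR_FLOOR):
            raise ParameterError(f"RR intervals must exceed {RR_FLOOR} s")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


def synth_beat_schedule(rr_mean: float, rr_sd: float, duration: float, seed: int = 0) -> BeatSchedule:
    """Draw a beat schedule with i.i.d. truncated-normal RR intervals.

    RR ~ Normal(rr_mean, rr_sd) truncated below at 0.35 s (rejection
    sampling, so rr_sd = 0 degenerates to a perfectly regular rhythm).
    The first beat is at t = 0; beats strictly before ``duration`` are kept.
    Reproducible: identical arguments give identical schedules.
    """
    if rr_mean <= 0.4:
        raise ParameterError("rr_mean must exceed 0.4 s")
    if rr_sd < 0:
        raise ParameterError("rr_sd must be non-negative")
    if duration <= rr_mean:
        raise ParameterError("duration too short for more than one beat")
    rng = np.random.default_rng(seed)
    times = [0.0]
    while True:
        rr = rr_mean if rr_sd == 0 else float(rng.normal(rr_mean, rr_sd))
        while rr <= RR_FLOOR:
            rr = float(rng.normal(rr_mean, rr_sd))
        if times[-1] + rr >= duration:
            break
        times.append(times[-1] + rr)
    return BeatSchedule(beat_times=np.array(times), rr_mean=rr_mean, rr_sd=rr_sd, seed=seed)


@dataclass
class ChannelNoise:
    """Additive noise mix for one channel (amplitudes in mV)."""

    broadband_sd: float = 0.02
    powerline_amp: float = 0.01
    baseline_amp: float = 0.05
    baseline_freq: float = 0.25
    emg_burst_rate: float = 2.0  # bursts per minute
    emg_burst_sd: float = 0.05

    def validate(self) -> None:
        for name in ("broadband_sd", "powerline_amp", "baseline_amp",
                     "baseline_freq", "emg_burst_rate", "emg_burst_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"noise parameter {name} must be non-negative")


@dataclass
class NoiseSpec:
    """Per-channel noise parameters plus the master seed.

    Identical seed and parameters yield bit-identical noise; each channel
    draws from an independent child stream spawned in channel order.
    """

    channels: dict[str, ChannelNoise]
    seed: int = 0

    def validate(self) -> None:
        for noise in self.channels.values():
            noise.validate()

    @classmethod
    def silent(cls, channels, seed: int = 0) -> "NoiseSpec":
        return cls({ch: ChannelNoise(0.0, 0.0, 0.0, 0.0, 0.0, 0.0) for ch in channels}, seed)

    @classmethod
    def from_config(cls, section: dict, seed: int = 0) -> "NoiseSpec":
        chans = {
            name: ChannelNoise(
                broadband_sd=p["broadband_sd_mv"],
                powerline_amp=p["powerline_amp_mv"],
                baseline_amp=p["baseline_amp_mv"],
                baseline_freq=p["baseline_freq_hz"],
                emg_burst_rate=p["emg_burst_rate_per_min"],
                emg_burst_sd=p["emg_burst_sd_mv"],
            )
            for name, p in section["channels"].items()
        }
        return cls(chans, seed=seed)


def _channel_noise(noise: ChannelNoise, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    if noise.broadband_sd > 0:
        out += rng.normal(0.0, noise.broadband_sd, n)
    if noise.powerline_amp > 0:
        out += noise.powerline_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if noise.baseline_amp > 0 and noise.baseline_freq > 0:
        # two incommensurate slow tones emulate respiration-like wander
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        out += noise.baseline_amp * (
            np.sin(2 * np.pi * noise.baseline_freq * t + ph1)
            + 0.5 * np.sin(2 * np.pi * noise.baseline_freq * np.sqrt(2) * t + ph2)
        )
    if noise.emg_burst_rate > 0 and noise.emg_burst_sd > 0:
        n_bursts = rng.poisson(noise.emg_burst_rate * (n / fs) / 60.0)
        burst_len = int(round(0.2 * fs))
        envelope = np.hanning(burst_len)
        for _ in range(n_bursts):
            start = int(rng.integers(0, max(1, n - burst_len)))
            out[start : start + burst_len] += envelope[: n - start] * rng.normal(
                0.0, noise.emg_burst_sd, min(burst_len, n - start)
            )
    return out


def render_recording(
    hv: HeartVector,
    schedule: BeatSchedule,
    lead_field,
    noise: NoiseSpec,
    fs_out: float = 500.0,
    duration: float | None = None,
) -> Recording:
    """Project the heart vector through the lead field and tile it at beat times.

    Each channel is sum over beats of (lead vector . p)(t - beat_time) plus
    that channel's noise; overlap between consecutive beats is resolved by
    summation. Channel order follows ``noise.channels``. Output units mV,
    with the schedule's beat times carried as annotations.
    """
    if float(fs_out) not in RENDER_RATES:
        raise ParameterError(f"fs_out must be one of {RENDER_RATES}, got {fs_out}")
    noise.validate()
    missing = [ch for ch in noise.channels if ch not in lead_field.vectors]
    if missing:
        raise ConfigError(f"channels {missing} absent from the lead field")
    if duration is None:
        duration = float(schedule.beat_times[-1]) + 0.6
    channels = list(noise.channels)
    n = int(round(duration * fs_out))
    r_off = round(0.2 * fs_out)
    n_cycle = round(0.6 * fs_out)

    # per-channel clean cycle template on the output rate
    if fs_out == hv.fs:
        p_out = hv.p
    else:
        from fractions import Fraction

        frac = Fraction(int(round(fs_out)), int(round(hv.fs))).limit_denominator()
        p_out = sps.resample_poly(hv.p, frac.numerator, frac.denominator, axis=1)
        p_out = p_out[:, :n_cycle]

    data = np.zeros((len(channels), n))
    beat_idx = np.rint(schedule.beat_times * fs_out).astype(int)
    for ci, ch in enumerate(channels):
        template = lead_field.vectors[ch] @ p_out
        for k in beat_idx:
            start = k - r_off
            lo, hi = max(start, 0), min(start + n_cycle, n)
            if hi <= lo:
                continue
            data[ci, lo:hi] += template[lo - start : hi - start]

    seeds = np.random.SeedSequence(noise.seed).spawn(len(channels))
    for ci, ch in enumerate(channels):
        data[ci] += _channel_noise(noise.channels[ch], n, fs_out, np.random.default_rng(seeds[ci]))

    return Recording(fs=float(fs_out), channels=channels, data=data,
                     annotations=schedule.beat_times.copy())
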