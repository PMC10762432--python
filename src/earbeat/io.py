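"""Recording container, CSV / WFDB-style readers and writers, and config loading.

The on-disk CSV dialect is one header row ``time_s,<ch1>,<ch2>,...`` with
comma separators and '.' decimals; amplitudes are millivolts end-to-end.
The WFDB-style writer emits a plain-text ``.hea`` header plus a 16-bit
little-endian ``.dat`` signal file (format 16), the subset of the WFDB
record convention sufficient for interoperability round-trips.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "load_config",
    "DEFAULT_N_GRID",
]

#: Ensemble sizes over which median cardiac rhythms are evaluated.
DEFAULT_N_GRID = [2, 8, 16, 32, 64, 120, 180, 240, 300, 420, 540]


@dataclass
class Recording:
    """Multichannel, uniformly sampled biopotential recording.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Ordered, unique channel names.
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in millivolts.
    annotations : ndarray or None
        Optional ground-truth R-peak times in seconds, carried from
        synthesis for validation; not used by the detection stage.
    """

    fs: float
    channels: list[str]
    data: np.ndarray
    annotations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise FormatError("data must be a channels x samples matrix")
        if len(self.channels) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("channel names must be unique")
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's trace (a view) by name."""
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channels}") from None


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _write_csv(rec: Recording, path: Path) -> None:
    df = pd.DataFrame(rec.data.T, columns=rec.channels)
    df.insert(0, "time_s", rec.time)
    # full float precision so the round trip is exact
    df.to_csv(path, index=False, float_format="%.17g")
    if rec.annotations is not None:
        ann = path.with_suffix(".rpeaks.csv")
        pd.DataFrame({"r_time_s": rec.annotations}).to_csv(
            ann, index=False, float_format="%.17g"
        )


def _read_csv(path: Path) -> Recording:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: first column must be 'time_s'")
    if df.shape[0] < 2:
        raise FormatError(f"{path}: need at least two samples to infer fs")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged channels (missing values)")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
        raise FormatError(f"{path}: time axis is not uniformly increasing")
    fs = 1.0 / dt[0]
    # snap to an integer rate when within float-printing error
    if abs(fs - round(fs)) < 1e-6:
        fs = float(round(fs))
    channels = [c for c in df.columns if c != "time_s"]
    ann_path = path.with_suffix(".rpeaks.csv")
    annotations = None
    if ann_path.exists():
        annotations = pd.read_csv(ann_path)["r_time_s"].to_numpy()
    return Recording(fs=fs, channels=channels, data=df[channels].to_numpy().T,
                     annotations=annotations)


# ---------------------------------------------------------------------------
# Minimal WFDB-style record (format 16)
# ---------------------------------------------------------------------------

def _write_wfdb(rec: Recording, path: Path) -> None:
    record = path.with_suffix("")
    name = record.name
    n_sig, n_samp = rec.data.shape
    if n_samp == 0:
        raise FormatError("cannot write an empty recording")
    gains = []
    adc = np.empty((n_samp, n_sig), dtype="<i2")
    for i in range(n_sig):
        peak = float(np.max(np.abs(rec.data[i])))
        gain = 30000.0 / peak if peak > 0 else 200.0  # ADC units per mV
        gains.append(gain)
        adc[:, i] = np.clip(np.rint(rec.data[i] * gain), -32768, 32767).astype("<i2")
    # fs printed at full precision; WFDB headers allow fractional rates
    lines = [f"{name} {n_sig} {fs_repr(rec.fs)} {n_samp}"]
    for i, ch in enumerate(rec.channels):
        lines.append(f"{name}.dat 16 {gains[i]:.6f}(0)/mV 16 0 0 0 0 {ch}")
    record.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.tofile(record.with_suffix(".dat"))


def fs_repr(fs: float) -> str:
    return str(int(fs)) if float(fs).is_integer() else repr(fs)


def _read_wfdb(path: Path) -> Recording:
    record = path.with_suffix("")
    hea = record.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header {hea}")
    lines = [ln for ln in hea.read_text().splitlines() if ln and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: header line needs 'name n_sig fs n_samples'")
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    channels, gains = [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if parts[1] != "16":
            raise FormatError(f"{hea}: only format 16 is supported, got {parts[1]}")
        gains.append(float(parts[2].split("(")[0].split("/")[0]))
        channels.append(parts[-1])
    raw = np.fromfile(record.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise FormatError(f"{record}.dat: expected {n_sig * n_samp} samples, got {raw.size}")
    data = raw.reshape(n_samp, n_sig).T / np.asarray(gains)[:, None]
    return Recording(fs=fs, channels=channels, data=data)


def write_recording(rec: Recording, path: str | Path, format: str = "csv") -> Path:
    """Write a Recording to disk; returns the path written.

    ``format='csv'`` writes the full-precision CSV dialect (plus a
    ``.rpeaks.csv`` sidecar when annotations are present); ``format='wfdb'``
    writes a text ``.hea`` header and int16 ``.dat`` pair, lossy only at the
    16-bit quantization step.
    """
    path = Path(path)
    if rec.data.shape[0] == 0 or rec.data.shape[1] == 0:
        raise FormatError("cannot write an empty recording")
    if format == "csv":
        _write_csv(rec, path)
    elif format == "wfdb":
        _write_wfdb(rec, path)
    else:
        raise FormatError(f"unknown format {format!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a Recording written by :func:`write_recording`.

    The format is inferred from the extension (``.hea``/``.dat`` -> wfdb,
    otherwise csv) unless given explicitly.
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in {".hea", ".dat"} else "csv"
    if format == "csv":
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

def _default_wave(amps, centre, width):
    return {"amplitude": list(amps), "center_ms": centre, "width_ms": width}


def _default_noise_channel():
    return {
        "broadband_sd_mv": 0.02,
        "powerline_amp_mv": 0.01,
        "baseline_amp_mv": 0.05,
        "baseline_freq_hz": 0.25,
        "emg_burst_rate_per_min": 2.0,
        "emg_burst_sd_mv": 0.05,
    }


def default_config() -> dict:
    """The fully resolved default configuration (deep copy)."""
    cfg = {
        "fs": 500.0,
        "fs_target": None,
        "duration_s": 600.0,
        "seed": 0,
        "n_grid": list(DEFAULT_N_GRID),
        "reference_channel": "wrist",
        "channels": ["wrist", "scalp", "ear", "neck"],
        "sigma_s_per_m": 0.2,
        "heart_vector": {
            "P": _default_wave((0.035, 0.002, -0.001), -160.0, 22.0),
            "Q": _default_wave((-0.050, -0.004, 0.002), -25.0, 9.0),
            "R": _default_wave((0.350, 0.020, -0.010), 0.0, 11.0),
            "S": _default_wave((-0.070, -0.006, 0.003), 25.0, 9.0),
            "T": _default_wave((0.105, 0.010, -0.005), 220.0, 40.0),
        },
        "schedule": {"rr_mean_s": 0.85, "rr_sd_s": 0.05},
        "noise": {"channels": {}},
        "filters": {
            "signal": {"order": 3, "f_lo": 0.5, "f_hi": 30.0},
            "reference": {"order": 3, "f_lo": 0.5, "f_hi": 95.0},
            "notch": {"order": 2, "f_c": 50.0, "bandwidth": 5.0},
        },
    }
    return cfg


def _merge(defaults, override, path: str):
    if isinstance(defaults, dict):
        if not isinstance(override, dict):
            raise ConfigError(f"{path or '<root>'}: expected a mapping")
        out = {}
        open_mapping = path.endswith("noise.channels") or path.endswith("heart_vector")
        for key, value in override.items():
            if key not in defaults and not open_mapping:
                raise ConfigError(f"{path + '.' if path else ''}{key}: unknown key")
        for key in set(defaults) | set(override):
            sub_path = f"{path + '.' if path else ''}{key}"
            if key in override:
                if key in defaults:
                    out[key] = _merge(defaults[key], override[key], sub_path)
                elif open_mapping and path.endswith("noise.channels"):
                    out[key] = _merge(_default_noise_channel(), override[key], sub_path)
                else:
                    raise ConfigError(f"{sub_path}: unknown key")
            else:
                out[key] = copy.deepcopy(defaults[key])
        return out
    return override


def _validate(cfg: dict) -> None:
    if cfg["fs"] is None or cfg["fs"] <= 0:
        raise ConfigError("fs: must be a positive rate in Hz")
    if cfg["fs_target"] is not None and cfg["fs_target"] > cfg["fs"]:
        raise ConfigError("fs_target: cannot exceed fs")
    grid = cfg["n_grid"]
    if not grid:
        raise ConfigError("n_grid: must be non-empty")
    for n in grid:
        if not isinstance(n, int) or n < 2:
            raise ConfigError(f"n_grid: ensemble size {n!r} invalid (integer >= 2 required)")
    if cfg["reference_channel"] not in cfg["channels"]:
        raise ConfigError("reference_channel: not in channels list")
    centres = [cfg["heart_vector"][w]["center_ms"] for w in ("P", "Q", "R", "S", "T")]
    if not all(a < b for a, b in zip(centres, centres[1:])):
        raise ConfigError("heart_vector: wave centres must be strictly ordered P<Q<R<S<T")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load and validate a pipeline configuration.

    Missing keys are filled from :func:`default_config` (including the
    standard ensemble-size grid); unknown keys are rejected with the
    offending key path. ``path`` may be YAML or JSON (YAML is a superset);
    ``overrides`` is merged the same way, after the file.
    """
    cfg = default_config()
    for source in (path, overrides):
        if source is None:
            continue
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            loaded = yaml.safe_load(text) or {}
        else:
            loaded = source
        cfg = _merge(cfg, loaded, "")
    _validate(cfg)
    return cfg
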