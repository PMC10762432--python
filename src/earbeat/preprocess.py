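"""Filtering and resampling of multichannel recordings.

Band selection follows the study protocol: head/ear channels are
bandpassed 0.5-30 Hz with a third-order Butterworth; the wrist reference
gets a 0.5-95 Hz third-order Butterworth plus a second-order IIR notch at
50 Hz with 5 Hz bandwidth. All filters are applied forward-backward
(zero phase), so wave timings are not biased by group delay; the
effective order is therefore doubled relative to the design order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .io import Recording

__all__ = ["FilterSpec", "bandpass_filter", "notch_filter", "resample_recording"]


@dataclass
class FilterSpec:
    """Bandpass or notch filter parameters.

    kind='bandpass' uses (order, f_lo, f_hi); kind='notch' uses
    (f_c, bandwidth), realised as the standard second-order IIR notch with
    quality factor Q = f_c / bandwidth.
    """

    kind: str = "bandpass"
    order: int = 3
    f_lo: float | None = 0.5
    f_hi: float | None = 30.0
    f_c: float | None = None
    bandwidth: float | None = None

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.kind == "bandpass":
            if self.f_lo is None or self.f_hi is None:
                raise ParameterError("bandpass needs f_lo and f_hi")
            if not (0 < self.f_lo < self.f_hi < nyq):
                raise ParameterError(
                    f"need 0 < f_lo < f_hi < fs/2; got ({self.f_lo}, {self.f_hi}) at fs={fs}"
                )
        elif self.kind == "notch":
            if self.f_c is None or self.bandwidth is None:
                raise ParameterError("notch needs f_c and bandwidth")
            if not (0 < self.f_c - self.bandwidth / 2 and self.f_c + self.bandwidth / 2 < nyq):
                raise ParameterError(
                    f"notch band [{self.f_c - self.bandwidth / 2}, "
                    f"{self.f_c + self.bandwidth / 2}] outside (0, fs/2) at fs={fs}"
                )
        else:
            raise ParameterError(f"unknown filter kind {self.kind!r}")


def _apply(rec: Recording, channels, fn) -> Recording:
    names = rec.channels if channels is None else list(channels)
    unknown = [c for c in names if c not in rec.channels]
    if unknown:
        raise KeyError(f"unknown channels {unknown}")
    data = rec.data.copy()
    for name in names:
        i = rec.channels.index(name)
        data[i] = fn(data[i])
    return Recording(fs=rec.fs, channels=list(rec.channels), data=data,
                     annotations=None if rec.annotations is None else rec.annotations.copy())


def bandpass_filter(rec: Recording, spec: FilterSpec, channels=None) -> Recording:
    """Zero-phase Butterworth bandpass on the named channels (all by default)."""
    spec = replace(spec, kind="bandpass") if spec.kind == "bandpass" else spec
    spec.validate(rec.fs)
    if spec.kind != "bandpass":
        raise ParameterError("bandpass_filter requires a bandpass FilterSpec")
    sos = sps.butter(spec.order, [spec.f_lo, spec.f_hi], btype="bandpass",
                     fs=rec.fs, output="sos")
    return _apply(rec, channels, lambda x: sps.sosfiltfilt(sos, x))


def notch_filter(rec: Recording, spec: FilterSpec, channels=None) -> Recording:
    """Zero-phase IIR notch on the named channels (all by default)."""
    spec.validate(rec.fs)
    if spec.kind != "notch":
        raise ParameterError("notch_filter requires a notch FilterSpec")
    b, a = sps.iirnotch(spec.f_c, spec.f_c / spec.bandwidth, fs=rec.fs)
    return _apply(rec, channels, lambda x: sps.filtfilt(b, a, x))


def resample_recording(rec: Recording, fs_target: float) -> Recording:
    """Anti-alias filter and resample every channel to ``fs_target``.

    Rational resampling via a polyphase FIR (Kaiser window); the 1200 to
    300 Hz case is a plain 4:1 decimation. Duration is preserved within
    one output sample. Annotations (in seconds) are carried unchanged.
    """
    if fs_target > rec.fs:
        raise ParameterError(f"fs_target {fs_target} exceeds recording rate {rec.fs}")
    if fs_target == rec.fs:
        return rec
    frac = Fraction(int(round(fs_target * 1000)), int(round(rec.fs * 1000)))
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(fs=float(fs_target), channels=list(rec.channels), data=data,
                     annotations=None if rec.annotations is None else rec.annotations.copy())
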