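"""PQRST peak delineation of a median cardiac rhythm.

The R wave is the extremum of largest magnitude within +/-40 ms of the
window origin; its sign fixes the rhythm's polarity (ear channels may
invert). Q and S are the opposite-polarity extrema immediately before and
after R (within 80 ms), P the same-polarity extremum before Q, T the
same-polarity extremum after S. Search windows bracket physiological
intervals and are overridable. A wave whose search interval is empty
after clamping to the rhythm is reported missing (None) and propagates
as such into the amplitude/timing metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import MedianRhythm
from .errors import ParameterError

__all__ = ["WaveFeatures", "SearchWindows", "delineate"]

WAVES = ("P", "Q", "R", "S", "T")


@dataclass
class SearchWindows:
    """Delineation search intervals (ms), relative to the window origin
    or to the located neighbour wave as documented per field."""

    r_halfwidth: float = 40.0     # R searched in [-r_halfwidth, +r_halfwidth]
    qs_span: float = 80.0         # Q in [c_R - qs_span, c_R); S in (c_R, c_R + qs_span]
    p_gap: float = 20.0           # P in [-200, c_Q - p_gap]
    t_gap: float = 40.0           # T in [c_S + t_gap, +400)


@dataclass
class WaveFeatures:
    """Peak timings (ms, window axis) and signed amplitudes (mV).

    Missing waves are None in both mappings. ``polarity`` is +1 or -1,
    the sign of the located R wave.
    """

    times_ms: dict[str, float | None]
    amps_mv: dict[str, float | None]
    polarity: int = 1
    missing: tuple[str, ...] = field(default_factory=tuple)

    def relative_timing(self, wave: str) -> float | None:
        """Timing of ``wave`` relative to the R wave (ms)."""
        if self.times_ms.get(wave) is None or self.times_ms.get("R") is None:
            return None
        return self.times_ms[wave] - self.times_ms["R"]


def _extremum(t, v, lo, hi, mode, closed_lo=True, closed_hi=True):
    """Index of the requested extremum of v on the time interval, or None.

    mode: 'max', 'min' or 'absmax'. Ties resolve to the earliest sample.
    """
    mask = (t >= lo) if closed_lo else (t > lo)
    mask &= (t <= hi) if closed_hi else (t < hi)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return None
    seg = v[idx]
    if mode == "absmax":
        return int(idx[np.argmax(np.abs(seg))])
    return int(idx[np.argmax(seg) if mode == "max" else np.argmin(seg)])


def delineate(m: MedianRhythm, polarity: str = "auto",
              windows: SearchWindows | None = None) -> WaveFeatures:
    """Locate the P, Q, R, S and T peaks of a median rhythm.

    ``polarity`` is 'auto' (sign of the R extremum), '+' or '-'.
    Raises :class:`ParameterError` if the rhythm does not cover the R
    search interval.
    """
    w = windows or SearchWindows()
    t = m.rel_time
    v = np.asarray(m.values, dtype=float)
    if t[0] > -w.r_halfwidth or t[-1] < w.r_halfwidth:
        raise ParameterError("rhythm window too short to bracket the R wave")

    if polarity == "auto":
        i_r = _extremum(t, v, -w.r_halfwidth, w.r_halfwidth, "absmax")
        pol = 1 if v[i_r] >= 0 else -1
    elif polarity in {"+", "-"}:
        pol = 1 if polarity == "+" else -1
        i_r = _extremum(t, v, -w.r_halfwidth, w.r_halfwidth,
                        "max" if pol > 0 else "min")
    else:
        raise ParameterError(f"polarity must be 'auto', '+' or '-', got {polarity!r}")

    same = "max" if pol > 0 else "min"
    opposite = "min" if pol > 0 else "max"
    c_r = t[i_r]

    times: dict[str, float | None] = {k: None for k in WAVES}
    amps: dict[str, float | None] = {k: None for k in WAVES}
    times["R"], amps["R"] = float(c_r), float(v[i_r])

    i_q = _extremum(t, v, c_r - w.qs_span, c_r, opposite, closed_hi=False)
    if i_q is not None:
        times["Q"], amps["Q"] = float(t[i_q]), float(v[i_q])
    i_s = _extremum(t, v, c_r, c_r + w.qs_span, opposite, closed_lo=False)
    if i_s is not None:
        times["S"], amps["S"] = float(t[i_s]), float(v[i_s])

    # if Q is missing, the P search falls back to bracketing against R
    p_hi = (times["Q"] if times["Q"] is not None else c_r) - w.p_gap
    i_p = _extremum(t, v, t[0], p_hi, same)
    if i_p is not None:
        times["P"], amps["P"] = float(t[i_p]), float(v[i_p])
    t_lo = (times["S"] if times["S"] is not None else c_r) + w.t_gap
    i_t = _extremum(t, v, t_lo, t[-1], same)
    if i_t is not None:
        times["T"], amps["T"] = float(t[i_t]), float(v[i_t])

    missing = tuple(k for k in WAVES if times[k] is None)
    return WaveFeatures(times_ms=times, amps_mv=amps, polarity=pol, missing=missing)
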