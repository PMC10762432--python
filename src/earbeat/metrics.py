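"""The four channel-similarity metrics.

Given a test median rhythm x and the reference grand-median y:

(i)   r      — Pearson product-moment correlation of the two traces.
(ii)  war    — wave amplitude ratio: the RMS over the P, Q, S, T waves of
               the R-normalized amplitude ratios,
               war = sqrt( (1/4) sum_j ((a_j b_R) / (b_j a_R))^2 ),
               where a are test amplitudes and b reference amplitudes.
(iii) dwt    — wave timing error (ms): the RMS over P, Q, S, T of the
               difference in R-relative timings,
               dwt = sqrt( (1/4) sum_j ((c_j - c_R) - (d_j - d_R))^2 ).
(iv)  dnv    — normalized variance: the RMSE between every individual
               beat window and the channel's grand-median, pooled over
               all windows and samples, divided by the grand-median's
               standard deviation.

Optimal channel performance gives r = 1, war = 1, dwt = 0 and dnv = 0.
Waves missing from either delineation (or with a zero reference
amplitude, for war) are excluded with the divisor reduced accordingly and
the result flagged.
"""

from __future__ import annotations

import numpy as np

from .delineate import WaveFeatures
from .ensemble import MedianRhythm, RhythmWindowSet
from .errors import UndefinedMetricError

__all__ = [
    "MetricValue",
    "pearson",
    "wave_amplitude_ratio",
    "wave_timing_error",
    "normalized_variance",
]

RATIO_WAVES = ("P", "Q", "S", "T")


class MetricValue(float):
    """A float carrying which waves contributed and whether any were dropped."""

    waves: tuple[str, ...]
    flagged: bool

    def __new__(cls, value: float, waves=(), flagged: bool = False):
        obj = float.__new__(cls, value)
        obj.waves = tuple(waves)
        obj.flagged = flagged
        return obj


def pearson(x, y) -> float:
    """Pearson correlation between two equal-length traces."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise UndefinedMetricError("traces must have equal length")
    if x.size < 3:
        raise UndefinedMetricError("need at least 3 samples")
    dx, dy = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(dx**2) * np.sum(dy**2))
    if denom == 0:
        raise UndefinedMetricError("correlation undefined for a constant trace")
    return float(np.sum(dx * dy) / denom)


def _usable_waves(test: WaveFeatures, ref: WaveFeatures, need_amp: bool):
    waves, flagged = [], False
    for j in RATIO_WAVES:
        ok = test.times_ms.get(j) is not None and ref.times_ms.get(j) is not None
        if need_amp:
            ok = (test.amps_mv.get(j) is not None and ref.amps_mv.get(j) is not None
                  and ref.amps_mv[j] != 0)
        if ok:
            waves.append(j)
        else:
            flagged = True
    if not waves:
        raise UndefinedMetricError("no usable P/Q/S/T waves shared by test and reference")
    return waves, flagged


def wave_amplitude_ratio(test: WaveFeatures, ref: WaveFeatures) -> MetricValue:
    """RMS of the R-normalized per-wave amplitude ratios (optimum 1)."""
    a_r, b_r = test.amps_mv.get("R"), ref.amps_mv.get("R")
    if not a_r or not b_r:
        raise UndefinedMetricError("R amplitude missing or zero")
    waves, flagged = _usable_waves(test, ref, need_amp=True)
    ratios = [(test.amps_mv[j] * b_r) / (ref.amps_mv[j] * a_r) for j in waves]
    value = float(np.sqrt(np.mean(np.square(ratios))))
    return MetricValue(value, waves=waves, flagged=flagged)


def wave_timing_error(test: WaveFeatures, ref: WaveFeatures) -> MetricValue:
    """RMS difference of R-relative wave timings, in ms (optimum 0)."""
    if test.times_ms.get("R") is None or ref.times_ms.get("R") is None:
        raise UndefinedMetricError("R timing missing")
    waves, flagged = _usable_waves(test, ref, need_amp=False)
    diffs = [test.relative_timing(j) - ref.relative_timing(j) for j in waves]
    value = float(np.sqrt(np.mean(np.square(diffs))))
    return MetricValue(value, waves=waves, flagged=flagged)


def normalized_variance(ws: RhythmWindowSet, gm: MedianRhythm,
                        per_rhythm: bool = False) -> float:
    """Grand-median-normalized RMSE of the individual beat windows.

    Default pooling takes one square root over all windows and samples;
    ``per_rhythm=True`` instead averages per-window RMSEs before
    normalizing. Raises for a constant grand-median (sigma_y = 0).
    """
    if ws.windows.shape[1] != gm.values.size:
        raise UndefinedMetricError("window set and grand median length mismatch")
    sigma_y = float(np.std(gm.values))
    if sigma_y == 0:
        raise UndefinedMetricError("grand median is constant; normalization undefined")
    err2 = (ws.windows - gm.values[None, :]) ** 2
    if per_rhythm:
        return float(np.mean(np.sqrt(np.mean(err2, axis=1))) / sigma_y)
    return float(np.sqrt(np.mean(err2)) / sigma_y)
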