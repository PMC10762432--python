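"""Beat-window extraction and median cardiac-rhythm ensembles.

One "cardiac rhythm" is a 600 ms beat window spanning -200 ms to +400 ms
around a detected R peak. A median cardiac rhythm of ensemble size N is
the per-sample median of N consecutive windows; sliding by one beat, a
segment of n consecutive rhythms yields n - N median rhythms (so 100
rhythms at N = 2 give 98 medians). The grand-median pools all available
windows and serves as the subject-level template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import Recording
from .rpeaks import RPeakSet

__all__ = ["RhythmWindowSet", "MedianRhythm", "extract_windows", "sliding_medians", "grand_median"]


@dataclass
class RhythmWindowSet:
    """Per-beat 600 ms windows of one channel.

    ``windows`` is n_rhythms x T (mV) with T = 0.6 * fs exactly;
    ``rel_time`` the shared axis in ms over [-200, +400).
    """

    windows: np.ndarray
    rel_time: np.ndarray
    fs: float
    channel: str

    @property
    def n_rhythms(self) -> int:
        return self.windows.shape[0]


@dataclass
class MedianRhythm:
    """Per-sample median of N consecutive beat windows.

    ``start_beat`` is the 0-based index of the first contributing window.
    """

    values: np.ndarray
    N: int
    start_beat: int
    fs: float

    @property
    def rel_time(self) -> np.ndarray:
        return (np.arange(self.values.size) - round(0.2 * self.fs)) * 1000.0 / self.fs


def extract_windows(rec: Recording, channel: str, rpeaks: RPeakSet) -> RhythmWindowSet:
    """Cut [k - 0.2 fs, k + 0.4 fs) windows around each R peak at sample k.

    Peaks too close to either end for a complete window are dropped.
    """
    if rpeaks.fs != rec.fs:
        raise ParameterError(f"rpeaks at {rpeaks.fs} Hz but recording at {rec.fs} Hz")
    trace = rec.channel(channel)
    before = round(0.2 * rec.fs)
    after = round(0.4 * rec.fs)
    keep = [k for k in rpeaks.indices if k - before >= 0 and k + after <= trace.size]
    windows = (np.stack([trace[k - before : k + after] for k in keep])
               if keep else np.empty((0, before + after)))
    rel_time = (np.arange(before + after) - before) * 1000.0 / rec.fs
    return RhythmWindowSet(windows=windows, rel_time=rel_time, fs=rec.fs, channel=channel)


def sliding_medians(ws: RhythmWindowSet, N: int) -> list[MedianRhythm]:
    """All ensemble-size-N median rhythms, sliding one beat at a time.

    Returns n_rhythms - N medians; median m covers beats m .. m+N-1.
    Even N takes the mean of the two central order statistics. Raises
    :class:`ParameterError` when N is out of range.
    """
    n = ws.n_rhythms
    if not 2 <= N <= n:
        raise ParameterError(f"need 2 <= N <= {n}, got N={N}")
    return [
        MedianRhythm(values=np.median(ws.windows[m : m + N], axis=0),
                     N=N, start_beat=m, fs=ws.fs)
        for m in range(n - N)
    ]


def grand_median(ws: RhythmWindowSet) -> MedianRhythm:
    """Per-sample median over all windows (N = n_rhythms)."""
    if ws.n_rhythms < 1:
        raise ParameterError("empty window set has no grand median")
    return MedianRhythm(values=np.median(ws.windows, axis=0),
                        N=ws.n_rhythms, start_beat=0, fs=ws.fs)
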