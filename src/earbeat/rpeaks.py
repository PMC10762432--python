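"""Pan-Tompkins QRS detection on the reference channel.

Classic stage sequence: 5-15 Hz bandpass to isolate QRS energy,
differentiation, squaring, and a 150 ms moving-window integration,
followed by adaptive dual-threshold peak classification with signal/noise
level tracking, a 200 ms refractory period and a search-back pass at
1.66x the running RR estimate. Detections are then refined to the local
maximum of the filtered input within +/-50 ms, which places them on the R
maxima that downstream windowing assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError

__all__ = ["RPeakSet", "pan_tompkins"]

REFRACTORY_S = 0.2


@dataclass
class RPeakSet:
    """Detected R-maximum sample indices (strictly increasing) at rate fs."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) < round(REFRACTORY_S * self.fs)):
            raise ParameterError("R peaks violate the 200 ms refractory invariant")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return self.indices.size


def _integrate(x: np.ndarray, width: int) -> np.ndarray:
    return np.convolve(x, np.ones(width) / width, mode="same")


def pan_tompkins(signal: np.ndarray, fs: float, refine: bool = True,
                 refine_window_s: float = 0.05) -> RPeakSet:
    """Detect R peaks in a (filtered) single-lead ECG trace.

    Parameters
    ----------
    signal : ndarray
        Reference-channel trace in mV (already bandpass/notch filtered).
    fs : float
        Sampling rate, >= 200 Hz.
    refine : bool
        Move each detection to the local maximum of ``signal`` within
        +/- ``refine_window_s``; ties resolve to the earliest sample.

    Returns an empty :class:`RPeakSet` for a zero-variance input and
    raises :class:`ParameterError` for signals shorter than 2 s.
    """
    signal = np.asarray(signal, dtype=float)
    if fs < 200:
        raise ParameterError("pan_tompkins needs fs >= 200 Hz")
    if signal.size < 2 * fs:
        raise ParameterError("signal shorter than 2 s")
    if np.ptp(signal) == 0:
        return RPeakSet(indices=np.array([], dtype=int), fs=fs)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, signal)
    deriv = np.gradient(bp)
    mwi = _integrate(deriv**2, int(round(0.15 * fs)))

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return RPeakSet(indices=np.array([], dtype=int), fs=fs)

    # threshold training on the first 2 s
    train = mwi[: int(2 * fs)]
    spki = 0.875 * float(np.max(train))
    npki = 0.5 * float(np.mean(train))

    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    def accept(idx: int, peak_val: float, searchback: bool) -> None:
        nonlocal spki
        if searchback:
            spki = 0.25 * peak_val + 0.75 * spki
        else:
            spki = 0.125 * peak_val + 0.875 * spki
        if accepted:
            rr_history.append((idx - accepted[-1]) / fs)
            del rr_history[:-8]
        accepted.append(idx)

    noise_peaks: list[int] = []
    for idx in cand:
        pk = mwi[idx]
        if accepted and idx - accepted[-1] < refractory:
            continue
        if pk > threshold():
            accept(int(idx), pk, searchback=False)
        else:
            npki = 0.125 * pk + 0.875 * npki
            noise_peaks.append(int(idx))
        # search-back: a missed beat leaves a gap > 1.66 * mean recent RR
        if len(rr_history) >= 2:
            rr_avg = float(np.mean(rr_history))
            if accepted and (idx - accepted[-1]) / fs > 1.66 * rr_avg:
                window = [j for j in noise_peaks
                          if accepted[-1] + refractory <= j < idx - refractory]
                if window:
                    best = max(window, key=lambda j: mwi[j])
                    if mwi[best] > 0.5 * threshold():
                        accept(best, mwi[best], searchback=True)
                        accepted.sort()

    if not accepted:
        return RPeakSet(indices=np.array([], dtype=int), fs=fs)

    peaks = np.array(sorted(accepted), dtype=int)
    if refine:
        half = int(round(refine_window_s * fs))
        refined = []
        for k in peaks:
            lo, hi = max(k - half, 0), min(k + half + 1, signal.size)
            refined.append(lo + int(np.argmax(signal[lo:hi])))
        peaks = np.array(refined, dtype=int)

    # dedupe / enforce refractory after refinement: keep the larger peak
    keep: list[int] = []
    for k in peaks:
        if keep and k - keep[-1] < refractory:
            if signal[k] > signal[keep[-1]]:
                keep[-1] = int(k)
        elif not keep or k != keep[-1]:
            keep.append(int(k))
    return RPeakSet(indices=np.array(keep, dtype=int), fs=fs)
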