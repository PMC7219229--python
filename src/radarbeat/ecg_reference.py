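"""Training targets from the reference ECG.

R peaks are located with the Pan-Tompkins stage sequence (band-pass,
derivative, squaring, moving-window integration, dual adaptive
thresholds with search-back), then converted into the surrogate
training label: a 400 ms binary pulse starting 200 ms after each R
wave, synthesized directly on the 100 Hz processing grid.  The delay
covers the electro-mechanical R-J interval (~203-290 ms) so the pulse
brackets where the mechanical beat signature appears in the radar
channels.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .signal_core import BeatTrain, SubjectRecording, TimeSeries

__all__ = [
    "BinaryTarget",
    "pan_tompkins",
    "binarize_targets",
    "sweep_target_params",
    "TARGET_DELAY",
    "TARGET_WIDTH",
]

TARGET_DELAY = 0.200  # s after the R wave
TARGET_WIDTH = 0.400  # s pulse width


@dataclass
class BinaryTarget:
    """Binary {0,1} label stream at the processing rate (100 Hz)."""

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("target values must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    def __len__(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------


def pan_tompkins(ecg: TimeSeries) -> BeatTrain:
    """Detect R peaks on the ECG at its native rate.

    Classic stage sequence: 5-15 Hz band-pass, five-point derivative,
    squaring, 150 ms moving-window integration, dual adaptive
    signal/noise thresholds with a 200 ms refractory interval and
    search-back at 1.66x the running RR.  Filtering is zero-phase /
    centered so the integrated peak stays aligned with the QRS; the
    returned time is the R apex on the original ECG within +/-40 ms of
    the integrated-peak location.
    """
    fs = ecg.rate
    if fs < 200:
        raise ValueError("pan_tompkins needs an ECG sampled at >= 200 Hz")
    n = len(ecg)
    if n < 2 * fs:
        raise ValueError("pan_tompkins needs at least 2 s of ECG")
    x = ecg.values

    sos = _signal.butter(2, (5.0, 15.0), btype="band", fs=fs, output="sos")
    filt = _signal.sosfiltfilt(sos, x)
    # centered five-point derivative (sign is irrelevant after squaring)
    deriv = np.convolve(filt, np.array([-1, -2, 0, 2, 1]) * (fs / 8.0),
                        mode="same")
    squared = deriv * deriv
    win = int(round(0.150 * fs))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = _signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return BeatTrain(np.empty(0))

    head = mwi[: int(2 * fs)]
    spki = 0.25 * float(np.max(head))
    npki = 0.5 * float(np.mean(head))
    qrs: List[int] = []
    rr: List[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for p in cand:
        if qrs and rr:
            rr_avg = float(np.mean(rr[-8:]))
            if p - qrs[-1] > 1.66 * rr_avg:
                # search back for the largest missed candidate at half
                # threshold inside the gap
                gap = cand[(cand > qrs[-1] + refractory) & (cand < p)]
                gap = gap[mwi[gap] > 0.5 * threshold()]
                if gap.size:
                    back = int(gap[np.argmax(mwi[gap])])
                    spki = 0.25 * mwi[back] + 0.75 * spki
                    rr.append(back - qrs[-1])
                    qrs.append(back)
        if mwi[p] >= threshold():
            if qrs:
                rr.append(p - qrs[-1])
            qrs.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki

    qrs_arr = np.sort(np.asarray(qrs, dtype=int))
    # refine to the R apex on the raw ECG within +/-40 ms
    w = int(round(0.040 * fs))
    apex = []
    for p in qrs_arr:
        lo = max(p - w, 0)
        hi = min(p + w + 1, n)
        apex.append(lo + int(np.argmax(x[lo:hi])))
    apex_arr = np.unique(np.asarray(apex, dtype=int))
    if apex_arr.size > 1:  # drop refinements collapsing into the refractory
        keep = [apex_arr[0]]
        for p in apex_arr[1:]:
            if p - keep[-1] >= refractory:
                keep.append(p)
        apex_arr = np.asarray(keep)
    return BeatTrain(ecg.t0 + apex_arr / fs)


# ---------------------------------------------------------------------------
# Binarized target
# ---------------------------------------------------------------------------


def binarize_targets(beats: BeatTrain, rate: float, span: tuple,
                     delay: float = TARGET_DELAY,
                     width: float = TARGET_WIDTH) -> BinaryTarget:
    """Delayed binary pulse train on the processing grid.

    Sample at time ``t`` is 1 iff some beat ``t_k`` satisfies
    ``t in [t_k + delay, t_k + delay + width)``; overlapping pulses
    merge into their union.  The label is synthesized directly at
    ``rate`` -- exactly equivalent to nearest-sample decimation of a
    high-rate binary pulse train, but keeps the values binary.
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    if delay < 0 or width < 0:
        raise ValueError("delay and width must be non-negative")
    start, stop = span
    if not start < stop:
        raise ValueError("need span start < stop")
    n = int(round((stop - start) * rate))
    v = np.zeros(n, dtype=np.uint8)
    for tb in beats.times:
        k0 = int(np.ceil((tb + delay - start) * rate - 1e-9))
        k1 = int(np.ceil((tb + delay + width - start) * rate - 1e-9))
        k0 = max(k0, 0)
        k1 = min(k1, n)
        if k0 < k1:
            v[k0:k1] = 1
    return BinaryTarget(v, rate, start)


# ---------------------------------------------------------------------------
# Delay/width sweep
# ---------------------------------------------------------------------------


def sweep_target_params(recordings: Sequence[SubjectRecording],
                        delays: Sequence[float],
                        widths: Sequence[float],
                        topology: str = "FF 10 1",
                        seed: int = 0,
                        train_overrides: Optional[dict] = None,
                        ) -> pd.DataFrame:
    """Grid-evaluate target delay/width choices with the smallest network.

    For every (delay, width) pair, trains an ``FF 10 1`` detector on the
    given recordings and reports the percentage of reference beats that
    receive a detection inside their ``[R+delay, R+delay+width)`` window.
    Duplicate grid points are dropped; grid bounds must lie in [0, 1] s.
    """
    from .detector import HeartbeatDetector  # local import: avoids a cycle

    if not recordings:
        raise ValueError("need at least one recording")
    if len(delays) == 0 or len(widths) == 0:
        raise ValueError("empty parameter grid")
    if any(not 0 <= d <= 1 for d in delays) or \
            any(not 0 <= w <= 1 for w in widths):
        raise ValueError("grid bounds must lie within [0, 1] s")
    pairs = list(dict.fromkeys((float(d), float(w))
                               for d in delays for w in widths))
    rows = []
    for delay, width in pairs:
        det = HeartbeatDetector(topology=topology, delay=delay, width=width,
                                seed=seed, **(train_overrides or {}))
        det.fit(list(recordings))
        hit = 0
        total = 0
        for rec in recordings:
            refs = pan_tompkins(rec.ecg)
            found = det.predict(rec).beats.times
            for tb in refs.times:
                total += 1
                lo, hi = tb + delay, tb + delay + width
                if np.any((found >= lo) & (found < hi)):
                    hit += 1
        rows.append({"delay": delay, "width": width,
                     "detection_rate": 100.0 * hit / max(total, 1)})
    return pd.DataFrame(rows)
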