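"""Conditioning of raw body-surface recordings.

Ventricular activity (the QRS complex) dominates torso recordings and must
be removed before atrial analysis; signals are then restricted to the atrial
band with a 2-20 Hz zero-phase Butterworth filter, and analysis windows are
planned: per recording, three >= 4 s windows for dominant-frequency maps,
each containing a 1 s window for rotor maps, with the per-window biomarkers
averaged at the end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signals import NodeSignalSet

__all__ = [
    "SegmentPlan",
    "remove_qrs",
    "detect_r_peaks",
    "band_filter",
    "plan_segments",
    "average_windows",
]


@dataclass
class SegmentPlan:
    """Analysis windows for one recording, in seconds.

    df_windows : three non-overlapping [start, end) windows of >= 4 s for
        dominant-frequency analysis
    rotor_windows : one 1 s window inside each DF window
    """

    df_windows: list[tuple[float, float]]
    rotor_windows: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for a, b in self.df_windows:
            if b - a < 4.0 - 1e-9:
                raise ValueError("DF windows must be >= 4 s")
        for a, b in self.rotor_windows:
            if abs((b - a) - 1.0) > 1e-9:
                raise ValueError("rotor windows must be exactly 1 s")


def remove_qrs(
    signal: NodeSignalSet,
    r_peaks_s: np.ndarray,
    pre_ms: float = 60.0,
    post_ms: float = 100.0,
) -> NodeSignalSet:
    """Blank and interpolate a window around each R peak.

    A window of [-pre_ms, +post_ms] around every peak is replaced, per
    channel, by a cubic spline fitted to flanking samples; overlapping
    windows are merged. Samples outside the blanking windows are returned
    bit-identical; output length equals input length.
    """
    r_peaks_s = np.sort(np.asarray(r_peaks_s, dtype=float))
    if r_peaks_s.size == 0:
        return signal.copy_with(signal.samples.copy())
    if r_peaks_s[0] < 0 or r_peaks_s[-1] > signal.duration_s:
        raise ValueError("R peaks outside the recording")
    fs = signal.fs_hz
    n = signal.n_samples
    pre = int(round(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))

    # merge overlapping blank intervals
    intervals: list[list[int]] = []
    for tp in r_peaks_s:
        c = int(round(tp * fs))
        lo, hi = max(0, c - pre), min(n, c + post + 1)
        if intervals and lo <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], hi)
        else:
            intervals.append([lo, hi])

    out = signal.samples.copy()
    flank = max(4, pre // 2)  # support samples each side of the gap
    for lo, hi in intervals:
        left = np.arange(max(0, lo - flank), lo)
        right = np.arange(hi, min(n, hi + flank))
        support = np.concatenate([left, right])
        gap = np.arange(lo, hi)
        if support.size < 4:
            # window swallows a recording edge: fall back to nearest value
            fill_idx = right[0] if right.size else left[-1]
            out[:, gap] = out[:, [fill_idx]]
            continue
        cs = CubicSpline(support, out[:, support], axis=1)
        out[:, gap] = cs(gap)
    return signal.copy_with(out)


def detect_r_peaks(signal: NodeSignalSet, channel: int = 0) -> np.ndarray:
    """Simple amplitude R-peak detector on one reference lead.

    Peaks must exceed 60% of the lead's maximum absolute amplitude and be
    at least 300 ms apart (refractory constraint). Returns peak times in s.
    """
    x = np.abs(signal.samples[channel])
    height = 0.6 * x.max()
    dist = int(0.3 * signal.fs_hz)
    peaks, _ = sps.find_peaks(x, height=height, distance=dist)
    return peaks / signal.fs_hz


def band_filter(
    signal: NodeSignalSet,
    low_hz: float = 2.0,
    high_hz: float = 20.0,
    order: int = 4,
) -> NodeSignalSet:
    """Zero-phase Butterworth band-pass restricted to the atrial band.

    Defaults are a 2 Hz high-pass and 20 Hz low-pass of order 4, applied
    forward-backward (``sosfiltfilt``) so no phase distortion is introduced
    ahead of Hilbert phase analysis.
    """
    if signal.fs_hz <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=signal.fs_hz, output="sos")
    # forward-backward filtering needs warm-up samples on both ends
    padlen = 3 * (2 * order + 1)
    if signal.n_samples <= 3 * padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering: {signal.n_samples} samples"
        )
    filtered = sps.sosfiltfilt(sos, signal.samples, axis=1)
    return signal.copy_with(np.ascontiguousarray(filtered))


def plan_segments(
    signal: NodeSignalSet,
    n_windows: int = 3,
    df_window_s: float = 4.0,
    rotor_window_s: float = 1.0,
) -> SegmentPlan:
    """Place the analysis windows deterministically (evenly spaced).

    Window starts are ``0, (D - w)/2, D - w`` for duration D and window
    length w, which for a 20 s recording yields [0,4), [8,12), [16,20).
    The 1 s rotor window is centred inside each DF window.
    """
    D = signal.duration_s
    need = n_windows * df_window_s
    if D < need - 1e-9:
        raise ValueError(
            f"recording too short: {D:.2f} s available, {need:.0f} s needed "
            f"({need - D:.2f} s deficit) for {n_windows} windows of {df_window_s:.0f} s"
        )
    if n_windows == 1:
        starts = np.array([0.0])
    else:
        starts = np.linspace(0.0, D - df_window_s, n_windows)
    df_windows = [(float(s), float(s + df_window_s)) for s in starts]
    rotor_windows = [
        (float(s + (df_window_s - rotor_window_s) / 2.0),
         float(s + (df_window_s + rotor_window_s) / 2.0))
        for s in starts
    ]
    return SegmentPlan(df_windows=df_windows, rotor_windows=rotor_windows)


def average_windows(values: list[dict]) -> dict:
    """Arithmetic mean of per-window biomarker dictionaries.

    All windows must report the same biomarker names.
    """
    if not values:
        raise ValueError("need at least one window")
    keys = set(values[0])
    for v in values[1:]:
        if set(v) != keys:
            raise ValueError(f"inconsistent biomarker sets: {sorted(keys)} vs {sorted(v)}")
    return {k: float(np.mean([v[k] for v in values])) for k in sorted(keys)}
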