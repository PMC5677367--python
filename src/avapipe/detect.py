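"""nLFP extraction from continuous LFP by fixed or adaptive thresholding.

Fixed thresholding places the threshold at ``mean - thr_sd * SD`` per channel,
with the statistics computed over the whole recording; every maximal
contiguous sub-threshold excursion produces one event at the sample of
largest negative amplitude. Adaptive thresholding recomputes the statistics
in consecutive non-overlapping windows (100 ms by default), so slow rate
transients show up as amplitude changes rather than event-rate changes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .raster import ArrayGeometry, EventRaster
from .synthlfp import LfpRecording

__all__ = ["detect_fixed", "detect_adaptive", "assign_trials"]


def _excursion_events(dev: np.ndarray, thr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Event sample indices and amplitudes of contiguous sub-threshold runs.

    ``dev`` is the mean-subtracted trace, ``thr`` the (negative) per-sample
    threshold. Each maximal run with dev < thr yields the index of its most
    negative sample.
    """
    below = dev < thr
    if not below.any():
        return np.empty(0, dtype=int), np.empty(0)
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(below)]
    idx = np.empty(len(starts), dtype=int)
    amp = np.empty(len(starts))
    for i, (a, b) in enumerate(zip(starts, ends)):
        j = a + int(np.argmin(dev[a:b]))
        idx[i] = j
        amp[i] = dev[j]
    return idx, amp


def detect_fixed(lfp: LfpRecording, thr_sd: float = 2.0) -> EventRaster:
    """Detect nLFPs at a fixed per-channel threshold of mean - thr_sd * SD.

    Returns an absolute-time raster (trial 0); use :func:`assign_trials` to
    align to trial marks. Amplitudes are mean-subtracted sample values
    (negative). Zero-variance channels are skipped with a warning.
    """
    if thr_sd <= 0:
        raise ValueError("thr_sd must be positive")
    if lfp.samples.size == 0:
        raise ValueError("empty recording")
    rows = []
    for ch in range(lfp.n_channels):
        x = lfp.samples[ch]
        sd = x.std()
        if sd == 0:
            warnings.warn(f"channel {lfp.channel_ids[ch]} has zero variance; skipped")
            continue
        dev = x - x.mean()
        idx, amp = _excursion_events(dev, np.full_like(dev, -thr_sd * sd))
        for j, a in zip(idx, amp):
            rows.append((int(lfp.channel_ids[ch]), 0, j / lfp.fs, a))
    df = pd.DataFrame(rows, columns=["electrode", "trial", "time", "amplitude"])
    return EventRaster(df, ArrayGeometry(n_electrodes=lfp.n_channels))


def detect_adaptive(
    lfp: LfpRecording, window: float = 0.1, thr_sd: float = 2.0
) -> EventRaster:
    """Detect nLFPs with mean/SD recomputed in consecutive windows.

    The per-sample threshold is a step function over non-overlapping windows
    of the given duration (a trailing partial window uses its own statistics).
    A deflection spanning a window boundary is one event, assigned the
    amplitude and threshold of the window containing its minimum.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = lfp.samples.shape[1]
    w = int(round(window * lfp.fs))
    if w < 2 or w > n:
        raise ValueError("window must fit within the recording")
    edges = list(range(0, n, w))
    rows = []
    for ch in range(lfp.n_channels):
        x = lfp.samples[ch]
        dev = np.empty_like(x)
        thr = np.empty_like(x)
        degenerate = True
        for a in edges:
            b = min(a + w, n)
            seg = x[a:b]
            sd = seg.std()
            if sd > 0:
                degenerate = False
            dev[a:b] = seg - seg.mean()
            thr[a:b] = -thr_sd * sd if sd > 0 else -np.inf
        if degenerate:
            warnings.warn(f"channel {lfp.channel_ids[ch]} has zero variance; skipped")
            continue
        idx, amp = _excursion_events(dev, thr)
        for j, a_ in zip(idx, amp):
            rows.append((int(lfp.channel_ids[ch]), 0, j / lfp.fs, a_))
    df = pd.DataFrame(rows, columns=["electrode", "trial", "time", "amplitude"])
    return EventRaster(df, ArrayGeometry(n_electrodes=lfp.n_channels))


def assign_trials(
    raster: EventRaster,
    trial_marks: np.ndarray,
    trial_span: tuple[float, float],
) -> EventRaster:
    """Cut an absolute-time raster into trial-relative events.

    Each event falling within ``mark + trial_span`` of some trial mark is
    relabelled with that trial's index and the trial-relative time; events
    outside every trial window are dropped.
    """
    marks = np.asarray(trial_marks, dtype=float)
    t0, t1 = trial_span
    ev = raster.events
    out = []
    for tr, m in enumerate(marks):
        sel = ev[(ev["time"] >= m + t0) & (ev["time"] < m + t1)]
        if len(sel):
            out.append(
                pd.DataFrame(
                    {
                        "electrode": sel["electrode"].to_numpy(),
                        "trial": tr,
                        "time": sel["time"].to_numpy() - m,
                        "amplitude": sel["amplitude"].to_numpy(),
                    }
                )
            )
    df = (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(columns=["electrode", "trial", "time", "amplitude"])
    )
    return EventRaster(df, raster.geometry, trial_span)
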