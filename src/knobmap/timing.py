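"""Movement-timing analysis of the paced visuomotor synchronisation task.

Subjects produced brief isometric finger abductions paced by a 1 Hz visual
cue; the force-sensor voltage (500 Hz, 0–2.5 V with hard saturation) is the
behavioural record.  Movement events are the force peaks: local maxima above
0.6 V, at least 400 ms apart, with topographic prominence of at least one
third of the trace's maximum (the per-subject, per-run maximum force).
Saturated taps appear as plateaus at the sensor ceiling; a plateau's midpoint
is taken as its peak time, so clipping does not bias intervals.

Timing precision is the coefficient of variation (CV = SD/mean, sample SD)
of the intermovement intervals — successive peak-to-peak differences taken
strictly within movement blocks, never across the rest blocks in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InputError
from .synthcohort import ForceTrace

logger = logging.getLogger(__name__)


@dataclass
class TimingResult:
    """Intermovement-interval statistics of one finger's run."""

    peak_times: np.ndarray       # s
    intervals: np.ndarray        # s, within movement blocks only
    mean_interval: float
    sd_interval: float
    cv: float
    valid: bool = True
    flag: str = ""


def detect_peaks(trace: ForceTrace, threshold: float = 0.6,
                 min_distance: float = 0.4,
                 prominence_fraction: float = 1.0 / 3.0) -> np.ndarray:
    """Movement-peak times (s) of a force trace.

    The signal is thresholded at ``threshold`` volts (values below are zeroed)
    and peaks are kept when separated by at least ``min_distance`` seconds
    (smaller neighbours of a larger peak are dropped first) and when their
    topographic prominence — height above the higher of the two flanking
    minima bounding the peak's own basin — reaches ``prominence_fraction``
    of the trace maximum.  Flat (saturated) peaks report their plateau
    midpoint.  An empty or all-subthreshold trace yields an empty result.
    """
    x = np.asarray(trace.samples, float)
    if x.size == 0:
        logger.warning("empty force trace; no peaks")
        return np.array([])
    thresholded = np.where(x >= threshold, x, 0.0)
    if not np.any(thresholded):
        logger.warning("force trace entirely below %.2f V; no peaks", threshold)
        return np.array([])
    fs = trace.sampling_rate
    prominence = prominence_fraction * x.max()
    idx, _ = find_peaks(thresholded, height=threshold,
                        distance=max(1, int(round(min_distance * fs))),
                        prominence=prominence)
    return idx / fs


def interval_cv(peak_times: np.ndarray,
                block_bounds: list | None = None) -> TimingResult:
    """Intermovement intervals and their CV from detected peak times.

    Intervals are differences of consecutive peaks within the same movement
    block (``block_bounds`` as (start, end) pairs in seconds); without bounds
    all consecutive pairs count.  Needs at least 3 peaks (2 intervals); the
    sample SD (n−1 denominator) is used.
    """
    t = np.sort(np.asarray(peak_times, float))
    if block_bounds is not None:
        intervals = []
        for start, end in block_bounds:
            tb = t[(t >= start) & (t <= end)]
            intervals.append(np.diff(tb))
        intervals = np.concatenate(intervals) if intervals else np.array([])
    else:
        intervals = np.diff(t)
    if len(intervals) < 2:
        return TimingResult(t, intervals, np.nan, np.nan, np.nan,
                            valid=False, flag="fewer than 3 peaks / 2 intervals")
    if np.any(intervals <= 0):
        raise InputError("non-positive intermovement interval")
    mean = float(intervals.mean())
    sd = float(intervals.std(ddof=1))
    return TimingResult(t, intervals, mean, sd, sd / mean)


def analyze_force_trace(trace: ForceTrace, threshold: float = 0.6,
                        min_distance: float = 0.4,
                        prominence_fraction: float = 1.0 / 3.0) -> TimingResult:
    """Peak detection + interval CV honouring the trace's block schedule."""
    peaks = detect_peaks(trace, threshold, min_distance, prominence_fraction)
    return interval_cv(peaks, trace.block_bounds)
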