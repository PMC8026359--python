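"""Motor-evoked-potential extraction and corticomotor excitability mapping.

Works on stimulus-locked surface-EMG traces (10 kHz, spanning at least
−100…+60 ms around the TMS pulse; the hardware band-pass of the acquisition
chain is assumed, no re-filtering happens here).  Per trial it provides

* artifact rejection — an objective surrogate for visual inspection: a trial
  is invalid when the pre-stimulus RMS exceeds a limit (default 0.02 mV),
* peak-to-peak amplitude in the 10–40 ms post-stimulus window,
* onset latency — a surrogate for expert marking: the earliest time in
  10–40 ms at which the rectified deviation from the baseline mean exceeds
  ``k_sd`` baseline SDs continuously for ``sustain_ms``.

Per site the valid-trial mean amplitudes form the 5×7 excitability map; the
site with the largest mean is the motor hotspot, and the shortest valid
latency among that site's trials is the subject's corticomotor latency.

The resting motor threshold is estimated with an adaptive maximum-likelihood
staircase (fixed-slope logistic refit on a 1 %-MSO grid after every response;
each next stimulus at the running ML threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import AnalysisError, InputError
from .gridgeom import StimulationGrid

logger = logging.getLogger(__name__)

AMP_WINDOW_MS = (10.0, 40.0)   # post-stimulus search window for amplitude & latency


@dataclass
class EMGTrace:
    """One stimulus-locked EMG sweep.

    ``samples`` in mV; ``stimulus_index`` is the sample of the TMS pulse.
    """

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    stimulus_index: int = 1000
    muscle: str = "FDI"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        pre_ms = self.stimulus_index / self.sampling_rate * 1e3
        post_ms = (len(self.samples) - self.stimulus_index) / self.sampling_rate * 1e3
        if pre_ms < 100.0 - 1e-9 or post_ms < 60.0 - 1e-9:
            raise InputError("trace must span at least -100...+60 ms around the stimulus")


@dataclass
class MEPRecord:
    """Extracted per-trial MEP: amplitude (mV), latency (ms or None), validity."""

    amplitude: float
    latency: float | None
    valid: bool
    rejection_reason: str = ""


@dataclass
class ExcitabilityMap:
    """Per-site mean MEP amplitude (mV) and valid-trial counts, shape (lines, targets)."""

    mean_amplitude: np.ndarray
    n_valid_trials: np.ndarray

    @property
    def flagged(self) -> np.ndarray:
        """Sites with zero valid trials (excluded from the hotspot search)."""
        return self.n_valid_trials == 0


@dataclass
class Hotspot:
    """The site of maximal mean MEP amplitude and its shortest valid latency."""

    line_index: int
    target_index: int
    position: np.ndarray
    mean_amplitude: float
    shortest_latency: float | None
    tie: bool = False

    @property
    def y_coordinate(self) -> float:
        return float(self.position[1])


# ---------------------------------------------------------------------------
# per-trial operations (scalar API; the session path below is vectorised)
# ---------------------------------------------------------------------------

def _baseline(trace: EMGTrace):
    pre = trace.samples[:trace.stimulus_index]
    return float(pre.mean()), float(pre.std())


def reject_artifact_trial(trace: EMGTrace, baseline_rms_limit: float = 0.02) -> bool:
    """True (valid) iff pre-stimulus RMS is within the limit."""
    n_pre = trace.stimulus_index
    if n_pre / trace.sampling_rate * 1e3 < 100.0 - 1e-9:
        raise InputError("need >= 100 ms of pre-stimulus baseline")
    rms = float(np.sqrt(np.mean(trace.samples[:n_pre] ** 2)))
    return rms <= baseline_rms_limit


def _window_slice(trace: EMGTrace):
    fs = trace.sampling_rate
    lo = trace.stimulus_index + int(round(AMP_WINDOW_MS[0] * 1e-3 * fs))
    hi = trace.stimulus_index + int(round(AMP_WINDOW_MS[1] * 1e-3 * fs))
    if hi > len(trace.samples):
        raise InputError("10-40 ms window extends beyond the trace")
    return lo, hi


def extract_amplitude(trace: EMGTrace) -> float:
    """Peak-to-peak amplitude (max − min, mV) within 10–40 ms post-stimulus."""
    lo, hi = _window_slice(trace)
    win = trace.samples[lo:hi + 1]
    return float(win.max() - win.min())


def estimate_latency(trace: EMGTrace, k_sd: float = 3.0,
                     sustain_ms: float = 0.5) -> float | None:
    """MEP onset latency (ms post-stimulus), or None when no onset is found.

    Earliest time in the 10–40 ms window where |signal − baseline mean|
    exceeds ``k_sd`` × baseline SD continuously for ``sustain_ms``.  With a
    silent baseline (SD 0) any strictly nonzero sustained deviation counts,
    so an all-zero trace yields None.
    """
    mean, sd = _baseline(trace)
    lo, hi = _window_slice(trace)
    dev = np.abs(trace.samples[lo:hi + 1] - mean) > k_sd * sd
    n_sustain = max(1, int(round(sustain_ms * 1e-3 * trace.sampling_rate)))
    onset = _first_sustained(dev[None, :], n_sustain)[0]
    if onset < 0:
        return None
    return AMP_WINDOW_MS[0] + onset / trace.sampling_rate * 1e3


def _first_sustained(dev: np.ndarray, n_sustain: int) -> np.ndarray:
    """First index per row where ``dev`` holds for ``n_sustain`` consecutive samples.

    ``dev`` is boolean with shape (rows, samples); returns −1 where never.
    """
    if dev.shape[-1] < n_sustain:
        return np.full(dev.shape[0], -1)
    cs = np.concatenate([np.zeros(dev.shape[:-1] + (1,), int),
                         np.cumsum(dev, axis=-1)], axis=-1)
    runs = cs[..., n_sustain:] - cs[..., :-n_sustain] == n_sustain
    has = runs.any(axis=-1)
    first = runs.argmax(axis=-1)
    return np.where(has, first, -1)


def analyze_trial(trace: EMGTrace, baseline_rms_limit: float = 0.02,
                  k_sd: float = 3.0, sustain_ms: float = 0.5) -> MEPRecord:
    if not reject_artifact_trial(trace, baseline_rms_limit):
        return MEPRecord(np.nan, None, False, "baseline RMS above limit")
    return MEPRecord(extract_amplitude(trace),
                     estimate_latency(trace, k_sd, sustain_ms), True)


# ---------------------------------------------------------------------------
# session-level (vectorised) path
# ---------------------------------------------------------------------------

@dataclass
class SessionResult:
    """Everything extracted from one mapping session of one muscle."""

    map: ExcitabilityMap
    hotspot: Hotspot
    amplitudes: np.ndarray       # (lines, targets, trials), NaN where invalid
    latencies: np.ndarray        # (lines, targets, trials), NaN where absent/invalid
    valid: np.ndarray            # boolean (lines, targets, trials)


def analyze_session(traces: np.ndarray, grid: StimulationGrid,
                    sampling_rate: float = 10_000.0, stimulus_index: int = 1000,
                    baseline_rms_limit: float = 0.02, k_sd: float = 3.0,
                    sustain_ms: float = 0.5) -> SessionResult:
    """Run rejection, amplitude and latency extraction on a full session.

    ``traces`` has shape (n_sites, n_trials, n_samples) with sites in
    row-major (line, target) order matching the grid.
    """
    n_sites, n_trials, n_samples = traces.shape
    if n_sites != grid.n_sites:
        raise InputError("session sites do not match the grid")
    fs = sampling_rate
    x = traces.astype(np.float64, copy=False)

    pre = x[..., :stimulus_index]
    rms = np.sqrt(np.mean(pre ** 2, axis=-1))
    valid = rms <= baseline_rms_limit
    base_mean = pre.mean(axis=-1)
    base_sd = pre.std(axis=-1)

    lo = stimulus_index + int(round(AMP_WINDOW_MS[0] * 1e-3 * fs))
    hi = stimulus_index + int(round(AMP_WINDOW_MS[1] * 1e-3 * fs))
    if hi + 1 > n_samples:
        raise InputError("10-40 ms window extends beyond the traces")
    win = x[..., lo:hi + 1]
    amps = win.max(axis=-1) - win.min(axis=-1)

    dev = np.abs(win - base_mean[..., None]) > k_sd * base_sd[..., None]
    n_sustain = max(1, int(round(sustain_ms * 1e-3 * fs)))
    onset = _first_sustained(dev.reshape(-1, dev.shape[-1]), n_sustain)
    onset = onset.reshape(n_sites, n_trials).astype(float)
    lats = AMP_WINDOW_MS[0] + onset / fs * 1e3
    lats[onset < 0] = np.nan

    shape = (grid.n_lines, grid.n_targets, n_trials)
    amps = np.where(valid, amps, np.nan).reshape(shape)
    lats = np.where(valid, lats, np.nan).reshape(shape)
    emap = build_map(amps)
    hotspot = find_hotspot(emap, grid, lats)
    return SessionResult(emap, hotspot, amps, lats, valid.reshape(shape))


def build_map(amplitudes: np.ndarray) -> ExcitabilityMap:
    """Mean amplitude per site over valid (non-NaN) trials.

    ``amplitudes`` has shape (lines, targets, trials).  A site with no valid
    trial is flagged (NaN mean, count 0) and excluded from the hotspot search.
    """
    n_valid = np.sum(~np.isnan(amplitudes), axis=-1)
    means = np.where(n_valid > 0,
                     np.nansum(amplitudes, axis=-1) / np.maximum(n_valid, 1),
                     np.nan)
    if (n_valid == 0).any():
        logger.warning("%d site(s) with zero valid trials flagged", int((n_valid == 0).sum()))
    return ExcitabilityMap(means, n_valid)


def find_hotspot(emap: ExcitabilityMap, grid: StimulationGrid,
                 latencies: np.ndarray | None = None) -> Hotspot:
    """Site of maximal mean amplitude; ties break to the lower (posterior)
    line index, then the lower target index, and are logged."""
    means = emap.mean_amplitude
    if np.all(np.isnan(means)):
        raise AnalysisError("all sites flagged; hotspot undefined")
    best = np.nanmax(means)
    cand = np.argwhere(means == best)
    tie = len(cand) > 1
    if tie:
        logger.info("hotspot tie between %d sites; posterior/medial site chosen", len(cand))
    k, i = cand[0]  # argwhere is row-major → lowest line, then target
    shortest = None
    if latencies is not None:
        site_lats = latencies[k, i]
        if np.any(~np.isnan(site_lats)):
            shortest = float(np.nanmin(site_lats))
    return Hotspot(int(k) + 1, int(i) + 1, grid.positions[k, i].copy(),
                   float(best), shortest, tie)


# ---------------------------------------------------------------------------
# resting motor threshold: adaptive maximum-likelihood staircase
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentModel:
    """Logistic recruitment: P(MEP >= criterion | I) = expit((I - threshold)/slope)."""

    threshold: float          # % MSO
    slope: float = 2.0        # % MSO (logistic scale)

    def __post_init__(self):
        if not (0.0 < self.threshold <= 100.0) or self.slope <= 0:
            raise AnalysisError("need 0 < threshold <= 100 and slope > 0")

    def responder(self, rng: np.random.Generator) -> Callable[[float], bool]:
        def respond(intensity: float) -> bool:
            p = 1.0 / (1.0 + np.exp(-(intensity - self.threshold) / self.slope))
            return bool(rng.random() < p)
        return respond


@dataclass
class RMTEstimate:
    threshold: float          # % MSO
    flagged: bool             # pinned at the intensity grid boundary
    intensities: list = field(default_factory=list)
    responses: list = field(default_factory=list)


def estimate_rmt_pest(responder: Callable[[float], bool], n_trials: int = 20,
                      start_intensity: float = 50.0, slope: float = 2.0,
                      grid_step: float = 1.0) -> RMTEstimate:
    """Adaptive maximum-likelihood threshold hunting.

    After each yes/no response the threshold of a fixed-slope logistic
    recruitment curve is refit by maximum likelihood over a 1 %-MSO grid
    (1–100), and the next stimulus is delivered at the running ML estimate.
    An estimate pinned at the grid boundary (e.g. an all-yes or all-no run)
    is flagged.
    """
    if n_trials < 1:
        raise AnalysisError("need at least one trial")
    thetas = np.arange(1.0, 100.0 + grid_step / 2, grid_step)
    loglik = np.zeros_like(thetas)
    intensity = float(start_intensity)
    intensities, responses = [], []
    eps = 1e-12
    for _ in range(n_trials):
        yes = bool(responder(intensity))
        intensities.append(intensity)
        responses.append(yes)
        p = 1.0 / (1.0 + np.exp(-(intensity - thetas) / slope))
        loglik += np.log(p + eps) if yes else np.log(1.0 - p + eps)
        intensity = float(thetas[int(np.argmax(loglik))])
    estimate = intensity
    flagged = estimate <= thetas[0] or estimate >= thetas[-1]
    if flagged:
        logger.warning("RMT estimate pinned at the intensity grid boundary (%.0f%% MSO)",
                       estimate)
    return RMTEstimate(estimate, flagged, intensities, responses)
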