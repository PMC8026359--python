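"""Synthetic-cohort generator.

Generates subjects, EMG mapping sessions, and paced-force-task traces with
the statistical structure the analysis pipeline assumes, calibrated by
default to the reference cohort statistics in :mod:`knobmap.calibration`.

Latent-trait model
------------------
A single standard-normal *myelin trait* ``z1`` drives every R1-coupled
quantity through Gaussian-copula loadings ``z = rho*z1 + sqrt(1-rho^2)*eps``:

* caudal/rostral precentral R1 (shared loading + anti-symmetric split, so the
  hand-knob mean R1 is an exact linear function of ``z1``),
* the hotspot *rostrality driver* ``z2`` (loading ``rho_r1_rostrality``),
  which places the true FDI hotspot along the anterior–posterior axis; the
  ADM hotspot follows ``z2`` with its own coupling,
* task-related BOLD effect size per finger (positive loadings),
* the intermovement-interval CV per finger (negative loadings).

Corticomotor latency is generated from the hotspot y-coordinate as
``latency = intercept + slope*(y - y_mean) + eps`` — more anterior hotspots
conduct later — with slope/residual calibrated to the reference y–latency
correlation.  Cortical thickness and curvature load on their own latents
(the reference data show no thickness/curvature coupling with function).

Raw-data emulation
------------------
``simulate_emg_session`` renders every trial as a stimulus-locked 10 kHz
trace: site-level expected amplitudes follow an isotropic Gaussian
excitability bump centred on the subject's true hotspot, trial amplitudes
are lognormal around the site mean, the MEP itself is a sharp-onset
biphasic sine cycle of 8 ms placed at the trial latency, on Gaussian
background noise.  ``simulate_force_trace`` renders the 1 Hz visuomotor
synchronisation task (18 movement blocks of 10 cues) as raised-cosine force
pulses with Gaussian onset jitter (SD = cv·/√2 so the intermovement-interval
CV equals the subject's target CV) and sensor clipping at 2.5 V.

Determinism: every randomness source descends from ``config.seed`` through
``numpy.random.SeedSequence([seed, subject_index, stream])`` so cohorts are
bit-reproducible and adding subjects does not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .errors import ConfigError
from .gridgeom import StimulationGrid, SulcusCurve, build_grid

MUSCLES = ("FDI", "ADM")
FINGERS = ("index", "little")   # index ↔ FDI, little ↔ ADM


# ---------------------------------------------------------------------------
# default mapping grid (an MNI-like right-hemisphere hand knob)
# ---------------------------------------------------------------------------

def default_sulcus_curve(n_points: int = 61) -> SulcusCurve:
    """A synthetic gyrus–sulcus border of the right precentral hand knob.

    30 mm long, running laterally (x 24→54 mm) at z = 66 mm with a gentle
    3 mm posterior bow at the knob's apex.
    """
    u = np.linspace(0.0, 1.0, n_points)
    x = 24.0 + 30.0 * u
    y = -23.0 - 3.0 * np.sin(np.pi * u)
    z = np.full_like(u, 66.0)
    return SulcusCurve(np.column_stack([x, y, z]))


def default_grid() -> StimulationGrid:
    return build_grid(default_sulcus_curve(), n_lines=5, n_targets=7,
                      spacing=5.0, interline=5.0)


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSubject:
    """Ground-truth state of one simulated participant."""

    subject_id: int
    latent_myelin: float                 # z1, standard normal
    roi_r1_caudal: float                 # ms^-1
    roi_r1_rostral: float
    r1_available: bool
    thickness_caudal: float              # mm
    thickness_rostral: float
    curvature_caudal: float              # mm^-1
    curvature_rostral: float
    bold_index: float                    # effect size (z)
    bold_little: float
    cv_index: float                      # target intermovement-interval CV
    cv_little: float
    rmt_true: float                      # % MSO
    true_hotspot: dict = field(default_factory=dict)   # muscle -> (x, y) mm
    true_latency: dict = field(default_factory=dict)   # muscle -> ms
    true_amplitude: dict = field(default_factory=dict) # muscle -> mV at hotspot

    @property
    def r1_mean(self) -> float:
        return 0.5 * (self.roi_r1_caudal + self.roi_r1_rostral)


def _rng(seed: int, subject: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subject, stream]))


def _couple(z: np.ndarray | float, rho: float, eps: np.ndarray | float):
    return rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps


def _lognormal_mult(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


def simulate_subject(config: GeneratorConfig, subject_index: int,
                     seed: int | None = None) -> SyntheticSubject:
    """Draw one subject from the latent-trait model (deterministic given seed)."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, subject_index, 0)

    z1 = rng.standard_normal()

    a, b, s = config.roi_split("r1")
    u = rng.standard_normal()
    r1_c = config.r1_caudal_mean + a * z1 + s * u
    r1_r = config.r1_rostral_mean + b * z1 - s * u

    at, bt, st = config.roi_split("thickness")
    zt, ut = rng.standard_normal(2)
    th_c = config.thickness_caudal_mean + at * zt + st * ut
    th_r = config.thickness_rostral_mean + bt * zt - st * ut

    ac, _, sc = config.roi_split("curvature")
    zc, uc = rng.standard_normal(2)
    cu_c = config.curvature_caudal_mean + ac * zc + sc * uc
    cu_r = config.curvature_rostral_mean + ac * zc - sc * uc

    # BOLD effect size per finger: hand-knob level loads on z1, ROI split on top
    ab_, bb_, sb_ = config.roi_split("bold")
    bold = {}
    for finger, rho in (("index", config.rho_r1_bold_index),
                        ("little", config.rho_r1_bold_little)):
        g = _couple(z1, rho, rng.standard_normal())
        ub = rng.standard_normal()
        bold[finger] = {
            "caudal": config.bold_caudal_mean + ab_ * g + sb_ * ub,
            "rostral": config.bold_rostral_mean + bb_ * g - sb_ * ub,
        }

    # timing variability: CV >= 0 enforced by a small floor
    cvs = {}
    for finger, rho in (("index", config.rho_r1_cv_index),
                        ("little", config.rho_r1_cv_little)):
        g = _couple(z1, abs(rho), rng.standard_normal())
        g = math.copysign(1.0, rho) * g
        cvs[finger] = max(1e-4, config.cv_mean + config.cv_sd * g)

    # hotspot geometry: FDI driven by the rostrality driver z2, ADM coupled to it
    z2 = _couple(z1, config.rho_r1_rostrality, rng.standard_normal())
    z2_adm = _couple(z2, config.rho_adm_coupling, rng.standard_normal())
    hot = {
        "FDI": (config.x_mean_fdi + config.x_sd_fdi * rng.standard_normal(),
                config.y_mean_fdi + config.y_sd_fdi * z2),
        "ADM": (config.x_mean_adm + config.x_sd_adm * rng.standard_normal(),
                config.y_mean_adm + config.y_sd_adm * z2_adm),
    }

    lat = {
        "FDI": (config.latency_intercept_fdi
                + config.latency_slope_fdi * (hot["FDI"][1] - config.y_mean_fdi)
                + config.latency_resid_sd_fdi * rng.standard_normal()),
        "ADM": (config.latency_intercept_adm
                + config.latency_slope_adm * (hot["ADM"][1] - config.y_mean_adm)
                + config.latency_resid_sd_adm * rng.standard_normal()),
    }

    amp = {
        "FDI": config.mep_amp_mean_fdi * _lognormal_mult(
            rng, config.mep_amp_subject_sd_fdi / config.mep_amp_mean_fdi, None),
        "ADM": config.mep_amp_mean_adm * _lognormal_mult(
            rng, config.mep_amp_subject_sd_adm / config.mep_amp_mean_adm, None),
    }

    rmt = float(np.clip(config.rmt_mean + config.rmt_sd * rng.standard_normal(),
                        5.0, 95.0))

    return SyntheticSubject(
        subject_id=subject_index, latent_myelin=float(z1),
        roi_r1_caudal=float(r1_c), roi_r1_rostral=float(r1_r),
        r1_available=True,
        thickness_caudal=float(th_c), thickness_rostral=float(th_r),
        curvature_caudal=float(cu_c), curvature_rostral=float(cu_r),
        bold_index=float(0.5 * (bold["index"]["caudal"] + bold["index"]["rostral"])),
        bold_little=float(0.5 * (bold["little"]["caudal"] + bold["little"]["rostral"])),
        cv_index=float(cvs["index"]), cv_little=float(cvs["little"]),
        rmt_true=rmt,
        true_hotspot={m: (float(x), float(y)) for m, (x, y) in hot.items()},
        true_latency={m: float(v) for m, v in lat.items()},
        true_amplitude={m: float(v) for m, v in amp.items()},
    )


# ---------------------------------------------------------------------------
# EMG sessions
# ---------------------------------------------------------------------------

def mep_template(config: GeneratorConfig) -> np.ndarray:
    """Biphasic MEP waveform, sampled at the EMG rate, unit peak-to-peak.

    One full sine period over ``mep_duration_ms``: a sharp-onset biphasic
    deflection, as compound muscle potentials present at the detection
    threshold (a slow-onset window would smear the very onset that latency
    extraction is meant to find).  The sampled waveform is rescaled so its
    discrete peak-to-peak is exactly 1.
    """
    n = int(round(config.mep_duration_ms * 1e-3 * config.emg_fs)) + 1
    u = np.linspace(0.0, 1.0, n)
    w = np.sin(2.0 * np.pi * u)
    return w / (w.max() - w.min())


def site_amplitude_surface(subject: SyntheticSubject, grid: StimulationGrid,
                           config: GeneratorConfig, muscle: str) -> np.ndarray:
    """Expected per-site MEP amplitude: isotropic Gaussian bump at the true hotspot."""
    hx, hy = subject.true_hotspot[muscle]
    pos = grid.flat_positions()
    d2 = (pos[:, 0] - hx) ** 2 + (pos[:, 1] - hy) ** 2
    return subject.true_amplitude[muscle] * np.exp(-d2 / (2.0 * config.spatial_sigma ** 2))


def simulate_site_trials(subject: SyntheticSubject, grid: StimulationGrid,
                         config: GeneratorConfig, muscle: str,
                         rng: np.random.Generator):
    """Per-trial amplitudes (mV) and latencies (ms) without waveform synthesis.

    Returns ``(amps, lats)`` of shape (n_sites, trials_per_site).  This is the
    statistical core of :func:`simulate_emg_session`; the EMG path adds the
    waveform, noise, and extraction on top.
    """
    t = config.trials_per_site
    mu = site_amplitude_surface(subject, grid, config, muscle)
    amps = mu[:, None] * _lognormal_mult(rng, config.trial_amp_cv, (grid.n_sites, t))
    lats = subject.true_latency[muscle] + config.trial_latency_jitter_sd \
        * rng.standard_normal((grid.n_sites, t))
    return amps, lats


def simulate_emg_session(subject: SyntheticSubject, grid: StimulationGrid,
                         config: GeneratorConfig, rng: np.random.Generator,
                         muscles=MUSCLES, dtype=np.float32) -> dict:
    """Render a full mapping session as stimulus-locked EMG traces.

    Returns ``{muscle: (n_sites, trials, n_samples) array}`` in mV, 10 kHz,
    spanning −pre…+post ms with the pulse at sample ``pre_ms*fs/1000``.
    A configurable fraction of trials (``artifact_rate``) is contaminated
    with baseline noise large enough to fail artifact rejection.
    """
    fs = config.emg_fs
    n_pre = int(round(config.emg_pre_ms * 1e-3 * fs))
    n_samples = n_pre + int(round(config.emg_post_ms * 1e-3 * fs))
    tmpl = mep_template(config).astype(dtype)
    out = {}
    for muscle in muscles:
        amps, lats = simulate_site_trials(subject, grid, config, muscle, rng)
        traces = rng.standard_normal((grid.n_sites, config.trials_per_site, n_samples),
                                     dtype=dtype)
        traces *= dtype(config.emg_noise_sd)
        onset = n_pre + np.round(lats * 1e-3 * fs).astype(int)
        onset = np.clip(onset, 0, n_samples - len(tmpl))
        idx = onset[..., None] + np.arange(len(tmpl))
        cur = np.take_along_axis(traces, idx, axis=-1)
        np.put_along_axis(traces, idx,
                          cur + amps[..., None].astype(dtype) * tmpl, axis=-1)
        if config.artifact_rate > 0:
            bad = rng.random((grid.n_sites, config.trials_per_site)) < config.artifact_rate
            art = rng.standard_normal((int(bad.sum()), n_pre), dtype=dtype) \
                * dtype(config.artifact_amp)
            traces[..., :n_pre][bad] += art
        out[muscle] = traces
    return out


# ---------------------------------------------------------------------------
# force traces (visuomotor synchronisation task)
# ---------------------------------------------------------------------------

@dataclass
class ForceTrace:
    """Force-sensor voltage trace of one finger's movement blocks."""

    samples: np.ndarray          # volts in [0, clip_level]
    sampling_rate: float
    cue_times: np.ndarray        # s
    block_bounds: list           # [(start, end), ...] of movement blocks, s


def simulate_force_trace(cv_target: float, config: GeneratorConfig,
                         rng: np.random.Generator) -> ForceTrace:
    """Simulate one finger's paced isometric-abduction force recording.

    One raised-cosine pulse per 1 Hz cue; onset jitter SD = ``cv_target/√2``
    per tap so consecutive-interval CV ≈ ``cv_target``; tap amplitudes are
    lognormal and clip at the sensor ceiling (2.5 V by default).
    """
    if cv_target < 0:
        raise ConfigError("cv_target must be >= 0")
    fs = config.force_fs
    block_len = config.cues_per_block * config.cue_period
    period = block_len + config.rest_block_duration
    starts = 1.0 + period * np.arange(config.n_move_blocks)
    cues = (starts[:, None] + config.cue_period * np.arange(config.cues_per_block)).ravel()
    total = starts[-1] + block_len + config.rest_block_duration
    n = int(round(total * fs))

    jitter_sd = cv_target * config.tap_jitter_scale
    onsets = cues + config.reaction_delay + jitter_sd * rng.standard_normal(cues.shape)
    amps = config.pulse_amp_mean * _lognormal_mult(rng, config.pulse_amp_cv, cues.shape)

    w = int(round(config.pulse_width * fs))
    shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(w + 1) / w))
    trace = np.zeros(n)
    idx = np.round(onsets * fs).astype(int)[:, None] + np.arange(w + 1)
    np.clip(idx, 0, n - 1, out=idx)
    np.add.at(trace, idx.ravel(), (amps[:, None] * shape).ravel())
    if config.force_noise_sd > 0:
        trace += config.force_noise_sd * rng.standard_normal(n)
    np.clip(trace, 0.0, config.clip_level, out=trace)

    half = config.cue_period / 2.0
    bounds = [(s - half, s + block_len - config.cue_period + half + config.pulse_width)
              for s in starts]
    return ForceTrace(trace, fs, cues, bounds)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """A simulated cohort: ground-truth table plus (optionally) raw data."""

    table: pd.DataFrame
    grid: StimulationGrid
    config: GeneratorConfig
    emg: dict = field(default_factory=dict)     # subject_id -> {muscle: traces}
    site: dict = field(default_factory=dict)    # subject_id -> {muscle: (amps, lats)}
    force: dict = field(default_factory=dict)   # subject_id -> {finger: ForceTrace}
    level: str = "emg"


def simulate_cohort(config: GeneratorConfig, level: str = "emg",
                    with_force: bool = True, force_fingers=FINGERS,
                    grid: StimulationGrid | None = None) -> CohortData:
    """Simulate a full cohort.

    ``level='emg'`` renders raw EMG waveforms per session (the full data the
    study would record); ``level='site'`` stops at per-trial amplitudes and
    latencies (the statistical core, ~100× cheaper); ``level='table'`` keeps
    only the ground-truth subject table.
    """
    config.validate()
    if level not in ("emg", "site", "table"):
        raise ConfigError(f"unknown simulation level {level!r}")
    grid = grid if grid is not None else default_grid()
    rows, emg, site, force = [], {}, {}, {}
    # the reference protocol lost R1 in a fixed number of subjects
    missing = set(range(config.r1_missing)) if config.r1_missing else set()
    for i in range(config.n_subjects):
        subj = simulate_subject(config, i)
        if i in missing:
            subj.r1_available = False
        rows.append(_subject_row(subj))
        if level == "emg":
            emg[i] = simulate_emg_session(subj, grid, config, _rng(config.seed, i, 1))
        elif level == "site":
            rng = _rng(config.seed, i, 1)
            site[i] = {m: simulate_site_trials(subj, grid, config, m, rng)
                       for m in MUSCLES}
        if with_force and level != "table" and force_fingers:
            rng_f = _rng(config.seed, i, 2)
            cv_by_finger = {"index": subj.cv_index, "little": subj.cv_little}
            force[i] = {f: simulate_force_trace(cv_by_finger[f], config, rng_f)
                        for f in force_fingers}
    table = pd.DataFrame(rows)
    return CohortData(table, grid, config, emg=emg, site=site, force=force, level=level)


def _subject_row(s: SyntheticSubject) -> dict:
    row = {
        "subject": s.subject_id,
        "latent_myelin": s.latent_myelin,
        "r1_caudal": s.roi_r1_caudal if s.r1_available else np.nan,
        "r1_rostral": s.roi_r1_rostral if s.r1_available else np.nan,
        "r1_mean": s.r1_mean if s.r1_available else np.nan,
        "thickness_caudal": s.thickness_caudal,
        "thickness_rostral": s.thickness_rostral,
        "curvature_caudal": s.curvature_caudal,
        "curvature_rostral": s.curvature_rostral,
        "bold_index": s.bold_index,
        "bold_little": s.bold_little,
        "cv_index_true": s.cv_index,
        "cv_little_true": s.cv_little,
        "rmt_true": s.rmt_true,
    }
    for m in MUSCLES:
        ml = m.lower()
        row[f"true_hotspot_x_{ml}"] = s.true_hotspot[m][0]
        row[f"true_hotspot_y_{ml}"] = s.true_hotspot[m][1]
        row[f"true_latency_{ml}"] = s.true_latency[m]
        row[f"true_amplitude_{ml}"] = s.true_amplitude[m]
    return row


def write_cohort(cohort: CohortData, out_dir) -> dict:
    """Write a cohort to disk: table CSV, raw traces, and a JSON manifest.

    Force traces go to per-subject ``(time, volts)`` CSVs; EMG sessions to
    NumPy ``.npy`` arrays of shape (sites, trials, samples) in mV (a
    documented columnar container; at 10 kHz a session is ~10⁶ samples per
    muscle, where CSV would be impractically large).  The manifest links
    every subject to its files and records the generator config hash.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(out / "cohort.csv", index=False)
    cohort.config.to_file(out / "generator.cfg")
    manifest = {"config_hash": cohort.config.config_hash(),
                "seed": int(cohort.config.seed), "level": cohort.level,
                "subjects": {}}
    for sid in cohort.table["subject"]:
        entry = {}
        if sid in cohort.emg:
            for m in MUSCLES:
                fname = f"subject{sid:02d}_{m.lower()}_emg.npy"
                np.save(out / fname, cohort.emg[sid][m])
                entry[f"emg_{m.lower()}"] = fname
        if sid in cohort.force:
            for f, trace in cohort.force[sid].items():
                fname = f"subject{sid:02d}_{f}_force.csv"
                t = np.arange(len(trace.samples)) / trace.sampling_rate
                pd.DataFrame({"time": t, "volts": trace.samples}).to_csv(
                    out / fname, index=False)
                bname = f"subject{sid:02d}_{f}_blocks.csv"
                pd.DataFrame(trace.block_bounds,
                             columns=["start", "end"]).to_csv(out / bname,
                                                              index=False)
                entry[f"force_{f}"] = fname
                entry[f"blocks_{f}"] = bname
        manifest["subjects"][int(sid)] = entry
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def serialize_cohort(cohort: CohortData) -> bytes:
    """Deterministic byte serialisation (for reproducibility checks)."""
    parts = [cohort.table.to_csv(index=False).encode()]
    for sid in sorted(cohort.emg):
        for m in MUSCLES:
            parts.append(np.ascontiguousarray(cohort.emg[sid][m]).tobytes())
    for sid in sorted(cohort.site):
        for m in MUSCLES:
            amps, lats = cohort.site[sid][m]
            parts.append(amps.tobytes() + lats.tobytes())
    for sid in sorted(cohort.force):
        for f in FINGERS:
            parts.append(cohort.force[sid][f].samples.tobytes())
    return b"".join(parts)
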