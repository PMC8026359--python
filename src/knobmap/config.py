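"""Generator and pipeline configuration.

:class:`GeneratorConfig` holds every tunable of the synthetic-cohort
generator.  Its defaults are calibrated so that a default cohort, pushed
through the full analysis pipeline (EMG extraction, hotspot localisation,
rostrality indexing, force-trace timing), reproduces the reference group
statistics in :mod:`knobmap.calibration`.  Printed group values map directly
onto fields (means, between-subject SDs from SEM·√n); the non-printed
couplings (latent-trait loadings, latency slope, amplitude scale) were frozen
from one run of :func:`knobmap.calibration.solve_generator_defaults`.

Configs round-trip through plain ``key = value`` text files (one ``[generator]``
section, stdlib :mod:`configparser`), so a run is fully described by a config
file plus a seed.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import calibration as _cal
from .errors import ConfigError

_REF = _cal.REFERENCE

# between-subject SDs recovered from printed SEMs
_R1_SD_CAUDAL = _cal.between_subject_sd(_REF["r1_caudal_sem"], _REF["r1_n"])
_R1_SD_ROSTRAL = _cal.between_subject_sd(_REF["r1_rostral_sem"], _REF["r1_n"])
_R1_SD_DIFF = _cal.paired_sd_diff(
    _REF["r1_caudal_mean"] - _REF["r1_rostral_mean"], _REF["r1_paired_t"], _REF["r1_n"]
)
_TH_SD_CAUDAL = _cal.between_subject_sd(_REF["thickness_caudal_sem"], _REF["n_subjects"])
_TH_SD_ROSTRAL = _cal.between_subject_sd(_REF["thickness_rostral_sem"], _REF["n_subjects"])
_TH_SD_DIFF = _cal.paired_sd_diff(
    _REF["thickness_caudal_mean"] - _REF["thickness_rostral_mean"],
    _REF["thickness_paired_t"], _REF["n_subjects"],
)
_CU_SD = _cal.between_subject_sd(_REF["curvature_caudal_sem"], _REF["n_subjects"])
_CU_SD_DIFF = _cal.paired_sd_diff(
    _REF["curvature_caudal_mean"] - _REF["curvature_rostral_mean"],
    _REF["curvature_paired_t"], _REF["n_subjects"],
)
_BO_SD_CAUDAL = _cal.between_subject_sd(_REF["bold_caudal_sem"], _REF["n_subjects"])
_BO_SD_ROSTRAL = _cal.between_subject_sd(_REF["bold_rostral_sem"], _REF["n_subjects"])
_BO_SD_DIFF = _cal.paired_sd_diff(
    _REF["bold_caudal_mean"] - _REF["bold_rostral_mean"],
    _REF["bold_paired_t"], _REF["n_subjects"],
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator.

    Units are stated per field.  All correlations must lie in [−1, 1], all
    SDs must be ≥ 0, and ``n_subjects`` ≥ 3 (:meth:`validate`).
    """

    # cohort
    n_subjects: int = 24
    seed: int = 0

    # quantitative MRI: R1 (ms^-1), caudal→rostral myelin gradient
    r1_caudal_mean: float = _REF["r1_caudal_mean"]
    r1_rostral_mean: float = _REF["r1_rostral_mean"]
    r1_caudal_sd: float = _R1_SD_CAUDAL
    r1_rostral_sd: float = _R1_SD_ROSTRAL
    r1_diff_sd: float = _R1_SD_DIFF          # SD of caudal − rostral within subject
    r1_missing: int = 4                      # subjects without usable R1 maps

    # cortical thickness (mm) and curvature (mm^-1), independent of the myelin trait
    thickness_caudal_mean: float = _REF["thickness_caudal_mean"]
    thickness_rostral_mean: float = _REF["thickness_rostral_mean"]
    thickness_caudal_sd: float = _TH_SD_CAUDAL
    thickness_rostral_sd: float = _TH_SD_ROSTRAL
    thickness_diff_sd: float = _TH_SD_DIFF
    curvature_caudal_mean: float = _REF["curvature_caudal_mean"]
    curvature_rostral_mean: float = _REF["curvature_rostral_mean"]
    curvature_sd: float = _CU_SD
    curvature_diff_sd: float = _CU_SD_DIFF

    # task-related BOLD effect size (z) in the hand-knob ROIs, per finger
    bold_caudal_mean: float = _REF["bold_caudal_mean"]
    bold_rostral_mean: float = _REF["bold_rostral_mean"]
    bold_caudal_sd: float = _BO_SD_CAUDAL
    bold_rostral_sd: float = _BO_SD_ROSTRAL
    bold_diff_sd: float = _BO_SD_DIFF

    # hotspot geometry (MNI-like mm): anterior = larger y
    y_mean_fdi: float = _REF["hotspot_y_mean_fdi"]
    y_sd_fdi: float = _cal.between_subject_sd(_REF["hotspot_y_sem_fdi"], _REF["n_subjects"])
    x_mean_fdi: float = _REF["hotspot_x_mean_fdi"]
    x_sd_fdi: float = _cal.between_subject_sd(_REF["hotspot_x_sem_fdi"], _REF["n_subjects"])
    y_mean_adm: float = _REF["hotspot_y_mean_adm"]
    y_sd_adm: float = _cal.between_subject_sd(_REF["hotspot_y_sem_adm"], _REF["n_subjects"])
    x_mean_adm: float = _REF["hotspot_x_mean_adm"]
    x_sd_adm: float = _cal.between_subject_sd(_REF["hotspot_x_sem_adm"], _REF["n_subjects"])

    # corticomotor latency model: latency = intercept + slope·(y − y_mean) + ε
    # (intercepts carry a small calibrated offset so the *extracted shortest*
    # latency, an extremum statistic, lands on the reference mean)
    latency_intercept_fdi: float = 22.99   # ms, calibrated (see calibration module)
    latency_intercept_adm: float = 23.21
    latency_slope_fdi: float = 0.225       # ms per mm, calibrated to r = 0.697
    latency_slope_adm: float = 0.167       # calibrated to r = 0.555
    latency_resid_sd_fdi: float = 0.95     # ms
    latency_resid_sd_adm: float = 1.14
    trial_latency_jitter_sd: float = 0.3   # ms, within-subject trial jitter

    # latent-trait couplings (Gaussian copula loadings on the myelin trait)
    rho_r1_rostrality: float = 0.811        # myelin → FDI spatial driver, calibrated
    rho_adm_coupling: float = 0.97         # FDI driver → ADM driver, calibrated
    rho_r1_bold_index: float = 0.664        # calibrated to r = 0.659 at n = 20
    rho_r1_bold_little: float = 0.757       # calibrated to r = 0.748
    rho_r1_cv_index: float = -0.656         # calibrated to r = −0.619
    rho_r1_cv_little: float = -0.737        # calibrated to r = −0.684

    # MEP amplitude model
    mep_amp_mean_fdi: float = 1.165         # mV at the true hotspot, calibrated so the
    mep_amp_mean_adm: float = 0.508         # extracted hotspot mean lands on 1.11 / 0.50
    mep_amp_subject_sd_fdi: float = _cal.between_subject_sd(_REF["amp_sem_fdi"], _REF["n_subjects"])
    mep_amp_subject_sd_adm: float = _cal.between_subject_sd(_REF["amp_sem_adm"], _REF["n_subjects"])
    spatial_sigma: float = 5.0             # mm, isotropic Gaussian excitability bump
    trial_amp_cv: float = 0.4              # lognormal trial-to-trial amplitude CV
    emg_noise_sd: float = 0.01             # mV, background EMG noise
    trials_per_site: int = 20
    artifact_rate: float = 0.0             # optional artifact-trial injection rate
    artifact_amp: float = 0.2              # mV, baseline contamination of injected artifacts

    # EMG acquisition
    emg_fs: float = 10_000.0               # Hz
    emg_pre_ms: float = 100.0              # trace span −pre … +post around the pulse
    emg_post_ms: float = 60.0
    mep_duration_ms: float = 8.0           # biphasic template duration

    # resting motor threshold (% MSO)
    rmt_mean: float = _REF["rmt_mean"]
    rmt_sd: float = _cal.between_subject_sd(_REF["rmt_sem"], _REF["n_subjects"])
    rmt_slope: float = 2.0                 # logistic recruitment slope, % MSO

    # force task: 1 Hz paced isometric abductions in 18 movement blocks of 10 cues
    force_fs: float = 500.0                # Hz
    n_move_blocks: int = 18
    cues_per_block: int = 10
    cue_period: float = 1.0                # s
    rest_block_duration: float = 10.0      # s between movement blocks
    pulse_width: float = 0.25              # s, raised-cosine force pulse
    pulse_amp_mean: float = 2.2            # V (lognormal across taps; clips often)
    pulse_amp_cv: float = 0.25
    reaction_delay: float = 0.15           # s, mean cue→onset delay
    clip_level: float = 2.5                # V, sensor saturation
    force_noise_sd: float = 0.005          # V
    cv_mean: float = 0.05                  # population mean intermovement-interval CV
    cv_sd: float = 0.015                   # between-subject SD of the CV
    tap_jitter_scale: float = 1.0 / math.sqrt(2.0)  # onset jitter SD = cv·scale per tap

    def validate(self) -> "GeneratorConfig":
        rhos = [self.rho_r1_rostrality, self.rho_adm_coupling,
                self.rho_r1_bold_index, self.rho_r1_bold_little,
                self.rho_r1_cv_index, self.rho_r1_cv_little]
        if any(not -1.0 <= r <= 1.0 for r in rhos):
            raise ConfigError("correlation parameters must lie in [-1, 1]")
        sds = [v for k, v in dataclasses.asdict(self).items()
               if k.endswith("_sd") or k.endswith("_cv") or k.endswith("sigma")]
        if any(s < 0 for s in sds):
            raise ConfigError("standard deviations and CVs must be >= 0")
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be >= 3")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigError("artifact_rate must be in [0, 1]")
        if self.trials_per_site < 1:
            raise ConfigError("trials_per_site must be >= 1")
        try:
            self.roi_split("r1")
            self.roi_split("thickness")
            self.roi_split("bold")
        except ValueError as exc:  # infeasible covariance → not PSD
            raise ConfigError(f"ROI covariance not positive semi-definite: {exc}") from exc
        return self

    # -- derived loadings -------------------------------------------------
    def roi_split(self, which: str):
        """Latent loadings (a, b, s) for a caudal/rostral ROI pair.

        ``caudal = mu_c + a·z + s·u``, ``rostral = mu_r + b·z − s·u`` with the
        shared trait ``z`` and split noise ``u``; see
        :func:`knobmap.calibration.solve_roi_split`.
        """
        if which == "r1":
            return _cal.solve_roi_split(self.r1_caudal_sd, self.r1_rostral_sd, self.r1_diff_sd)
        if which == "thickness":
            return _cal.solve_roi_split(self.thickness_caudal_sd, self.thickness_rostral_sd,
                                        self.thickness_diff_sd)
        if which == "bold":
            return _cal.solve_roi_split(self.bold_caudal_sd, self.bold_rostral_sd,
                                        self.bold_diff_sd)
        if which == "curvature":
            # equal marginals: a = b, s = diff_sd / 2
            s = self.curvature_diff_sd / 2.0
            a = math.sqrt(max(self.curvature_sd**2 - s * s, 0.0))
            return a, a, s
        raise ValueError(which)

    # -- (de)serialisation ------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        cp["generator"] = {k: repr(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise ConfigError(f"cannot read config file {path}")
        if "generator" not in cp:
            raise ConfigError("config file lacks a [generator] section")
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, raw in cp["generator"].items():
            if key not in fields:
                raise ConfigError(f"unknown generator option {key!r}")
            kwargs[key] = int(raw) if fields[key] == "int" else float(raw)
        return cls(**kwargs).validate()

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: generator + analysis parameters."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    output_dir: str = "knobmap_out"
    seed: int = 0
    verbosity: int = 1
    # analysis parameters (surrogates for the manual steps of the protocol)
    baseline_rms_limit: float = 0.02    # mV, artifact-rejection limit
    latency_k_sd: float = 3.0           # onset threshold, multiples of baseline SD
    latency_sustain_ms: float = 0.5     # onset must persist this long
    peak_threshold: float = 0.6         # V, force-trace peak threshold
    peak_min_distance: float = 0.4      # s
    peak_prominence_fraction: float = 1.0 / 3.0
    rmt_trials: int = 20
    rmt_response_criterion: float = 0.05  # mV

    def validate(self) -> "PipelineConfig":
        self.generator.validate()
        if self.baseline_rms_limit <= 0 or self.latency_k_sd <= 0:
            raise ConfigError("analysis thresholds must be positive")
        return self
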