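"""Parameter-recovery simulations.

These runners repeat cohort simulation + analysis many times and report how
well the pipeline recovers the population parameters the generator was
calibrated to.  Two granularities:

* :func:`recover_correlations` — cohorts at the *site* level (per-trial
  amplitudes/latencies without waveform synthesis) plus real force traces,
  for the cross-subject correlation battery.  The site level carries the
  same trial statistics the EMG extraction recovers, at ~100× the speed.
* :func:`recover_emg_marginals` — cohorts at the full EMG level, running
  artifact rejection, amplitude extraction, map building and hotspot
  localisation on rendered waveforms, for the hotspot amplitude and
  shortest-latency marginals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import mep, timing
from .config import GeneratorConfig
from .gridgeom import StimulationGrid
from .stats import pearson
from .synthcohort import (MUSCLES, default_grid, simulate_cohort,
                          simulate_emg_session, simulate_subject, _rng)
from .rostrality import rostrality_index


def measure_cohort_site_level(cohort, muscles=("FDI",), force_finger="little",
                              peak_kwargs=None) -> pd.DataFrame:
    """Measured per-subject quantities from a site-level cohort.

    Hotspot = argmax of the per-site valid-trial mean amplitude; shortest
    latency = min over that site's trials; CV from the little-finger force
    trace via peak detection.  Returns the cohort table with measured columns
    appended.
    """
    grid = cohort.grid
    peak_kwargs = peak_kwargs or {}
    rows = []
    for sid, per_muscle in cohort.site.items():
        row = {"subject": sid}
        for m in muscles:
            amps, lats = per_muscle[m]
            emap = mep.build_map(amps.reshape(grid.n_lines, grid.n_targets, -1))
            hot = mep.find_hotspot(emap, grid,
                                   lats.reshape(grid.n_lines, grid.n_targets, -1))
            ml = m.lower()
            row[f"hotspot_line_{ml}"] = hot.line_index
            row[f"hotspot_y_{ml}"] = hot.y_coordinate
            row[f"hotspot_amp_{ml}"] = hot.mean_amplitude
            row[f"shortest_latency_{ml}"] = hot.shortest_latency
        if cohort.force and force_finger:
            res = timing.analyze_force_trace(cohort.force[sid][force_finger],
                                             **peak_kwargs)
            row[f"cv_{force_finger}"] = res.cv
        rows.append(row)
    return cohort.table.merge(pd.DataFrame(rows), on="subject")


def recover_correlations(config: GeneratorConfig | None = None,
                         n_cohorts: int = 200, n_subjects: int = 20,
                         seed: int = 0, with_force: bool = True) -> pd.DataFrame:
    """Mean-sample-correlation recovery over repeated simulated cohorts.

    Per cohort (site level, all subjects with usable R1) computes the sample
    Pearson correlations the calibration targets: mean precentral R1 vs FDI
    rostrality index, detected hotspot y vs extracted shortest latency (FDI),
    R1 vs little-finger BOLD, and R1 vs the little-finger intermovement CV
    recovered from force traces.  Returns one row per cohort.
    """
    base = config or GeneratorConfig()
    out = []
    for c in range(n_cohorts):
        cfg = dataclasses.replace(base, n_subjects=n_subjects, r1_missing=0,
                                  seed=seed * 1_000_003 + c)
        cohort = simulate_cohort(cfg, level="site", with_force=with_force,
                                 force_fingers=("little",) if with_force else ())
        df = measure_cohort_site_level(cohort, muscles=("FDI",),
                                       force_finger="little" if with_force else None)
        ros = rostrality_index(pd.DataFrame({
            "subject": df["subject"], "muscle": "FDI",
            "hotspot_y": df["hotspot_y_fdi"],
            "shortest_latency": df["shortest_latency_fdi"],
            "hotspot_line": df["hotspot_line_fdi"],
        }))
        df["rostrality_fdi"] = ros["rostrality_index"].to_numpy()
        row = {
            "r1_rostrality_fdi": pearson(df["r1_mean"], df["rostrality_fdi"]).r,
            "y_latency_fdi": pearson(df["hotspot_y_fdi"], df["shortest_latency_fdi"]).r,
            "r1_bold_little": pearson(df["r1_mean"], df["bold_little"]).r,
        }
        if with_force:
            row["r1_cv_little"] = pearson(df["r1_mean"], df["cv_little"]).r
        out.append(row)
    return pd.DataFrame(out)


def recover_emg_marginals(config: GeneratorConfig | None = None,
                          n_cohorts: int = 100, n_subjects: int = 24,
                          seed: int = 0, muscles=("FDI",),
                          grid: StimulationGrid | None = None) -> pd.DataFrame:
    """EMG-level recovery of the hotspot amplitude / shortest-latency marginals.

    Simulates cohorts at the full EMG level and pushes every session through
    artifact rejection, peak-to-peak extraction, excitability-map building
    and hotspot localisation.  Returns one row per subject with the extracted
    hotspot amplitude (mV) and shortest latency (ms) per muscle.
    """
    base = config or GeneratorConfig()
    grid = grid if grid is not None else default_grid()
    rows = []
    for c in range(n_cohorts):
        cfg = dataclasses.replace(base, n_subjects=n_subjects,
                                  seed=seed * 1_000_003 + c)
        for i in range(cfg.n_subjects):
            subj = simulate_subject(cfg, i)
            traces = simulate_emg_session(subj, grid, cfg, _rng(cfg.seed, i, 1),
                                          muscles=muscles)
            row = {"cohort": c, "subject": i}
            for m in muscles:
                res = mep.analyze_session(traces[m], grid,
                                          sampling_rate=cfg.emg_fs,
                                          stimulus_index=int(round(
                                              cfg.emg_pre_ms * 1e-3 * cfg.emg_fs)))
                ml = m.lower()
                row[f"hotspot_amp_{ml}"] = res.hotspot.mean_amplitude
                row[f"shortest_latency_{ml}"] = res.hotspot.shortest_latency
            rows.append(row)
    return pd.DataFrame(rows)
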