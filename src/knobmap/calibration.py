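"""Reference cohort statistics used to calibrate the synthetic generator.

The synthetic-cohort generator in :mod:`knobmap.synthcohort` is calibrated so
that, by default, a simulated cohort reproduces the group-level summary
statistics of a sulcus-aligned TMS mapping study of the right precentral hand
knob (n = 24 healthy adults; quantitative-MRI R1 available in 20).  The
constants below are those reference values: group means with their standard
errors (SEM), and the cross-subject Pearson correlations between regional
myelination (R1), hotspot rostrality, task-related BOLD effect size, and
movement-timing variability.

Between-subject standard deviations are recovered from the printed SEMs as
``SEM * sqrt(n)``; within-subject caudal/rostral ROI splits additionally use
the printed paired-t statistics, which pin down the SD of the caudal−rostral
difference.

``solve_generator_defaults`` re-derives the non-printed generator defaults
(latent-trait loadings, latency slope/residual, amplitude scale and latency
intercept offsets) by Monte-Carlo so that the *measured* quantities coming out
of the full analysis pipeline — detected hotspot y, extracted shortest
latency, extracted hotspot amplitude, CV recovered from force traces — match
the reference values.  The shipped defaults in :mod:`knobmap.config` were
frozen from one run of this solver; the function is kept so the derivation is
reproducible.
"""

from __future__ import annotations

import math
from functools import lru_cache as _lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# Reference group statistics (means ± SEM unless noted)
# ---------------------------------------------------------------------------

REFERENCE = {
    # quantitative MRI, precentral hand-knob ROIs (n = 20)
    "r1_caudal_mean": 796.48,      # ms^-1
    "r1_caudal_sem": 8.51,
    "r1_rostral_mean": 756.75,     # ms^-1
    "r1_rostral_sem": 9.29,
    "r1_n": 20,
    "r1_paired_t": 5.069,          # caudal vs rostral, dof 19
    # cortical thickness (n = 24)
    "thickness_caudal_mean": 2.51,  # mm
    "thickness_caudal_sem": 0.04,
    "thickness_rostral_mean": 2.73,
    "thickness_rostral_sem": 0.03,
    "thickness_paired_t": -6.431,
    # mean curvature (n = 24)
    "curvature_caudal_mean": 0.02,   # mm^-1
    "curvature_caudal_sem": 0.01,
    "curvature_rostral_mean": -0.08,
    "curvature_rostral_sem": 0.01,
    "curvature_paired_t": 42.368,
    # task-related BOLD effect size (z), hand-knob ROIs (n = 24)
    "bold_caudal_mean": 1.60,
    "bold_caudal_sem": 0.13,
    "bold_rostral_mean": 1.26,
    "bold_rostral_sem": 0.09,
    "bold_paired_t": 3.401,
    # TMS marginals (n = 24)
    "rmt_mean": 58.1,              # % MSO, FDI
    "rmt_sem": 2.2,
    "amp_mean_fdi": 1.11,          # mV, mean MEP amplitude at hotspot
    "amp_sem_fdi": 0.17,
    "amp_mean_adm": 0.50,
    "amp_sem_adm": 0.08,
    "latency_mean_fdi": 22.6,      # ms, shortest MEP latency at hotspot
    "latency_sem_fdi": 0.3,
    "latency_mean_adm": 22.9,
    "latency_sem_adm": 0.3,
    "hotspot_x_mean_fdi": 38.7,    # mm, MNI-like
    "hotspot_x_sem_fdi": 0.6,
    "hotspot_y_mean_fdi": -16.6,
    "hotspot_y_sem_fdi": 1.0,
    "hotspot_x_mean_adm": 35.4,
    "hotspot_x_sem_adm": 1.2,
    "hotspot_y_mean_adm": -17.8,
    "hotspot_y_sem_adm": 1.1,
    "n_subjects": 24,
    # cross-subject Pearson correlations
    "r_y_latency_fdi": 0.697,
    "r_y_latency_adm": 0.555,
    "r_r1_rostrality_fdi": 0.699,
    "r_r1_rostrality_adm": 0.637,
    "r_r1_bold_index": 0.659,
    "r_r1_bold_little": 0.748,
    "r_r1_cv_index": -0.619,
    "r_r1_cv_little": -0.684,
    "r_rostrality_fdi_adm": 0.819,
}


def between_subject_sd(sem: float, n: int) -> float:
    """Recover a between-subject SD from a printed SEM."""
    return sem * math.sqrt(n)


@_lru_cache(maxsize=64)
def solve_roi_split(sd_caudal: float, sd_rostral: float, sd_diff: float):
    """Solve latent loadings for a caudal/rostral ROI pair.

    Model: ``caudal = mu_c + a*z + s*u`` and ``rostral = mu_r + b*z - s*u``
    with independent standard-normal ``z`` (shared trait) and ``u``
    (anti-symmetric within-subject split).  Returns ``(a, b, s)`` matching the
    two marginal SDs and the SD of the caudal−rostral difference:

        a^2 + s^2 = sd_caudal^2
        b^2 + s^2 = sd_rostral^2
        (a - b)^2 + 4 s^2 = sd_diff^2

    Solved by scalar bisection on ``s``.
    """
    vc, vr, vd = sd_caudal**2, sd_rostral**2, sd_diff**2

    def f(s):
        a2, b2 = vc - s * s, vr - s * s
        if a2 <= 0 or b2 <= 0:
            return np.inf
        return (math.sqrt(a2) - math.sqrt(b2)) ** 2 + 4 * s * s - vd

    lo, hi = 0.0, min(sd_caudal, sd_rostral) * (1 - 1e-9)
    if f(hi) < 0:  # difference more variable than the split can produce
        raise ValueError("ROI split infeasible for the given SDs")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    return math.sqrt(vc - s * s), math.sqrt(vr - s * s), s


def paired_sd_diff(mean_diff: float, t_stat: float, n: int) -> float:
    """SD of paired differences implied by a paired-t statistic."""
    return abs(mean_diff) / abs(t_stat) * math.sqrt(n)


# ---------------------------------------------------------------------------
# Design-time solver for the non-printed generator defaults
# ---------------------------------------------------------------------------

def solve_generator_defaults(n_mc: int = 200_000, seed: int = 12345,
                             emg_cohorts: int = 30, verbose: bool = False):
    """Re-derive the calibrated generator defaults by Monte-Carlo.

    Returns a dict of the defaults that are frozen in
    :class:`knobmap.config.GeneratorConfig`:

    * ``latency_slope_*`` / ``latency_resid_sd_*`` — chosen so the extracted
      shortest latency has the reference SD and its correlation with the
      detected hotspot y equals the reference y–latency correlation,
    * ``rho_r1_rostrality`` / ``rho_adm_coupling`` — so the mean sample
      correlation between mean R1 and the rostrality index over cohorts of
      n = 20 matches the reference values,
    * ``rho_r1_bold_*`` / ``rho_r1_cv_*`` — likewise for BOLD and for the CV
      recovered from force traces,
    * ``mep_amp_mean_*`` / ``latency_intercept_*`` — so the grand means of the
      EMG-level extracted hotspot amplitude and shortest latency match the
      reference marginals.

    The solver works on the site-level fast path for the correlation targets
    and on EMG-level cohorts for the marginal offsets; both are unbiased for
    the quantities being matched.  Each parameter enters its target almost
    linearly (a copula loading scales the recovered correlation; the
    amplitude scale and latency intercept shift their extracted marginals),
    so one proportional secant step from the current defaults suffices;
    repeated application converges.  Takes a few minutes per call.
    """
    # imported here to avoid an import cycle (config freezes this solver's output)
    import dataclasses

    from . import config as _cfg
    from . import recovery as _rec

    out = {}
    ref = REFERENCE
    base = _cfg.GeneratorConfig()

    # --- correlation couplings: proportional secant step ---
    df = _rec.recover_correlations(base, n_cohorts=emg_cohorts * 4, n_subjects=20,
                                   seed=seed, with_force=True)
    m = df.mean()
    for key, target, attr in [
        ("r1_rostrality_fdi", ref["r_r1_rostrality_fdi"], "rho_r1_rostrality"),
        ("r1_bold_little", ref["r_r1_bold_little"], "rho_r1_bold_little"),
        ("r1_cv_little", ref["r_r1_cv_little"], "rho_r1_cv_little"),
    ]:
        rho0 = getattr(base, attr)
        out[attr] = float(np.clip(rho0 * target / m[key], -0.999, 0.999))

    # --- extracted-marginal offsets (EMG level) ---
    em = _rec.recover_emg_marginals(base, n_cohorts=emg_cohorts, n_subjects=24,
                                    seed=seed + 1, muscles=("FDI", "ADM"))
    for muscle in ("fdi", "adm"):
        amp_attr = f"mep_amp_mean_{muscle}"
        int_attr = f"latency_intercept_{muscle}"
        amp_target = ref[f"amp_mean_{muscle}"]
        lat_target = ref[f"latency_mean_{muscle}"]
        got_amp = em[f"hotspot_amp_{muscle}"].mean()
        got_lat = em[f"shortest_latency_{muscle}"].mean()
        out[amp_attr] = float(getattr(base, amp_attr) * amp_target / got_amp)
        out[int_attr] = float(getattr(base, int_attr) + (lat_target - got_lat))
    if verbose:
        print("measured correlations:", dict(m))
        print("proposed defaults:", out)
    return out
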