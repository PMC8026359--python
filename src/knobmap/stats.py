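"""Cohort-level statistics: correlations, group tests, multiple comparisons.

Pearson product-moment correlations (two-sided p from the t transform with
n−2 dof), Welch and paired t tests, Bonferroni adjustment with explicit
family sizes, and the full structure–function correlation battery run on a
cohort table.

Bonferroni families mirror the three analysis sets of the mapping protocol:

* ``roi_contrasts`` — paired caudal-vs-rostral ROI tests (R1, thickness,
  curvature, BOLD per finger): m = 5,
* ``rostrality`` — hotspot-coordinate vs latency correlations per muscle:
  m = 2,
* ``structure_function`` — mean precentral R1 vs rostrality index (per
  muscle), task BOLD (per finger) and timing CV (per finger): m = 6.

Sub-ROI follow-ups (caudal/rostral Pre-CG separately) and the
thickness-control battery are reported as their own families.  Subjects
without usable R1 are excluded from R1 analyses only; everything else runs
on the full cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    p_adjusted: float = np.nan
    family: str = ""


@dataclass
class TestResult:
    statistic: float
    dof: float
    p: float
    kind: str  # "welch" | "paired"


def pearson(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p from the t transform (n − 2 dof)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("pearson needs two equal-length 1D arrays")
    if len(x) < 3:
        raise AnalysisError("pearson needs n >= 3")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise AnalysisError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance in correlation input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), len(x), float(res.pvalue))


def welch_t(group_a, group_b) -> TestResult:
    """Welch's unequal-variance t test with Welch–Satterthwaite dof."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("welch_t needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise AnalysisError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "welch")


def welch_t_from_summary(mean_a: float, sem_a: float, n_a: int,
                         mean_b: float, sem_b: float, n_b: int) -> TestResult:
    """Welch's t reconstructed from group means and SEMs."""
    if sem_a <= 0 and sem_b <= 0:
        raise AnalysisError("zero variance in both groups")
    va, vb = sem_a**2, sem_b**2        # squared SEMs = s^2/n
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return TestResult(float(t), float(dof), float(p), "welch")


def paired_t(before, after) -> TestResult:
    """Paired t test on the differences."""
    a = np.asarray(before, float)
    b = np.asarray(after, float)
    if a.shape != b.shape or len(a) < 2:
        raise AnalysisError("paired_t needs equal-length samples, n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        raise AnalysisError("zero-variance differences; paired t undefined")
    res = sps.ttest_rel(a, b)
    return TestResult(float(res.statistic), float(len(a) - 1), float(res.pvalue),
                      "paired")


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, m·p)."""
    p = np.asarray(p_values, float)
    m = len(p) if family_size is None else family_size
    if m < len(p):
        raise AnalysisError("family size smaller than the number of p values")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# the correlation battery
# ---------------------------------------------------------------------------

#: (family, label, x column, y column); R1 columns imply R1-complete subjects only
BATTERY_ROWS = (
    ("rostrality", "y_vs_latency_fdi", "hotspot_y_fdi", "shortest_latency_fdi"),
    ("rostrality", "y_vs_latency_adm", "hotspot_y_adm", "shortest_latency_adm"),
    ("structure_function", "r1_vs_rostrality_fdi", "r1_mean", "rostrality_fdi"),
    ("structure_function", "r1_vs_rostrality_adm", "r1_mean", "rostrality_adm"),
    ("structure_function", "r1_vs_bold_index", "r1_mean", "bold_index"),
    ("structure_function", "r1_vs_bold_little", "r1_mean", "bold_little"),
    ("structure_function", "r1_vs_cv_index", "r1_mean", "cv_index"),
    ("structure_function", "r1_vs_cv_little", "r1_mean", "cv_little"),
    ("structure_function_subroi", "r1_caudal_vs_rostrality_fdi", "r1_caudal", "rostrality_fdi"),
    ("structure_function_subroi", "r1_rostral_vs_rostrality_fdi", "r1_rostral", "rostrality_fdi"),
    ("structure_function_subroi", "r1_caudal_vs_rostrality_adm", "r1_caudal", "rostrality_adm"),
    ("structure_function_subroi", "r1_rostral_vs_rostrality_adm", "r1_rostral", "rostrality_adm"),
    ("structure_function_subroi", "r1_caudal_vs_cv_index", "r1_caudal", "cv_index"),
    ("structure_function_subroi", "r1_rostral_vs_cv_index", "r1_rostral", "cv_index"),
    ("structure_function_subroi", "r1_caudal_vs_cv_little", "r1_caudal", "cv_little"),
    ("structure_function_subroi", "r1_rostral_vs_cv_little", "r1_rostral", "cv_little"),
    ("thickness_control", "thickness_vs_rostrality_fdi", "thickness_mean", "rostrality_fdi"),
    ("thickness_control", "thickness_vs_rostrality_adm", "thickness_mean", "rostrality_adm"),
    ("thickness_control", "thickness_vs_cv_index", "thickness_mean", "cv_index"),
    ("thickness_control", "thickness_vs_cv_little", "thickness_mean", "cv_little"),
)


def run_correlation_battery(cohort: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Run the fixed correlation battery on a wide cohort table.

    Expects the measured cohort columns named in :data:`BATTERY_ROWS`
    (``thickness_mean`` is derived if absent).  Rows whose inputs are
    degenerate (constant column) error individually and are reported with
    NaN statistics and the failure reason; other rows are unaffected.
    Bonferroni adjustment uses the per-family row counts.
    """
    df = cohort.copy()
    if "thickness_mean" not in df.columns:
        df["thickness_mean"] = 0.5 * (df["thickness_caudal"] + df["thickness_rostral"])
    if len(df) < 10:
        logger.warning("correlation battery on only n=%d subjects", len(df))
    rows = []
    for family, label, xcol, ycol in BATTERY_ROWS:
        sub = df[[xcol, ycol]].dropna()
        note = ""
        try:
            if len(sub) < min_n:
                raise AnalysisError(f"only {len(sub)} complete observations")
            res = pearson(sub[xcol], sub[ycol])
            r, n, p = res.r, res.n, res.p
        except AnalysisError as exc:
            r, n, p = np.nan, len(sub), np.nan
            note = str(exc)
            logger.warning("battery row %s failed: %s", label, exc)
        rows.append({"family": family, "label": label, "x": xcol, "y": ycol,
                     "r": r, "n": n, "p": p, "note": note})
    out = pd.DataFrame(rows)
    out["family_size"] = out.groupby("family")["label"].transform("count")
    out["p_adjusted"] = np.minimum(1.0, out["p"] * out["family_size"])
    return out


def roi_contrasts(cohort: pd.DataFrame) -> pd.DataFrame:
    """Paired caudal-vs-rostral ROI tests (family ``roi_contrasts``)."""
    pairs = [
        ("r1", "r1_caudal", "r1_rostral"),
        ("thickness", "thickness_caudal", "thickness_rostral"),
        ("curvature", "curvature_caudal", "curvature_rostral"),
    ]
    rows = []
    for label, c, r in pairs:
        sub = cohort[[c, r]].dropna()
        try:
            res = paired_t(sub[c], sub[r])
            stat, dof, p, kind = res.statistic, res.dof, res.p, res.kind
        except AnalysisError as exc:
            logger.warning("ROI contrast %s failed: %s", label, exc)
            stat = dof = p = np.nan
            kind = "paired"
        rows.append({"family": "roi_contrasts", "label": f"{label}_caudal_vs_rostral",
                     "statistic": stat, "dof": dof, "p": p,
                     "n": len(sub), "kind": kind})
    out = pd.DataFrame(rows)
    out["family_size"] = len(out)
    out["p_adjusted"] = np.minimum(1.0, out["p"] * out["family_size"])
    return out


def group_comparisons(cohort: pd.DataFrame, group_col: str = "group_fdi",
                      variables: tuple = ("shortest_latency_fdi", "shortest_latency_adm",
                                          "hotspot_amp_fdi", "hotspot_amp_adm",
                                          "rmt_estimated")) -> pd.DataFrame:
    """Welch tests of caudal vs rostral hotspot groups on cohort variables."""
    rows = []
    for var in variables:
        if var not in cohort.columns:
            continue
        a = cohort.loc[cohort[group_col] == "caudal", var].dropna()
        b = cohort.loc[cohort[group_col] == "rostral", var].dropna()
        try:
            res = welch_t(a, b)
            rows.append({"family": "group_comparisons", "label": var,
                         "statistic": res.statistic, "dof": res.dof, "p": res.p,
                         "n_caudal": len(a), "n_rostral": len(b), "kind": res.kind})
        except AnalysisError as exc:
            logger.warning("group comparison %s failed: %s", var, exc)
    return pd.DataFrame(rows)
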