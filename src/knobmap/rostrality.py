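"""Spatiotemporal rostrality of the precentral motor hotspot.

For each muscle, a subject's hotspot is characterised by a spatial measure
(the anterior–posterior y-coordinate; anterior = larger y in the MNI-like
frame) and a temporal measure (the shortest MEP latency at the hotspot).
Each measure is min–max normalised across the cohort *within muscle* — 0 for
the most posterior hotspot / shortest latency, 1 for the most anterior /
longest — and the two normalised values are multiplied, giving the
muscle- and subject-specific spatiotemporal rostrality index in [0, 1].

Subjects are assigned to the *caudal* hotspot group when the hotspot lies on
one of the two posterior grid lines (1–2, next to the central sulcus) and to
the *rostral* group for the three anterior lines (3–5).

A cohort in which all subjects share the same extreme (max = min) leaves the
index undefined; this raises rather than silently returning 0 or 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError

CAUDAL_LINES = (1, 2)
ROSTRAL_LINES = (3, 4, 5)


def minmax_normalize(values) -> np.ndarray:
    """Scale values to [0, 1] as (v − min) / (max − min), cohort-wide."""
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 2:
        raise AnalysisError("min-max normalisation needs at least 2 values")
    if np.any(~np.isfinite(v)):
        raise AnalysisError("non-finite values in min-max normalisation")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise AnalysisError("degenerate cohort: max equals min, index undefined")
    return (v - lo) / (hi - lo)


def assign_group(hotspot_line: int) -> str:
    """'caudal' for grid lines 1–2 (posterior), 'rostral' for lines 3–5."""
    if hotspot_line in CAUDAL_LINES:
        return "caudal"
    if hotspot_line in ROSTRAL_LINES:
        return "rostral"
    raise InputError(f"hotspot line must be 1-5, got {hotspot_line}")


def rostrality_index(inputs: pd.DataFrame) -> pd.DataFrame:
    """Compute per-subject rostrality indices and group labels.

    ``inputs`` is long-format with columns ``subject``, ``muscle``,
    ``hotspot_y`` (mm, anterior = larger), ``shortest_latency`` (ms) and
    ``hotspot_line`` (1–5).  Normalisation runs within muscle across the
    whole cohort.  Returns the frame with ``normalized_y``,
    ``normalized_latency``, ``rostrality_index`` and ``group`` appended.
    """
    required = {"subject", "muscle", "hotspot_y", "shortest_latency", "hotspot_line"}
    missing = required - set(inputs.columns)
    if missing:
        raise InputError(f"rostrality input lacks columns {sorted(missing)}")
    out = inputs.copy()
    out["normalized_y"] = np.nan
    out["normalized_latency"] = np.nan
    for muscle, idx in out.groupby("muscle").groups.items():
        sub = out.loc[idx]
        if len(sub) < 2:
            raise AnalysisError(f"need >= 2 subjects per muscle (muscle {muscle!r})")
        lat = sub["shortest_latency"].to_numpy(float)
        if np.any((lat < 10.0) | (lat > 40.0)):
            raise InputError("latencies outside the 10-40 ms window")
        out.loc[idx, "normalized_y"] = minmax_normalize(sub["hotspot_y"])
        out.loc[idx, "normalized_latency"] = minmax_normalize(lat)
    out["rostrality_index"] = out["normalized_y"] * out["normalized_latency"]
    out["group"] = [assign_group(int(l)) for l in out["hotspot_line"]]
    return out
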