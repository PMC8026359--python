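# knobmap

Multimodal motor mapping of the precentral hand knob: a tested Python
pipeline for **sulcus-aligned TMS mapping** and the measures that surround it
— stimulation-grid geometry, MEP extraction, hotspot rostrality, paced
movement timing, and cohort-level structure–function statistics — exercised
end-to-end on a **calibrated synthetic-cohort generator**.

## The scientific problem

The precentral "hand knob" houses both the primary motor hand area (M1_HAND,
caudally, facing the central sulcus) and caudal dorsal premotor cortex (PMd,
rostrally, on the gyral crown). Where exactly TMS excites the corticomotor
output varies between people along this caudo-rostral axis, and that
variation tracks cortical microstructure: more heavily myelinated precentral
cortex (higher quantitative-MRI R1 = 1/T1) goes with more rostral, later-
conducting hotspots, stronger task-related BOLD responses, and more precise
movement timing. Testing those relationships requires several non-trivial
ingredients this package implements:

* **Sulcus-aligned grid geometry** (`knobmap.gridgeom`) — a 5 × 7 target
  grid anchored to the digitized gyrus–sulcus border: 7 equidistant targets
  (5 mm apart) per line, 5 lines at 5 mm anterior offsets following the
  local curve shape, coil orientation at every site perpendicular to the
  local gyral curvature (posterior→anterior second-phase current).
* **MEP extraction** (`knobmap.mep`) — from stimulus-locked EMG (10 kHz):
  artifact rejection by pre-stimulus RMS, peak-to-peak amplitude in the
  10–40 ms window, onset latency (3 × baseline-SD crossing sustained
  0.5 ms), per-site mean-amplitude excitability maps, hotspot = site of
  maximal mean amplitude with its shortest valid latency, and adaptive
  maximum-likelihood estimation of the resting motor threshold (fixed-slope
  logistic refit on a 1 %-MSO grid after every response).
* **Spatiotemporal rostrality index** (`knobmap.rostrality`) — per muscle,
  min–max-normalise the hotspot y-coordinate and the shortest MEP latency
  across the cohort (0 = most posterior / fastest, 1 = most anterior /
  slowest) and multiply:
  `index = norm(y) × norm(latency) ∈ [0, 1]`. Hotspots on grid lines 1–2
  form the *caudal* group, lines 3–5 the *rostral* group.
* **Movement timing** (`knobmap.timing`) — force traces from 1 Hz-paced
  isometric finger abductions (500 Hz, 0–2.5 V with saturation): peaks above
  0.6 V, ≥ 400 ms apart, topographic prominence ≥ ⅓ of the trace maximum;
  intermovement intervals within movement blocks; CV = SD/mean.
* **Cohort statistics** (`knobmap.stats`) — Pearson correlations (two-sided
  p via the t transform, n − 2 dof), Welch and paired t tests, Bonferroni
  correction per analysis family, and the fixed structure–function battery
  (R1 vs rostrality / BOLD / CV, plus sub-ROI and thickness-control rows).
* **Synthetic cohorts** (`knobmap.synthcohort`) — no raw data are publicly
  deposited for this kind of study, so the package ships a generator whose
  single latent "myelin trait" drives R1, hotspot rostrality, BOLD, and
  (negatively) timing CV through Gaussian-copula loadings, renders raw EMG
  sessions and force traces, and is calibrated so the *analysed* synthetic
  data reproduce the reference group statistics (see
  `knobmap.calibration.REFERENCE`): caudal/rostral Pre-CG R1
  796.48/756.75 ms⁻¹, hotspot FDI amplitude 1.11 mV, shortest FDI latency
  22.6 ms, RMT 58.1 % MSO, and the cross-subject correlations
  r ≈ 0.70 (R1–rostrality), 0.70 (y–latency), 0.75 (R1–BOLD little),
  −0.68 (R1–CV little).

## Worked example

```python
import pandas as pd
from knobmap import rostrality_index

cohort = pd.DataFrame({
    "subject": [0, 1, 2], "muscle": "FDI",
    "hotspot_y": [-22.0, -16.0, -13.0],
    "shortest_latency": [21.5, 22.6, 23.4],
    "hotspot_line": [1, 3, 4],
})
print(rostrality_index(cohort)[["subject", "normalized_y",
                                "normalized_latency", "rostrality_index",
                                "group"]].to_string(index=False))
```

prints

```
 subject  normalized_y  normalized_latency  rostrality_index   group
       0      0.000000            0.000000          0.000000  caudal
       1      0.666667            0.578947          0.385965 rostral
       2      1.000000            1.000000          1.000000 rostral
```

Subject 0 holds both cohort minima (most posterior hotspot, shortest
latency) → index 0; subject 2 holds both maxima → index 1; subject 1 scores
0.667 × 0.579 = 0.386. The `examples/` directory has one short script per
capability (grid building, MEP extraction, rostrality, movement timing, and
a full synthetic-study reproduction), each printing the numbers it computes.

A thin CLI wraps the same functions:

```bash
knobmap reproduce --subjects 24 --seed 1 --out out/   # full synthetic study
knobmap grid --curve curve.csv --out grid.csv
knobmap rostrality --cohort cohort_long.csv
```

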