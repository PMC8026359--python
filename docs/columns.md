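# Cohort table column dictionary

One row per subject. Coordinates are MNI-like millimetres with **anterior =
larger y**; muscles: FDI (index finger) / ADM (little finger); fingers map
to muscles as index ↔ FDI, little ↔ ADM. `*_fdi` / `*_adm` columns exist for
both muscles, `*_index` / `*_little` for both fingers.

## Ground truth (written by the generator)

| column | units | meaning |
| --- | --- | --- |
| `subject` | – | subject index within the cohort |
| `latent_myelin` | z | the latent myelin trait driving all couplings |
| `r1_caudal`, `r1_rostral` | ms⁻¹ | mean R1 of the caudal / rostral Pre-CG ROI (NaN when the subject's quantitative MRI is unusable) |
| `r1_mean` | ms⁻¹ | hand-knob mean R1, (caudal + rostral)/2 |
| `thickness_caudal`, `thickness_rostral` | mm | ROI cortical thickness |
| `curvature_caudal`, `curvature_rostral` | mm⁻¹ | ROI mean curvature |
| `bold_index`, `bold_little` | z | task-related BOLD effect size per finger (hand-knob ROI mean) |
| `cv_index_true`, `cv_little_true` | – | generative intermovement-interval CV per finger |
| `rmt_true` | % MSO | generative resting motor threshold |
| `true_hotspot_x_*`, `true_hotspot_y_*` | mm | generative hotspot centre per muscle |
| `true_latency_*` | ms | generative corticomotor latency per muscle |
| `true_amplitude_*` | mV | generative MEP amplitude at the hotspot per muscle |

## Measured (appended by the analysis pipeline)

| column | units | meaning |
| --- | --- | --- |
| `hotspot_line_*`, `hotspot_target_*` | 1–5 / 1–7 | detected hotspot grid indices (line 1 = most posterior) |
| `hotspot_y_*` | mm | y-coordinate of the detected hotspot site |
| `hotspot_amp_*` | mV | mean peak-to-peak MEP amplitude at the hotspot |
| `shortest_latency_*` | ms | minimum valid MEP onset latency at the hotspot |
| `rmt_estimated` | % MSO | adaptive maximum-likelihood threshold estimate |
| `cv_index`, `cv_little` | – | intermovement-interval CV recovered from the force traces |
| `rostrality_*` | 0–1 | spatiotemporal rostrality index per muscle |
| `group_*` | caudal/rostral | hotspot group (lines 1–2 vs 3–5) per muscle |

## Long-format rostrality table (`rostrality.csv`)

`subject`, `muscle`, `hotspot_y`, `shortest_latency`, `hotspot_line` →
`normalized_y`, `normalized_latency`, `rostrality_index`, `group`.
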