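"""Movement-timing variability from a paced force trace.

Simulates the 1 Hz visuomotor synchronisation task for one finger (18
movement blocks of 10 cues, 500 Hz force sensor clipping at 2.5 V), detects
movement peaks (threshold 0.6 V, min distance 400 ms, prominence one third
of the trace maximum), and reports the intermovement-interval CV.
"""

from knobmap import GeneratorConfig, analyze_force_trace, simulate_force_trace
from knobmap.synthcohort import _rng

config = GeneratorConfig()
cv_target = 0.05  # a subject of average timing precision

trace = simulate_force_trace(cv_target, config, _rng(0, 0, 2))
result = analyze_force_trace(trace)

print(f"trace: {len(trace.samples)} samples at {trace.sampling_rate:.0f} Hz, "
      f"max {trace.samples.max():.2f} V (sensor ceiling {config.clip_level} V)")
print(f"peaks detected:    {len(result.peak_times)} "
      f"({config.n_move_blocks} blocks x {config.cues_per_block} cues)")
print(f"intervals used:    {len(result.intervals)} (within blocks only)")
print(f"mean interval:     {result.mean_interval:.3f} s")
print(f"SD of intervals:   {result.sd_interval:.3f} s")
print(f"CV (SD/mean):      {result.cv:.4f}   (generative target {cv_target})")
print("\nThe CV quantifies how precisely the subject reproduces the 1 s cue "
      "period; in the cohort model lower CV accompanies higher precentral "
      "myelination (R1).")
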