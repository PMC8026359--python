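"""One-command synthetic reproduction of the mapping study.

Simulates a 24-subject cohort at the raw-data level (EMG sessions + force
traces), runs every analysis stage, and prints the summary comparing the
recovered group statistics with the generator's calibration targets.
Equivalent to ``knobmap reproduce --subjects 24 --seed 1``.
"""

from knobmap import GeneratorConfig, PipelineConfig, run_pipeline

pconf = PipelineConfig(generator=GeneratorConfig(),
                       output_dir="scratch/example_out", seed=1)
bundle = run_pipeline(pconf)

print(open(f"{bundle['output_dir']}/summary.txt").read())
print("Single-cohort sample correlations scatter around the calibration "
      "targets with SE ~0.15 at n = 20; the acceptance script averages 200 "
      "cohorts to recover them tightly.")
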