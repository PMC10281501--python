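"""The whole chain under one seeded configuration.

Runs the reduced demo configuration (three populations, smaller samples,
three predictors): simulate -> respirometry -> trait models -> thermal
optima -> environmental screen -> summary CSVs + manifest.
"""

from pathlib import Path

from salmoscope import demo_config, run_pipeline

cfg = demo_config(seed=1, out_dir="scratch/pipeline_demo")
bundle = run_pipeline(cfg)

print("stage timings (s):", bundle["manifest"].stage_seconds)
print("outputs:")
for f in sorted(Path(cfg.out_dir).iterdir()):
    print("  ", f.name)
caps = bundle["acclimation_capacity"]
print("\nacclimation capacities:")
for (trait, pop), c in sorted(caps.items()):
    print(f"  {trait:6s} {pop:14s} {c.mean:+6.3f} [{c.significance}]")
# rerunning with the same seed reproduces every CSV byte-for-byte; the
# manifest records config and input hashes for attribution.
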