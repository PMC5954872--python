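"""A small seeded benchmark: detection, cross-validation, Sens/FPI, FROC.

Generates 16 phantoms (some mass-free), runs the pipeline on each,
cross-validates the kernel extreme learning machine on the grown ROIs
and reports the pooled operating point plus the FROC curve.
"""

import masscad as mc

dataset = mc.generate_benchmark(n_images=16, normal_fraction=0.25, seed=20)
config = mc.config_for_image_size((256, 256))
result = mc.run_benchmark(dataset, config, seed=20)

n_masses = sum(len(t.mass_masks) for t in result.truths)
print(f"{len(dataset)} images, {n_masses} masses")
print(f"operating point (score threshold {result.threshold:+.2f} from the "
      f"cross-validated FROC, budget {config.fpi_budget} FP/image):")
print(f"  Sens = {result.sens:.3f}   FPI = {result.fpi:.2f}")
print("per-stage sensitivity/FPI:")
for stage, (s, f) in result.stage_metrics.items():
    print(f"  {stage:<14} Sens={s:.2f}  FPI={f:.2f}")
print("FROC operating points (FPI, Sens):")
for fpi, sens in result.froc_curve.points[:10]:
    print(f"  ({fpi:5.2f}, {sens:.3f})")
print("\nstage accounting (counts):")
cols = [c for c in result.stage_table.columns if not c.endswith("_pct")]
print(result.stage_table[cols].to_string())
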