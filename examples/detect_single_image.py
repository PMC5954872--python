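"""Run the full three-stage pipeline on one phantom and trace the stages.

Shows the monotone candidate reduction: salient patches (sensation) are
filtered by the densification and shape rules (semantic integration),
then grown into ROIs (verification happens once a classifier is
trained; without one the post-shape candidates are returned).
"""

import masscad as mc

image, truth = mc.generate(mc.PhantomSpec(seed=42, n_masses=1, density_level="F"))
config = mc.config_for_image_size(image.shape)  # K scaled to keep patch size
result = mc.detect(image, config)

print(f"{image.id}: K={config.k_clusters} clusters, "
      f"{len(result.partition.patches)} visual patches in the breast")
for stage, (n_patches, n_regions) in result.provenance.counts().items():
    print(f"  after {stage:<14} {n_patches:3d} candidate patches, "
          f"{n_regions} suspicious region(s)")

gt = truth.mass_masks[0]
for i, roi in enumerate(result.rois):
    overlap = mc.overlap_ratio(roi.mask, gt)
    print(f"ROI {i}: {len(roi.patch_ids)} patches, {roi.area} px, "
          f"covers {100 * overlap:.0f}% of the true mass")
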