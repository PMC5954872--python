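"""The two semantic rules on real patches: densification and shape.

Mass patches are homogeneous (high GLCM correlation) and compact (low
fitted-ellipse eccentricity); glandular strips are textured and
elongated. The rule thresholds 0.93 and 0.86 separate them.
"""

import numpy as np
from scipy import ndimage as ndi

import masscad as mc
from masscad.phantom import TISSUE_GLAND, TISSUE_MASS

image, truth = mc.generate(mc.PhantomSpec(seed=3, n_masses=1, density_level="G"))
config = mc.config_for_image_size(image.shape)
breast = mc.segment_breast(image)
enhanced = mc.enhance(image, breast, radius=config.enhance_radius)
opened = mc.open_with_disk(enhanced.pixels, config.opening_radius,
                           use_reconstruction=True)
saliency = mc.salient_regions(opened, breast, config.attention_threshold)
partition = mc.cluster_patches(enhanced, saliency, breast, config)

# texture is read off the lightly denoised original intensities
tissue_img = ndi.gaussian_filter(
    np.where(breast.mask, image.pixels, 0).astype(float), 1.0)

print(f"{'patch':>5} {'tissue':>7} {'dens':>6} {'ecc':>6}  verdict")
for pid, patch in sorted(partition.patches.items()):
    tl = truth.tissue_labels[patch.pixels[:, 0], patch.pixels[:, 1]]
    if (tl == TISSUE_MASS).mean() > 0.5:
        tissue = "mass"
    elif (tl == TISSUE_GLAND).mean() > 0.5:
        tissue = "gland"
    else:
        continue
    dens = mc.densification(patch, tissue_img)
    ecc = mc.patch_eccentricity(patch, partition.label_image)
    keep = dens >= config.t_dens and ecc < config.t_e
    print(f"{pid:>5} {tissue:>7} {dens:6.3f} {ecc:6.3f}  "
          f"{'kept as candidate' if keep else 'rejected'}")
print(f"\nthresholds: densification >= {config.t_dens}, "
      f"eccentricity < {config.t_e}")
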