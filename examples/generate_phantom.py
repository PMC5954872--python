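"""Render a synthetic mammographic phantom and inspect its ground truth.

The phantom carries every structure the detection pipeline keys on: a
breast half-disk, radiating glandular strips with fibrous texture, and
smooth dome-shaped masses, plus film-like correlated noise.
"""

import numpy as np

import masscad as mc

spec = mc.PhantomSpec(seed=7, n_masses=2, density_level="G", pectoral=True)
image, truth = mc.generate(spec)

print(f"image: {image.shape[0]}x{image.shape[1]}, laterality {image.laterality}")
print(f"density level: {truth.density_level} (F=fatty, G=fatty-glandular, D=dense)")
print(f"breast area: {truth.breast_mask.sum()} px "
      f"({100 * truth.breast_mask.mean():.0f}% of the frame)")
print(f"gland area:  {truth.gland_mask.sum()} px")
print(f"pectoral:    {truth.pectoral_mask.sum()} px")
for i, (mask, region) in enumerate(zip(truth.mass_masks, truth.mass_regions)):
    contrast = (image.pixels[mask].astype(float).mean()
                - np.median(image.pixels[truth.breast_mask].astype(float)))
    print(f"mass {i}: center ({region.center[0]:.0f}, {region.center[1]:.0f}), "
          f"annotation radius {region.radius:.1f} px, footprint {mask.sum()} px, "
          f"mean contrast over tissue {contrast:+.1f} gray levels")

mc.write_mammogram(image, "phantom_example.png")
print("wrote phantom_example.png (8-bit grayscale, with a laterality sidecar)")
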