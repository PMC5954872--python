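import numpy as np
import pytest

import masscad as mc
from masscad.patches import VisualPatch


@pytest.fixture(scope="session")
def phantom_pair():
    """One seeded two-mass phantom with its ground truth."""
    spec = mc.PhantomSpec(seed=11, n_masses=2, density_level="G")
    return mc.generate(spec)


@pytest.fixture(scope="session")
def phantom_pipeline(phantom_pair):
    """Preprocessed stages of the session phantom, computed once."""
    image, truth = phantom_pair
    cfg = mc.config_for_image_size(image.shape)
    breast = mc.segment_breast(image)
    enhanced = mc.enhance(image, breast, radius=cfg.enhance_radius)
    opened = mc.open_with_disk(enhanced.pixels, cfg.opening_radius)
    saliency = mc.salient_regions(opened, breast, cfg.attention_threshold)
    partition = mc.cluster_patches(enhanced, saliency, breast, cfg)
    return {
        "image": image,
        "truth": truth,
        "config": cfg,
        "breast": breast,
        "enhanced": enhanced,
        "opened": opened,
        "saliency": saliency,
        "partition": partition,
    }


def rect_patch(r0, r1, c0, c1, label=1):
    """A rectangular VisualPatch covering [r0, r1) x [c0, c1)."""
    pts = np.stack(np.mgrid[r0:r1, c0:c1], axis=-1).reshape(-1, 2)
    return VisualPatch(
        label=label,
        pixels=pts,
        centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        mean_intensity=0.0,
        area=len(pts),
    )


@pytest.fixture
def make_rect_patch():
    return rect_patch
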