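"""Densification (GLCM correlation) and shape (ellipse) rule tests.

The brute-force oracles here recount co-occurrences pixel by pixel in
plain Python and evaluate the correlation statistic directly from its
definition, independently of the vectorized implementation.
"""

import math

import numpy as np
import pytest

import masscad as mc
from masscad.errors import DegenerateShapeError
from masscad.patches import VisualPatch
from masscad.semantic import AXIAL_OFFSETS, DEFAULT_OFFSETS, glcm, glcm_correlation

from conftest import rect_patch


def brute_force_glcm(patch, image, levels, offsets, value_range=None):
    """Reference GLCM: per-pair Python loops, symmetric, normalized."""
    coords = {tuple(p) for p in patch.pixels}
    vals = np.array([image[r, c] for r, c in patch.pixels], dtype=float)
    lo, hi = (vals.min(), vals.max()) if value_range is None else value_range
    m = np.zeros((levels, levels))

    def q(v):
        if hi <= lo:
            return 0
        return min(int((v - lo) / (hi - lo) * levels), levels - 1)

    for (r, c) in coords:
        for dr, dc in offsets:
            if (r + dr, c + dc) in coords:
                a, b = q(image[r, c]), q(image[r + dr, c + dc])
                m[a, b] += 1
                m[b, a] += 1
    total = m.sum()
    if total == 0:
        m[0, 0] = 1.0
        return m
    return m / total


def brute_force_correlation(m):
    """Direct evaluation of the correlation definition."""
    levels = m.shape[0]
    u_i = sum(i * m[i, j] for i in range(levels) for j in range(levels))
    u_j = sum(j * m[i, j] for i in range(levels) for j in range(levels))
    var_i = sum(m[i, j] * (i - u_i) ** 2 for i in range(levels) for j in range(levels))
    var_j = sum(m[i, j] * (j - u_j) ** 2 for i in range(levels) for j in range(levels))
    if var_i <= 0 or var_j <= 0:
        return 1.0
    num = sum(i * j * m[i, j] for i in range(levels) for j in range(levels)) - u_i * u_j
    return num / math.sqrt(var_i * var_j)


class TestGlcm:
    def test_two_row_patch_hand_count(self):
        img = np.array([[0, 0], [255, 255]], dtype=float)
        patch = rect_patch(0, 2, 0, 2)
        m = glcm(patch, img, levels=2, offsets=((0, 1),)).matrix
        # both horizontal pairs are within one row: (0,0) and (1,1)
        assert m[0, 0] == pytest.approx(0.5)
        assert m[1, 1] == pytest.approx(0.5)
        assert m[0, 1] == 0 and m[1, 0] == 0

    def test_constant_patch_concentrates_on_one_cell(self):
        img = np.full((4, 4), 42.0)
        m = glcm(rect_patch(0, 4, 0, 4), img, levels=16).matrix
        assert m[0, 0] == pytest.approx(1.0)
        assert m.sum() == pytest.approx(1.0)

    def test_checkerboard_all_off_diagonal(self):
        img = np.indices((6, 6)).sum(axis=0) % 2 * 255.0
        m = glcm(rect_patch(0, 6, 0, 6), img, levels=2, offsets=((0, 1),)).matrix
        assert m[0, 0] == 0 and m[1, 1] == 0
        assert m[0, 1] + m[1, 0] == pytest.approx(1.0)

    def test_pairs_restricted_to_patch_pixels(self):
        img = np.zeros((6, 6))
        img[:, 3:] = 255.0  # bright half lies outside the patch
        m = glcm(rect_patch(0, 6, 0, 3), img, levels=2).matrix
        assert m[0, 0] == pytest.approx(1.0)  # no cross-boundary pairs

    def test_matches_brute_force_on_random_patches(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            h, w = rng.integers(4, 20, 2)
            img = rng.integers(0, 256, (32, 32)).astype(float)
            patch = rect_patch(0, h, 0, w)
            got = glcm(patch, img, levels=8).matrix
            want = brute_force_glcm(patch, img, 8, DEFAULT_OFFSETS)
            assert np.abs(got - want).max() < 1e-12


class TestDensification:
    def test_constant_patch_is_one_by_convention(self):
        img = np.full((8, 8), 99.0)
        assert mc.densification(rect_patch(0, 8, 0, 8), img) == 1.0

    def test_smooth_gradient_is_high(self):
        img = np.tile(np.linspace(40, 120, 24), (24, 1))
        assert mc.densification(rect_patch(0, 24, 0, 24), img) > 0.9

    def test_iid_noise_is_near_zero(self):
        # Monte-Carlo: 100 seeds, |Dens| < 0.2 in at least 99% of draws
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = rng.uniform(0, 255, (64, 64))
            d = mc.densification(rect_patch(0, 64, 0, 64), img)
            hits += abs(d) < 0.2
        assert hits >= 99

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            img = rng.integers(0, 256, (24, 24)).astype(float)
            h, w = rng.integers(4, 16, 2)
            patch = rect_patch(0, h, 0, w)
            got = mc.densification(patch, img)
            want = brute_force_correlation(
                brute_force_glcm(patch, img, 16, AXIAL_OFFSETS)
            )
            assert got == pytest.approx(want, abs=1e-9)


class TestDensificationFilter:
    def _partition_with(self, dens_values):
        """Patches of controlled densification: constant (1.0) or noise."""
        rng = np.random.default_rng(3)
        size = 8
        n = len(dens_values)
        img = np.zeros((size, size * n))
        label_image = np.zeros((size, size * n), dtype=np.int32)
        patches = {}
        for i, kind in enumerate(dens_values):
            sl = slice(i * size, (i + 1) * size)
            img[:, sl] = 100.0 if kind == "smooth" else rng.uniform(0, 255, (size, size))
            label_image[:, sl] = i + 1
            patches[i + 1] = rect_patch(0, size, i * size, (i + 1) * size, label=i + 1)
        part = mc.PatchPartition(
            label_image=label_image, patches=patches, U=set(patches)
        )
        return part, img

    def test_threshold_splits_u_and_n(self):
        part, img = self._partition_with(["smooth", "noisy"])
        mc.filter_densification(part, img, t_dens=0.93)
        assert part.U == {1}
        assert part.N == {2}

    def test_zero_threshold_keeps_nonnegative_patches(self):
        # blocky texture: positive but far-from-one correlation
        rng = np.random.default_rng(0)
        img = np.kron(rng.uniform(0, 255, (4, 4)), np.ones((2, 2)))
        part = mc.PatchPartition(
            label_image=np.ones((8, 8), dtype=np.int32),
            patches={1: rect_patch(0, 8, 0, 8)},
            U={1},
        )
        mc.filter_densification(part, img, t_dens=0.0)
        assert part.N == set()
        assert 0 < part.stats["densification"][1] < 0.93

    def test_filters_only_shrink_u(self, phantom_pipeline):
        part = phantom_pipeline["partition"]
        import copy

        part = copy.deepcopy(part)
        img = phantom_pipeline["image"].pixels.astype(float)
        u0 = set(part.U)
        mc.filter_densification(part, img)
        u1 = set(part.U)
        mc.filter_shape(part, img)
        u2 = set(part.U)
        assert u1 <= u0 and u2 <= u1
        assert part.N.isdisjoint(part.U)

    def test_mass_patches_survive_gland_patches_rejected(self, phantom_pipeline):
        """On a mass+gland phantom the rule separates the tissues."""
        import copy

        part = copy.deepcopy(phantom_pipeline["partition"])
        truth = phantom_pipeline["truth"]
        img = phantom_pipeline["image"].pixels.astype(float)
        from scipy import ndimage as ndi

        smooth = ndi.gaussian_filter(img, 1.0)
        labels = truth.tissue_labels
        gland_pids, mass_center_pids = [], []
        for pid, patch in part.patches.items():
            tl = labels[patch.pixels[:, 0], patch.pixels[:, 1]]
            frac_gland = (tl == 2).mean()
            frac_mass = (tl == 4).mean()
            if frac_gland > 0.6:
                gland_pids.append(pid)
            if frac_mass > 0.9:
                mass_center_pids.append(pid)
        part.U = set(part.patches)
        mc.filter_densification(part, smooth, t_dens=0.93)
        assert mass_center_pids, "phantom should yield mass-center patches"
        surv_mass = sum(1 for p in mass_center_pids if p in part.U)
        rej_gland = sum(1 for p in gland_pids if p in part.N)
        assert surv_mass / len(mass_center_pids) >= 0.8
        assert rej_gland / max(len(gland_pids), 1) >= 0.8


def circle_points(a, b, n=40, phi=0.0, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    xr = x * np.cos(phi) - y * np.sin(phi) + center[1]
    yr = x * np.sin(phi) + y * np.cos(phi) + center[0]
    return np.stack([yr, xr], axis=1)  # (row, col)


class TestEllipseFit:
    def test_circle_recovers_radius_and_low_eccentricity(self):
        fit = mc.fit_ellipse(circle_points(20, 20, n=50, center=(5, 7)))
        assert fit.valid
        assert fit.semi_major == pytest.approx(20, rel=5e-3)
        assert fit.semi_minor == pytest.approx(20, rel=5e-3)
        assert fit.eccentricity < 0.05

    def test_axis_aligned_ellipse_eccentricity(self):
        fit = mc.fit_ellipse(circle_points(40, 24, n=60))
        want = math.sqrt(1 - (24 / 40) ** 2)
        assert mc.eccentricity(fit) == pytest.approx(want, abs=0.01)

    @pytest.mark.parametrize("phi", [0.3, 1.0, 2.2])
    def test_rotation_invariance(self, phi):
        fit = mc.fit_ellipse(circle_points(30, 18, n=50, phi=phi, center=(50, 80)))
        assert fit.semi_major == pytest.approx(30, rel=1e-2)
        assert fit.semi_minor == pytest.approx(18, rel=1e-2)

    def test_five_points_degenerate(self):
        with pytest.raises(DegenerateShapeError):
            mc.fit_ellipse(circle_points(10, 10, n=5))

    def test_collinear_points_degenerate(self):
        pts = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
        with pytest.raises(DegenerateShapeError):
            mc.fit_ellipse(pts)

    def test_agrees_with_independent_reference_fit(self):
        """Cross-check against the image library's ellipse model."""
        from skimage.measure import EllipseModel

        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.uniform(15, 40)
            b = rng.uniform(8, a)
            phi = rng.uniform(0, np.pi)
            pts = circle_points(a, b, n=40, phi=phi, center=(60, 60))
            pts_noisy = pts + rng.normal(0, 0.05, pts.shape)
            fit = mc.fit_ellipse(pts_noisy)
            ref = EllipseModel()
            assert ref.estimate(pts_noisy[:, ::-1])  # (x, y)
            ra, rb = sorted(ref.params[2:4], reverse=True)
            assert fit.semi_major == pytest.approx(ra, rel=0.02)
            assert fit.semi_minor == pytest.approx(rb, rel=0.02)


class TestEccentricity:
    def test_circle_zero(self):
        fit = mc.fit_ellipse(circle_points(12, 12))
        assert mc.eccentricity(fit) < 0.05

    def test_closed_form_three_four_five(self):
        fit = mc.fit_ellipse(circle_points(5, 3, n=60))
        assert mc.eccentricity(fit) == pytest.approx(0.8, abs=0.01)

    def test_flat_limit_approaches_one(self):
        fit = mc.fit_ellipse(circle_points(50, 2, n=80))
        assert mc.eccentricity(fit) > 0.97

    def test_invalid_fit_counts_as_maximally_eccentric(self):
        from masscad.semantic import EllipseFit

        bad = EllipseFit(conic=(0, 0, 0, 0, 0, 0), semi_major=0, semi_minor=0,
                         eccentricity=1.0, valid=False)
        assert mc.eccentricity(bad) == 1.0


class TestShapeFilter:
    def _partition_with_shapes(self):
        """Label 1: 12x12 square block; label 2: 64x4 elongated strip."""
        label_image = np.zeros((70, 70), dtype=np.int32)
        label_image[10:22, 10:22] = 1
        label_image[30:34, 2:66] = 2
        patches = {}
        for pid in (1, 2):
            pts = np.argwhere(label_image == pid)
            patches[pid] = VisualPatch(
                label=pid,
                pixels=pts,
                centroid=tuple(pts.mean(axis=0)),
                mean_intensity=0.0,
                area=len(pts),
            )
        return mc.PatchPartition(
            label_image=label_image, patches=patches, U={1, 2}
        )

    def test_compact_kept_elongated_rejected(self):
        part = self._partition_with_shapes()
        # aspect 16:1 strip has analytic eccentricity sqrt(1-(1/16)^2) ~ 0.998
        mc.filter_shape(part, None, t_e=0.86)
        assert 1 in part.U
        assert 2 in part.N

    def test_boundary_value_is_rejected(self):
        """The rule uses >=: eccentricity exactly at the threshold fails."""
        part = self._partition_with_shapes()
        e_square = part.stats.get("eccentricity", {})
        mc.filter_shape(part, None, t_e=0.86)
        e1 = part.stats["eccentricity"][1]
        part2 = self._partition_with_shapes()
        mc.filter_shape(part2, None, t_e=e1)  # threshold == its eccentricity
        assert 1 in part2.N

    def test_eccentricity_of_patch_matches_sampled_ellipse(self):
        # rasterized disk patch: near-zero eccentricity
        rr, cc = np.mgrid[0:41, 0:41]
        inside = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
        label_image = inside.astype(np.int32)
        pts = np.argwhere(inside)
        patch = VisualPatch(label=1, pixels=pts, centroid=(20.0, 20.0),
                            mean_intensity=0.0, area=len(pts))
        assert mc.patch_eccentricity(patch, label_image) < 0.2
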