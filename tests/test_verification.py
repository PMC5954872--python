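import math

import numpy as np
import pytest
from scipy import stats as sstats

import masscad as mc
from masscad.errors import TrainingError
from masscad.patches import VisualPatch
from masscad.semantic import DEFAULT_OFFSETS
from masscad.verification import FEATURE_NAMES, N_FEATURES

from conftest import rect_patch
from test_semantic import brute_force_correlation, brute_force_glcm


def reference_features(patch, image, levels=16):
    """Straightforward per-formula recomputation of all 12 features."""
    vals = np.array([image[r, c] for r, c in patch.pixels], dtype=float)
    m = brute_force_glcm(patch, image, levels, DEFAULT_OFFSETS)
    i = np.arange(levels)[:, None].astype(float)
    j = np.arange(levels)[None, :].astype(float)
    u_i = (i * m).sum()
    u_j = (j * m).sum()
    var_i = (((i - u_i) ** 2) * m).sum()
    var_j = (((j - u_j) ** 2) * m).sum()
    hist = np.bincount(np.rint(vals).astype(int), minlength=256)
    p = hist[hist > 0] / hist.sum()
    return np.array([
        vals.mean(),
        vals.var(),
        (((i - j) ** 2) * m).sum(),
        brute_force_correlation(m),
        (m**2).sum(),
        (m / (1 + np.abs(i - j))).sum(),
        math.sqrt((var_i + var_j) / 2),
        (m / (1 + (i - j) ** 2)).sum(),
        sstats.kurtosis(vals) if vals.var() > 0 else 0.0,
        sstats.skew(vals) if vals.var() > 0 else 0.0,
        -(p * np.log2(p)).sum(),
        math.sqrt((vals**2).mean()),
    ])


class TestFeatures:
    def test_constant_patch_closed_forms(self):
        img = np.full((8, 8), 100.0)
        f = mc.extract_features(rect_patch(0, 8, 0, 8), img)
        named = dict(zip(FEATURE_NAMES, f))
        assert named["gray_mean"] == 100.0
        assert named["gray_variance"] == 0.0
        assert named["energy"] == 1.0
        assert named["entropy"] == 0.0
        assert named["kurtosis"] == 0.0
        assert named["root_mean_square"] == 100.0

    def test_two_valued_patch_hand_arithmetic(self):
        img = np.zeros((2, 8))
        img[1, :] = 255.0
        f = dict(zip(FEATURE_NAMES, mc.extract_features(rect_patch(0, 2, 0, 8), img)))
        assert f["gray_mean"] == pytest.approx(127.5)
        assert f["root_mean_square"] == pytest.approx(math.sqrt(255**2 / 2), rel=1e-6)
        assert f["entropy"] == pytest.approx(1.0)  # two equal bins

    def test_matches_reference_on_random_patches(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            img = rng.integers(0, 256, (24, 24)).astype(float)
            h, w = rng.integers(3, 16, 2)
            patch = rect_patch(0, h, 0, w)
            got = mc.extract_features(patch, img)
            want = reference_features(patch, img)
            assert np.allclose(got, want, atol=1e-9)

    def test_vector_length_and_finiteness(self, phantom_pipeline):
        part = phantom_pipeline["partition"]
        img = phantom_pipeline["image"].pixels.astype(float)
        for pid in list(part.patches)[:10]:
            f = mc.extract_features(part.patches[pid], img)
            assert f.shape == (N_FEATURES,)
            assert np.all(np.isfinite(f))


class TestGrowRois:
    def _two_patch_partition(self, gap=False):
        label_image = np.zeros((10, 20), dtype=np.int32)
        label_image[:, :10] = 1
        label_image[:, 10:] = 2
        if gap:
            label_image[:, 8:12] = 3
        patches = {}
        for pid in np.unique(label_image):
            if pid == 0:
                continue
            pts = np.argwhere(label_image == pid)
            patches[int(pid)] = VisualPatch(
                label=int(pid), pixels=pts,
                centroid=tuple(pts.mean(axis=0)),
                mean_intensity=0.0, area=len(pts),
            )
        return label_image, patches

    def test_identical_adjacent_patches_merge_features_unchanged(self):
        label_image, patches = self._two_patch_partition()
        part = mc.PatchPartition(label_image=label_image, patches=patches, U={1, 2})
        f = np.array([1.0, 2.0] + [0.0] * 10)
        rois = mc.grow_rois(part, {1: f.copy(), 2: f.copy()}, tau=1.0)
        assert len(rois) == 1
        assert rois[0].patch_ids == frozenset({1, 2})
        assert np.allclose(rois[0].features, f)

    def test_far_apart_seeds_stay_separate(self):
        label_image, patches = self._two_patch_partition(gap=True)
        part = mc.PatchPartition(label_image=label_image, patches=patches, U={1, 2})
        feats = {1: np.zeros(12), 2: np.zeros(12), 3: np.full(12, 100.0)}
        rois = mc.grow_rois(part, feats, tau=1.0)
        assert len(rois) == 2

    def test_roi_feature_is_exact_mean(self):
        # three patches in a row: two similar (merge), one far (sets the
        # feature scale and stays out)
        label_image, patches = self._two_patch_partition(gap=True)
        part = mc.PatchPartition(label_image=label_image, patches=patches, U={1})
        rng = np.random.default_rng(0)
        f1 = rng.normal(size=12)
        f2 = f1 + 0.01
        f3 = f1 + 100.0
        rois = mc.grow_rois(part, {1: f1, 3: f2, 2: f3}, tau=1.0)
        (roi,) = rois
        assert roi.patch_ids == frozenset({1, 3})
        assert np.allclose(roi.features, (f1 + f2) / 2, atol=1e-12)

    def test_max_extent_confines_growth(self):
        label_image = np.zeros((10, 50), dtype=np.int32)
        patches = {}
        for k in range(5):
            label_image[:, k * 10 : (k + 1) * 10] = k + 1
            pts = np.argwhere(label_image == k + 1)
            patches[k + 1] = VisualPatch(
                label=k + 1, pixels=pts, centroid=tuple(pts.mean(axis=0)),
                mean_intensity=0.0, area=len(pts),
            )
        part = mc.PatchPartition(label_image=label_image, patches=patches, U={1})
        feats = {pid: np.zeros(12) for pid in patches}
        rois = mc.grow_rois(part, feats, tau=1.0, max_extent=22.0)
        assert rois[0].patch_ids == frozenset({1, 2, 3})  # centroids 5, 15, 25

    def test_empty_u_empty_result(self):
        label_image, patches = self._two_patch_partition()
        part = mc.PatchPartition(label_image=label_image, patches=patches, U=set())
        assert mc.grow_rois(part, {1: np.zeros(12), 2: np.zeros(12)}) == []

    def test_mass_fragmented_into_patches_forms_one_roi(self, phantom_pipeline):
        """A phantom mass split over several patches grows into one ROI
        covering most of its footprint."""
        import copy

        part = copy.deepcopy(phantom_pipeline["partition"])
        truth = phantom_pipeline["truth"]
        cfg = phantom_pipeline["config"]
        img = phantom_pipeline["image"].pixels.astype(float)
        feats = mc.extract_all_features(part, img)
        from masscad.patches import initial_spacing

        spacing = initial_spacing(part.label_image.shape, cfg.k_clusters)
        rois = mc.grow_rois(part, feats, tau=cfg.roi_tau,
                            max_extent=cfg.roi_max_extent_spacings * spacing)
        best = max(
            mc.overlap_ratio(r.mask, truth.mass_masks[0]) for r in rois
        )
        assert best >= 0.5

    def test_roi_masks_connected(self, phantom_pipeline):
        from skimage.measure import label as cc_label
        import copy

        part = copy.deepcopy(phantom_pipeline["partition"])
        img = phantom_pipeline["image"].pixels.astype(float)
        feats = mc.extract_all_features(part, img)
        for roi in mc.grow_rois(part, feats, tau=2.0):
            assert cc_label(roi.mask, connectivity=2).max() == 1


def gaussian_clouds(separation, n=100, d=12, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, (n, d))
    x1 = rng.normal(0.0, 1.0, (n, d)) + separation / math.sqrt(d)
    x = np.vstack([x0, x1])
    y = np.array([0] * n + [1] * n)
    return x, y


class TestElm:
    def test_separable_clouds_perfect_training_accuracy(self):
        x, y = gaussian_clouds(6.0)
        model = mc.elm_train(x, y)
        labels, _ = mc.elm_predict(model, x)
        assert np.all((labels > 0) == (y == 1))

    def test_conflicting_duplicate_scores_near_zero(self):
        # an isolated point present once per class: by symmetry the
        # regularized solution averages its targets to ~0
        x, y = gaussian_clouds(6.0, n=20)
        far = x.mean(axis=0) + 50.0
        x2 = np.vstack([x, far, far])
        y2 = np.concatenate([y, [0, 1]])
        model = mc.elm_train(x2, y2)
        score = mc.elm_decision(model, far[None, :])[0]
        assert abs(score) < 0.1

    def test_large_c_interpolates_targets(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 12))
        y = np.array([0, 1] * 4)
        model = mc.elm_train(x, y, c=1e12, gamma=0.5)
        scores = mc.elm_decision(model, x)
        t = np.where(y == 1, 1.0, -1.0)
        assert np.allclose(scores, t, atol=1e-6)

    def test_support_point_of_positive_class_scores_positive(self):
        x, y = gaussian_clouds(6.0)
        model = mc.elm_train(x, y)
        assert mc.elm_decision(model, x[-1][None, :])[0] > 0

    def test_permutation_invariance(self):
        x, y = gaussian_clouds(3.0, n=40)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(x))
        m1 = mc.elm_train(x, y)
        m2 = mc.elm_train(x[perm], y[perm])
        probe = rng.normal(size=(10, 12))
        assert np.allclose(
            mc.elm_decision(m1, probe), mc.elm_decision(m2, probe), atol=1e-10
        )

    def test_single_class_rejected(self):
        x = np.zeros((10, 12))
        with pytest.raises(TrainingError):
            mc.elm_train(x, np.zeros(10))

    def test_accuracy_monotone_in_separation(self):
        accs = []
        for sep in (1.0, 3.0, 6.0):
            x, y = gaussian_clouds(sep, n=80, seed=3)
            cv = mc.crossval_10fold(x, y, seed=0, n_folds=5)
            accs.append(cv.accuracy)
        assert accs[0] <= accs[1] <= accs[2]


class TestCrossval:
    def test_balanced_folds(self):
        x, y = gaussian_clouds(6.0, n=50)
        cv = mc.crossval_10fold(x, y, seed=1)
        assert cv.n_folds == 10
        counts = np.bincount(cv.fold_of)
        assert counts.min() >= 9 and counts.max() <= 11
        for f in range(10):
            sel = cv.fold_of == f
            assert len(set(cv.targets[sel])) == 2

    def test_perfect_feature_reaches_full_accuracy(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        x = rng.normal(size=(100, 12))
        x[:, 0] = y * 10.0  # label leaked into a feature
        cv = mc.crossval_10fold(x, y, seed=0)
        assert cv.accuracy == 1.0

    def test_label_permutation_null_near_chance(self):
        """Label-permuted data: pooled CV accuracy 50% +- 10% over repeats."""
        accs = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            x = rng.normal(size=(60, 12))
            y = np.array([0, 1] * 30)
            perm = rng.permutation(60)
            cv = mc.crossval_10fold(x, y[perm], seed=rep, n_folds=5)
            accs.append(cv.accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_few_positives_reduces_folds_with_warning(self):
        x, y = gaussian_clouds(6.0, n=40)
        y = y.copy()
        y[y == 1] = 0
        y[:6] = 1  # only 6 positives
        with pytest.warns(UserWarning, match="folds"):
            cv = mc.crossval_10fold(x, y, seed=0)
        assert cv.n_folds == 6
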