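"""Stage-1b visual-patch generation.

Pixels are grouped into "visual patches" — superpixel-like basic
processing units — by an iterative local clustering on the joint
similarity index

    D_s = (mu / S) * d_xy + d_g,

where ``d_xy`` is the Euclidean distance in the image plane, ``d_g`` the
absolute gray-level difference to the cluster's mean intensity, ``mu``
the pixel-compactness weight and ``S`` a constant balancing spatial
proximity against gray distance.  K initial centers are laid out on a
regular grid of spacing g = sqrt(H*W/K); each pixel within 2g of a
center competes by minimal D_s for a fixed number of sweeps, after which
connectivity is enforced.  Patches that intersect the saliency mask
become the initial candidate-mass set U; the rest take no further part
in candidate selection (they remain in the partition and can still be
absorbed when regions are grown around candidates later).

Everything here is deterministic: identical inputs yield an identical
label image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from .attention import SaliencyMask
from .config import PipelineConfig
from .errors import ParameterError
from .io import Mammogram
from .preprocess import BreastMask


@dataclass
class VisualPatch:
    """One connected, homogeneous pixel group — the basic processing unit."""

    label: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    centroid: tuple[float, float]
    mean_intensity: float
    area: int

    def edge_points(self, label_image: np.ndarray) -> np.ndarray:
        """Boundary pixels of the patch, ordered by angle about the centroid.

        A pixel is on the boundary when one of its 4-neighbors (or the
        image edge) carries a different label.  The angular ordering is a
        convenience for consumers that expect a closed contour; the
        ellipse fit downstream is order-independent.
        """
        rows, cols = self.pixels[:, 0], self.pixels[:, 1]
        h, w = label_image.shape
        on_boundary = np.zeros(len(rows), dtype=bool)
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            nr, nc = rows + dr, cols + dc
            outside = (nr < 0) | (nr >= h) | (nc < 0) | (nc >= w)
            differs = np.ones(len(rows), dtype=bool)
            inside = ~outside
            differs[inside] = label_image[nr[inside], nc[inside]] != self.label
            on_boundary |= outside | differs
        pts = self.pixels[on_boundary]
        ang = np.arctan2(pts[:, 0] - self.centroid[0], pts[:, 1] - self.centroid[1])
        order = np.lexsort((pts[:, 1], pts[:, 0], ang))
        return pts[order]


@dataclass
class PatchPartition:
    """Label image plus the evolving candidate bookkeeping.

    ``U`` holds candidate-mass patch ids, ``N`` patches rejected by a
    semantic rule; the two never overlap.  ``stats`` accumulates
    per-patch diagnostics (densification, eccentricity) as the pipeline
    runs.
    """

    label_image: np.ndarray
    patches: dict[int, VisualPatch]
    U: set[int] = field(default_factory=set)
    N: set[int] = field(default_factory=set)
    objective_history: list[float] = field(default_factory=list)
    stats: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.U & self.N:
            raise ValueError("U and N must be disjoint")

    def move_to_N(self, patch_id: int) -> None:
        self.U.discard(patch_id)
        self.N.add(patch_id)

    def adjacency(self) -> dict[int, set[int]]:
        """Patch adjacency from the label image (4-connected boundaries)."""
        li = self.label_image
        pairs = set()
        for a, b in ((li[:, :-1], li[:, 1:]), (li[:-1, :], li[1:, :])):
            diff = (a != b) & (a > 0) & (b > 0)
            uv = np.unique(
                np.stack([a[diff], b[diff]], axis=1), axis=0
            ) if diff.any() else np.empty((0, 2), dtype=li.dtype)
            for u, v in uv:
                pairs.add((int(min(u, v)), int(max(u, v))))
        adj: dict[int, set[int]] = {pid: set() for pid in self.patches}
        for u, v in pairs:
            adj[u].add(v)
            adj[v].add(u)
        return adj


def initial_spacing(shape: tuple[int, int], k: int) -> float:
    """Grid spacing g = sqrt(H*W/K) of the initial cluster centers."""
    return math.sqrt(shape[0] * shape[1] / k)


def init_centers(
    image: np.ndarray,
    breast: BreastMask,
    k: int = 2000,
) -> np.ndarray:
    """Lay out cluster centers on a regular grid inside the breast.

    Centers start at grid nodes of spacing g, are perturbed to the
    lowest-gradient pixel of their 3x3 neighborhood (so no center sits on
    an edge), and centers outside the breast are dropped.  Returns an
    (n, 3) float array of (row, col, intensity).
    """
    if k < 4:
        raise ParameterError(f"k={k} < 4")
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    g = initial_spacing((h, w), k)
    gy, gx = np.gradient(image)
    grad = gy**2 + gx**2
    rows = np.arange(g / 2, h, g)
    cols = np.arange(g / 2, w, g)
    centers = []
    for r0 in rows:
        for c0 in cols:
            r, c = int(round(r0)), int(round(c0))
            r = min(max(r, 1), h - 2)
            c = min(max(c, 1), w - 2)
            win = grad[r - 1 : r + 2, c - 1 : c + 2]
            dr, dc = np.unravel_index(int(win.argmin()), win.shape)
            r, c = r - 1 + dr, c - 1 + dc
            if breast.mask[r, c]:
                centers.append((r, c, image[r, c]))
    return np.asarray(centers, dtype=np.float64).reshape(-1, 3)


def similarity(
    pixel_rc: tuple[float, float],
    pixel_gray: float,
    center_rc: tuple[float, float],
    center_gray: float,
    mu: float = 10.0,
    s: float = 25.0,
) -> float:
    """Similarity index D_s = (mu/S) * d_xy + d_g for one pixel/center pair."""
    d_xy = math.hypot(pixel_rc[0] - center_rc[0], pixel_rc[1] - center_rc[1])
    d_g = abs(pixel_gray - center_gray)
    return (mu / s) * d_xy + d_g


def cluster_patches(
    enhanced: Mammogram,
    saliency: SaliencyMask,
    breast: BreastMask,
    config: PipelineConfig | None = None,
) -> PatchPartition:
    """Partition the breast into visual patches and select candidates.

    Iterative local clustering on D_s (fixed number of sweeps, search
    window 2g around each center), followed by connectivity enforcement:
    each label's largest connected component keeps the label and orphan
    fragments are relabeled to the neighboring patch with the longest
    shared boundary.  Patches intersecting the saliency mask form U.
    """
    config = config or PipelineConfig()
    img = enhanced.pixels.astype(np.float64)
    h, w = img.shape
    mask = breast.mask
    centers = init_centers(img, breast, config.k_clusters)
    partition = PatchPartition(
        label_image=np.zeros((h, w), dtype=np.int32), patches={}
    )
    if len(centers) == 0 or not mask.any():
        return partition

    g = initial_spacing((h, w), config.k_clusters)
    win = max(int(round(2 * g)), 2)
    ratio = config.compactness_mu / config.balance_s

    labels = np.zeros((h, w), dtype=np.int32)
    for _ in range(config.patch_iterations):
        dist = np.full((h, w), np.inf)
        labels.fill(0)
        for idx in range(len(centers)):
            cr, cc, cg = centers[idx]
            r0, r1 = max(int(cr) - win, 0), min(int(cr) + win + 1, h)
            c0, c1 = max(int(cc) - win, 0), min(int(cc) + win + 1, w)
            sub = img[r0:r1, c0:c1]
            rr = np.arange(r0, r1, dtype=np.float64)[:, None]
            cc_ = np.arange(c0, c1, dtype=np.float64)[None, :]
            d_xy = np.sqrt((rr - cr) ** 2 + (cc_ - cc) ** 2)
            ds = ratio * d_xy + np.abs(sub - cg)
            better = (ds < dist[r0:r1, c0:c1]) & mask[r0:r1, c0:c1]
            dist[r0:r1, c0:c1] = np.where(better, ds, dist[r0:r1, c0:c1])
            lab = labels[r0:r1, c0:c1]
            lab[better] = idx + 1
        assigned = labels > 0
        partition.objective_history.append(float(dist[assigned].sum()))
        # update centers to the mean position/intensity of their pixels
        flat = labels[assigned]
        counts = np.bincount(flat, minlength=len(centers) + 1).astype(np.float64)
        rr_idx, cc_idx = np.nonzero(assigned)
        sum_r = np.bincount(flat, weights=rr_idx, minlength=len(centers) + 1)
        sum_c = np.bincount(flat, weights=cc_idx, minlength=len(centers) + 1)
        sum_g = np.bincount(flat, weights=img[assigned], minlength=len(centers) + 1)
        nonzero = counts > 0
        for k_ in np.flatnonzero(nonzero):
            if k_ == 0:
                continue
            centers[k_ - 1, 0] = sum_r[k_] / counts[k_]
            centers[k_ - 1, 1] = sum_c[k_] / counts[k_]
            centers[k_ - 1, 2] = sum_g[k_] / counts[k_]

    # some breast pixels may fall outside every search window; attach them
    # to the nearest assigned pixel's label
    unassigned = mask & (labels == 0)
    if unassigned.any():
        if (labels > 0).any():
            _, (ir, ic) = ndi.distance_transform_edt(
                labels == 0, return_indices=True
            )
            labels[unassigned] = labels[ir[unassigned], ic[unassigned]]
        else:
            labels[unassigned] = 1

    labels = _enforce_connectivity(labels)
    partition.label_image = labels

    # build patch objects
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows, cols = np.nonzero(labels)
    flat = labels[rows, cols]
    order = np.argsort(flat, kind="stable")
    flat, rows, cols = flat[order], rows[order], cols[order]
    bounds = np.searchsorted(flat, np.r_[ids, ids[-1] + 1] if len(ids) else [])
    for i, pid in enumerate(ids):
        sl = slice(bounds[i], bounds[i + 1])
        px = np.stack([rows[sl], cols[sl]], axis=1)
        vals = img[px[:, 0], px[:, 1]]
        partition.patches[int(pid)] = VisualPatch(
            label=int(pid),
            pixels=px,
            centroid=(float(px[:, 0].mean()), float(px[:, 1].mean())),
            mean_intensity=float(vals.mean()),
            area=len(px),
        )

    # candidate selection: patches touching the saliency mask enter U
    salient_ids = np.unique(labels[saliency.mask & (labels > 0)])
    partition.U = {int(i) for i in salient_ids}
    return partition


def _enforce_connectivity(labels: np.ndarray) -> np.ndarray:
    """Keep each label's largest component; merge orphans into neighbors.

    Orphan fragments are relabeled to the adjacent patch with which they
    share the longest boundary, repeating until stable.
    """
    out = labels.copy()
    for _ in range(8):
        comp = cc_label(out, background=0, connectivity=2)
        n_comp = comp.max()
        if n_comp == 0:
            return out
        # main component per label = the largest
        comp_sizes = np.bincount(comp.ravel())
        comp_to_label = np.zeros(n_comp + 1, dtype=out.dtype)
        # map each component to its label via one representative pixel
        reps_r, reps_c = _component_representatives(comp, n_comp)
        comp_to_label[1:] = out[reps_r, reps_c]
        main_comp = {}
        for cid in range(1, n_comp + 1):
            lbl = comp_to_label[cid]
            if lbl == 0:
                continue
            if (
                lbl not in main_comp
                or comp_sizes[cid] > comp_sizes[main_comp[lbl]]
            ):
                main_comp[lbl] = cid
        orphan_comps = [
            cid
            for cid in range(1, n_comp + 1)
            if comp_to_label[cid] != 0 and main_comp[comp_to_label[cid]] != cid
        ]
        if not orphan_comps:
            return out
        orphan_set = np.zeros(n_comp + 1, dtype=bool)
        orphan_set[orphan_comps] = True
        # boundary votes: count neighbor labels along 4-adjacency
        votes: dict[int, dict[int, int]] = {cid: {} for cid in orphan_comps}
        for axis in (0, 1):
            a = comp if axis == 0 else comp.T
            la = out if axis == 0 else out.T
            left, right = a[:, :-1], a[:, 1:]
            ll, lr = la[:, :-1], la[:, 1:]
            sel = (left != right)
            for oc, nl in zip(
                np.concatenate([left[sel], right[sel]]),
                np.concatenate([lr[sel], ll[sel]]),
            ):
                if orphan_set[oc] and nl > 0:
                    d = votes[int(oc)]
                    d[int(nl)] = d.get(int(nl), 0) + 1
        changed = False
        for cid in orphan_comps:
            own = int(comp_to_label[cid])
            cand = {l: c for l, c in votes[cid].items() if l != own}
            if not cand:
                continue
            best = max(sorted(cand), key=lambda l: cand[l])
            out[comp == cid] = best
            changed = True
        if not changed:
            return out
    return out


def _component_representatives(comp: np.ndarray, n_comp: int):
    """First (row-major) pixel of each component 1..n_comp."""
    flat = comp.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    first = np.searchsorted(sorted_flat, np.arange(1, n_comp + 1))
    idx = order[first]
    return np.unravel_index(idx, comp.shape)
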