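# Methods

## The detection model

`masscad` detects breast masses in digitized mammograms by a three-stage
procedure modeled on how radiologists read a film: first notice what
stands out, then apply morphological knowledge about what masses look
like, and finally verify against learned texture experience.

**Stage 0 — figure-ground segregation.** The breast is separated from
the dark background by a global Otsu threshold; of the above-threshold
components only the largest is kept (which discards bright labels and
tape marks) and its holes are filled. An optional step excises the
pectoral-muscle wedge by seeded region growing from the top chest-wall
corner, clipped by a straight-line fit to the grown boundary, with a
fail-safe: if the grown region is implausibly small (< 2% of the breast)
or large (> 40%) nothing is removed and a warning flag is set.
Mass-like structure is then enhanced as
`I + tophat(I, r) − bottomhat(I, r)` with a disk of radius `r = 30` px,
computed after filling the background with each pixel's nearest breast
value so the skin-line step does not produce a halo of width `r`, and
finally contrast-stretched so the breast spans the full 8-bit range.
The stretch makes every later threshold on normalized intensity
independent of the film's absolute exposure. Each of these steps is a
stand-in for whatever preprocessing a site already uses, and each can be
switched off in the config.

**Stage 1 — sensation.** Attention: a grayscale opening with a flat
disk (radius 6 px) levels structures narrower than a mass; the regional
maxima (8-connected plateaus with no brighter neighbour) of the opened
image mark the focal areas, and components whose peak, normalized by
255, falls below the attention threshold (0.5) are dropped. By default
the opening uses morphological reconstruction of the eroded image under
the original ("opening by reconstruction"): plain opening leaves maxima
plateaus so small that a typical mass contributes a single candidate
patch, whereas reconstruction preserves the shape of every structure
that survives erosion and yields 2–4 candidates per mass; plain opening
remains available (`use_reconstruction=False`).

Visual patches: pixels are grouped into superpixel-like units by
iterative local clustering on the similarity index

    D_s = (mu / S) · d_xy + d_g,

with `d_xy` the Euclidean image-plane distance to the cluster center,
`d_g` the absolute gray difference to the cluster's mean intensity,
`S = 25`, and 10 assignment/update sweeps in windows of twice the grid
spacing `g = sqrt(H·W/K)`. Connectivity is enforced afterwards by
merging orphan fragments into the neighbour with the longest shared
boundary. Patches that intersect the saliency mask become the candidate
set `U`; the rest remain in the partition (region growing may absorb
them later) but take no part in candidate selection.

**Stage 2 — semantic integration.** Two rules move candidates from `U`
to the reject set `N`:

* *Densification.* The homogeneity of a patch is the correlation
  statistic of its gray-level co-occurrence matrix (GLCM),
  `(Σ i·j·M(i,j) − u_i·u_j)/(σ_i·σ_j)`; candidates below
  `T_dens = 0.93` are rejected. A constant patch is perfectly
  homogeneous and scores 1 by convention.
* *Shape.* An ellipse is fitted to the patch boundary by the direct
  least-squares conic method (Fitzgibbon's constrained eigenproblem,
  with centering/scaling for conditioning); semi-axes come from the
  eigen-decomposition of the conic's quadratic part, and the
  eccentricity `E = sqrt(1 − (b/a)²)` must stay below `T_e = 0.86`.
  Degenerate boundaries (fewer than 6 points, collinear, or no ellipse
  solution) count as maximally eccentric and are rejected.

**Stage 3 — verification.** Each patch gets a 12-feature texture vector
(gray mean and variance; GLCM contrast, correlation, energy,
homogeneity, standard deviation and inverse difference moment;
histogram kurtosis, skewness, entropy; root mean square). Surviving
candidates seed a region growing over the patch adjacency graph:
neighbours join, nearest first, while their standardized feature
distance to the ROI's running mean stays within `tau = 2.5`, confined
to 1.8 initial spacings around the seed centroid. The ROI feature
vector is the unweighted mean of its member patches' vectors. A kernel
extreme learning machine — output weights `beta = (I/C + Omega)^{-1} t`
with `Omega` the RBF kernel matrix (`C = 10`, `gamma = 0.01` on
standardized features) — separates mass from normal ROIs. The kernel
variant has no random hidden layer, so training is deterministic.

**Evaluation.** A detection is a true positive when it covers more than
half a ground-truth region (intersection over ground-truth area;
intersection-over-union is available). Pooled over a dataset,
`Sens = TP marks / ground-truth regions` and `FPI = FP marks / images`,
with mass-free images counted in the FPI denominator. The FROC curve
sweeps the classifier score from the highest value down. Benchmarks are
reported at the operating point with the highest sensitivity among FROC
points within a false-positive budget (2 FP/image by default, the
conventional reporting point for mammography CAD), read off
out-of-fold scores from stratified 10-fold cross-validation so no ROI
is scored by a model that saw it.

## Which image each stage reads

Enhancement exists to drive attention; the top/bottom-hat roughly
triples noise variance, so the semantic rules and texture features read
the *original* breast-masked intensities instead, after a light
Gaussian denoise (`texture_smooth_sigma = 1` px). The correlation
statistic compares distance-1 neighbours, and unsmoothed sensor noise
would otherwise dominate it. Patch clustering does use the enhanced
image — its boundaries should follow the structures attention found.

## Parameter choices that were genuinely open

* `mu = 50` (pixel compactness). With small `mu` the clustering hugs
  iso-intensity bands so tightly that within-patch variance collapses to
  the noise floor and the homogeneity statistic of genuinely smooth
  mass patches drops to ~0.88; `mu/S = 2` keeps patches compact so the
  statistic measures tissue smoothness, not the clustering's own
  intensity-flattening.
* Densification offsets: the rule uses the two unit-distance offsets
  {(0,1), (1,0)} accumulated symmetrically. Diagonal pairs are √2
  apart and mixing them in deflates the statistic on smooth tissue by
  0.015–0.03 — enough to push real mass patches under the 0.93
  threshold. The 12-feature GLCM keeps the 4-direction
  orientation-averaged matrix.
* GLCM quantization: 16 levels over the patch's own min–max range. A
  fixed global range makes the statistic hostage to where bin
  boundaries happen to cut a smooth dome.
* Region growing: `tau` and the spatial cap are not dictated by the
  model. A pure feature-distance rule either stops at the first
  brightness step (small `tau`) or floods homogeneous background (large
  `tau`); treating an ROI as the local neighbourhood of its focal seed
  — growth confined to 1.8 patch spacings — separates the two concerns.
* Patch scale on small images: the rule thresholds are calibrated for
  the reference operating point (1024×1024 images, K = 2000, i.e.
  ~524 px per initial patch), and the homogeneity statistic depends on
  patch scale (for a smooth field it behaves like `1 − c/g²`).
  `config_for_image_size` therefore scales K with image area so patches
  keep their absolute size; on the 256×256 phantoms K = 125.

## The phantom generator

Real mammogram benchmarks cannot ship with the package, so the phantom
module renders the structures the pipeline's stages key on, at desk
scale (256×256), with exact per-layer ground truth:

* breast half-disk on a dark background, base intensity by density
  class (fatty 90, fatty-glandular 110, dense 130), with an optional
  pectoral wedge (+40) and an optional bright label artifact outside
  the breast;
* glandular strips radiating from the nipple (Gaussian ridge profile,
  +10..+35, width 4–10 px) carrying a coarse blocky fibrous texture —
  elongated *and* inhomogeneous, the two properties the semantic rules
  reject;
* masses as smooth domes (`contrast · (1 − d²)` on an elliptical
  support, axis ratio 1.0–1.6, semi-major 24–48 px, peak contrast
  +20..+60) that locally displace the glandular pattern, as a growing
  mass disrupts parenchyma; the ground-truth extent of a mass is its
  half-maximum footprint, and the annotation circle has the same area;
* a smooth zero-mean parenchymal mottle over the whole breast
  (amplitude 4 gray levels, correlation length 10 px) — the large-scale
  texture that makes every real-mammogram patch locally smooth — plus
  additive Gaussian noise (sigma 1.5) followed by a mild acquisition
  blur (0.8 px), the spatially correlated grain of digitized film.

All randomness flows through one seeded generator; a spec renders
byte-identical images. Multi-mass layouts that cannot be placed after
400 rejection-sampling tries raise an error; the benchmark generator
redraws a fresh child seed in that case.

What the phantoms deliberately do **not** model: X-ray physics,
breast-thickness falloff toward the skin line, spiculated or ill-defined
mass margins, calcifications, and real parenchymal texture families.
Passing the phantom benchmark therefore shows that the pipeline's
stages interact correctly and that each rule has the discriminative
power it claims *given* masses that are smoother and rounder than their
surroundings — it does not certify clinical performance on MIAS/DDSM,
whose headline numbers require those datasets.

## Numerical and degenerate-case conventions

* Constant image → breast segmentation fails loudly (`EmptyBreastError`);
  an empty candidate set at any later stage short-circuits to an empty,
  valid detection result.
* Constant patch → densification 1.0, variance/entropy 0, GLCM energy 1.
* Ellipse fit: points are centered and scaled before the eigenproblem;
  complex eigenpairs are truncated to their real parts; the conic's
  overall sign is normalized so an ellipse has positive quadratic part.
* Greedy TP matching consumes (roi, gt) pairs by descending overlap,
  ties broken by lower roi id then lower gt id, each side used at most
  once.
* Stage accounting tracks the attention-stage connected components
  through the pipeline (a suspicious region persists while any of its
  patches survives). Recomputing connected components of the surviving
  subset could split one region into two and break the monotone
  bookkeeping by accident of counting.
* Benchmark problem sizes: 40 images of 256×256 with ~1 mass per
  non-normal image, chosen so a full cross-validated benchmark run
  completes in well under a minute while every stage still sees dozens
  of positive and negative examples.

## Known limitations

* The sensitivity of the densification rule to patch scale means the
  Table-style thresholds only transfer to other resolutions through the
  K-scaling rule; on very small patches (< ~100 px) the statistic is
  noise-dominated.
* Pectoral removal assumes the wedge is the brightest structure touching
  the top chest-wall corner; it has no model of the pectoral edge's
  curvature.
* The ELM is trained per-benchmark; no pretrained model ships with the
  package.
* Laterality inference from the mask centroid fails on centered or
  cropped views; provide laterality explicitly in that case.
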