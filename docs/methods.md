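# Methods

This note documents the models, conventions and numerical choices behind
`glioseg`, in the order the pipeline applies them.

## Diffusion tensor estimation and the p-map

Per voxel the DWI signal is modelled mono-exponentially,
`S(b, g) = S0 · exp(−b gᵀ D g)`, and the six unique components of the
symmetric tensor `D` are estimated by **ordinary least squares on the
log-attenuations** (`dti.fit_tensor`). `S0` is the mean of the b = 0
measurements; rows of the design matrix are
`b·(gx², gy², gz², 2gxgy, 2gxgz, 2gygz)`. Choices:

- *No weighting, no positivity constraint.* The plain log-linear fit is the
  simplest estimator that is exact on noiseless data (verified to 1e-9 over
  random SPD tensors) and transparent under noise.
- *Voxels with any non-positive measurement are excluded* from the valid
  mask rather than floored — flooring injects log-domain bias silently.
- *Negative eigenvalues are retained*, only counted and logged. Clipping
  would hide noise problems from diagnostics.
- The isotropic map is **p = √3 · MD** (a multiplicative √3 on the mean
  diffusivity). The alternative reading √(3·MD) is dimensionally
  inconsistent for a diffusivity-scaled map and contradicts the convention
  of the prior p/q-decomposition literature; this is unit-tested.

The reference acquisition scheme is 1 b=0 plus 12 icosahedral directions at
b = 1000 s/mm² (`phantom.default_dwi_scheme`). The minimum usable scheme is
1 b0 + 6 independent directions; rank deficiency raises immediately.

## Preprocessing

Grey levels are min–max normalized to [0, 1] per volume (affine-invariant,
idempotent; constant images are an error). The p-map additionally gets an
**unsharp mask**, `v + a·(v − G_σ(v))` clipped back to [0, 1], with
σ = 1 voxel and gain a = 0.8 by default; both are configurable. The exact
enhancement operator applied in practice varies between sites, so the
choice is deliberately the most generic one.

The sharpened volume feeds the *clustering* stage only: the region-growing
homogeneity test (below) runs on the unsharpened normalized intensities,
because unsharp overshoot at tissue boundaries systematically displaces
rim voxels out of any fixed homogeneity band and biases the region mean.
On phantoms this separation is worth ~0.1 Dice on the p-map channel.

## Segmentation

**Fuzzy C-means** with C = 4 clusters, fuzziness m = 2 (the universal
default), convergence when the largest centroid change drops below 1e-5 or
after 300 iterations. Centroids are initialized at evenly spaced grey
levels across the intensity range. We initially used in-mask intensity
quantiles, but on whole-head images the air background holds the majority
of voxels, so two quantile centroids start inside it and the small bright
classes never acquire one; evenly spaced levels are equally deterministic
and place one centroid per brightness band. The rng seed only jitters
restarts after coincident centroids (at most 3 attempts). Membership rows
sum to 1 to 1e-9 and the objective is non-increasing; both are enforced by
tests, along with a plug-in check that the converged state satisfies the
two FCM update equations.

**Tissue roles.** Clusters ranked by centroid brightness map onto
modality-specific roles: on T2 — lesion hyper-signal; CSF + edema; normal
WM/GM/scalp; skull/background. On FLAIR — hyper; edema; normal;
CSF/skull/background (CSF is suppressed). On the p-map — hyper (cystic
core, hemorrhage **and CSF**, which is bright there); edema; normal;
background. Centroid ties break deterministically by cluster index and are
logged; membership ties go to the lower cluster index.

**Region growing.** The abnormal candidate set is the union of the hyper
and edema roles. From a user seed inside it, the connected component
(26-neighbourhood in 3D by default, configurable) is refined by
breadth-first growth: a frontier voxel is accepted when its intensity is
within `tolerance` (default 0.1 on normalized intensities) of the running
region mean, updated after every acceptance. Each voxel is examined once in
FIFO order with a fixed neighbour order, so the result is deterministic; a
brute-force flood-fill oracle reproduces it exactly in tests. Two
post-steps finish the mask:

- a **morphological closing** (1 iteration) confined to the candidate
  component, recovering isolated voxels that noise pushed out of the
  homogeneity band — confinement guarantees the closing can never leak
  outside the fuzzy-knowledge region;
- **hole filling** (all fully enclosed holes by default, size-cappable),
  which restores the necrotic/cystic core when the seed sat in the edema
  rim and the core intensity fell outside the growth band.

Without closing, permanent BFS rejection of ~2σ outliers caps phantom Dice
near 0.87 at the highest benchmark noise; with it the pipeline reaches
≥ 0.99 on all modalities. Segmentation operates on the 3D volume; the
2D per-slice convention survives in the *area* metric (below), which is
what the per-patient numbers use.

## Metrics

- Area: true-pixel count × in-plane pixel area, mm²→cm². The single
  per-patient area uses the **slice of maximal lesion extent** (the
  convention is not fixed by the source material; per-slice and total
  volume are also exposed).
- `DI = (|A∪B| − |A∩B|)/|A∪B| = 1 − Jaccard`; Dice and DI satisfy
  `dice = 2(1−DI)/(2−DI)`, used as a cross-check.
- Specificity counts true negatives **inside the brain mask only**, so the
  air background cannot inflate it.
- The third DI pair (T2 vs FLAIR) uses `|A_T2 ∪ A_F|` as denominator; one
  printed source formula carries an obvious typo in that denominator.

## Cohort analysis

Percent difference is symmetric: `100·|a−b|/max(a,b)`. A patient is
*approximately equal* when all three pairwise differences are below 5%
(checked before the orderings); otherwise p-smallest / p-largest /
in-between by strict comparison. Summaries use sample (n−1) SD; a
single-patient cohort reports SD 0 with a flag. Strict recomputation from
the packaged 25-patient table gives category counts 17/5/2/1
(smallest/largest/between/equal) — the narrative counts published alongside
that table (17/4/3/1) cannot be reproduced from its own printed areas, so
the recomputed counts are reported. Likewise the printed T2/p DI range low
(0.266) conflicts with the table's own minimum (0.258); the table is
treated as ground truth. The printed FLAIR/p mean 0.462 is a truncation of
the exact column mean 0.46276.

## Synthetic phantoms

`phantom.generate_phantom` renders an ellipsoidal head: scalp and skull
shells, brain with a cortical GM shell over WM, two CSF ventricles, and a
lesion = necrotic/cystic core + edema rim. Default grid 128×128×20 at
0.9×0.9×5 mm, so lesion areas land in the clinically reported cm² range.
Per-tissue grey levels (`INTENSITY_TABLES`) fall into exactly four
brightness groups per modality, matching the four FCM classes — including
the characteristic inversions (CSF bright on T2 and p-map, dark on FLAIR).
The **edema rim radii are drawn per modality** (nested ellipsoids), so the
three ground-truth masks disagree by construction and the DI between them
is controlled analytically (`1 − V_small/V_large` for nested rims).

Noise is Rician by default (magnitude MRI), Gaussian available for
analytic checks; σ is a fraction of the unit dynamic range. The phantom's
diffusion tensor field assigns each tissue an isotropic tensor with
`√3·MD` proportional to its p-map grey level (WM gets a prolate tensor of
equal MD), making the DWI→tensor→p-map round trip exact up to the known
scale at zero noise. This is a stylized consistency device, not a
physiological diffusivity atlas: real CSF has higher MD than cystic tumour
core, but the phantom orders p-intensities to honour the four-class
segmentation model instead.

The default benchmark suite (20 phantoms) varies lesion size, position and
noise σ ∈ [0.02, 0.06], covers all three size orderings of the p-map area
in roughly the observed cohort proportions (13/4/3), and
rejection-samples lesion placement to stay inside the brain and ≥ 2 voxels
clear of the ventricles. A green benchmark therefore establishes that the
pipeline recovers piecewise-constant lesions under moderate Rician noise
with well-separated class intensities — it does **not** establish
performance on real data with bias fields, partial-volume gradients,
infiltrative (non-ellipsoidal) margins, or inter-rater ambiguity.

## Determinism and degenerate inputs

All randomness flows through explicit integer seeds (phantom noise, FCM
restarts, DWI noise); two runs from the same config are byte-identical,
including gzipped NIfTI output. Degenerate inputs fail loudly: constant
images (normalization), empty masks and empty unions (metrics), seeds in
normal tissue (prompting reseeding), non-co-registered inputs (the
pipeline refuses; registration is out of scope), rank-deficient gradient
schemes.
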