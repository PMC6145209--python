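# glioseg

Semi-automatic delineation and comparison of postoperative hyper-signal
abnormal regions in glioblastoma across three MRI contrasts: T2-weighted,
T2-FLAIR, and the DTI-derived isotropic **p-map**.

## The problem

Glioblastoma infiltrates diffusely along white matter, so the bright
(hyper-signal) abnormality — residual tumour plus edema — has no sharp
boundary, and radiotherapy target volumes drawn on T2 or T2-FLAIR alone may
miss infiltrated tissue. Diffusion tensor imaging offers a complementary
view: the isotropic component of the diffusion tensor,

```
p = √3 · MD,      MD = (λ₁ + λ₂ + λ₃) / 3,
```

is elevated in edema and tumour-infiltrated white matter. `glioseg`
implements a full pipeline to quantify how much the abnormal regions
delineated on the three contrasts agree:

1. **DTI fitting** — log-linear least-squares estimation of the diffusion
   tensor from DWI (NIfTI + FSL-style bval/bvec), eigenvalues, mean
   diffusivity, and the p-map.
2. **Segmentation** — four-class fuzzy C-means (FCM) clustering maps
   brightness-ranked clusters onto modality-specific tissue roles; a seeded
   region-growing step restricted to the abnormal candidate classes
   extracts a single connected hyper-signal region.
3. **Comparison** — slice areas in cm², Dice score
   `DS = 2|A∩B| / (|A|+|B|)`, sensitivity/specificity against a reference
   mask, and the Discordance Index

   ```
   DI(A, B) = (|A∪B| − |A∩B|) / |A∪B|     ∈ [0, 1]
   ```

   (0 = identical regions, 1 = completely apart; `DI = 1 − Jaccard`).
4. **Cohort analysis** — per-patient size categories (p-map area smallest /
   largest / in between / approximately equal within 5%), symmetric
   difference percentages, and DI summary statistics. A 25-patient
   reference table is packaged and can be re-summarized exactly.
5. **Synthetic phantoms** — co-registered multimodal head phantoms (skull,
   scalp, grey/white matter, CSF ventricles, necrotic core + edema rim)
   with per-modality ground-truth masks and a DWI simulator, so every stage
   is testable without patient data.

Intended users: medical-imaging researchers evaluating multi-contrast
target delineation, and anyone needing a tested, deterministic
FCM + region-growing reference implementation.

## Worked example

Generate a phantom, run the full pipeline, and summarize the packaged
reference cohort:

```sh
glioseg phantom --seed 7 --n 1 --outdir ph
glioseg run --config run.toml        # paths + seed points, see below
glioseg cohort --out cohort.json
```

with `run.toml`:

```toml
brain_mask = "ph/phantom00_brain_mask.nii.gz"
output_dir = "full_run"

[volumes]
t2 = "ph/phantom00_t2.nii.gz"
flair = "ph/phantom00_flair.nii.gz"
pmap = "ph/phantom00_pmap.nii.gz"

[seeds]                 # 0-based voxel indices inside the lesion rim
t2 = [29, 77, 10]
flair = [29, 77, 10]
pmap = [28, 77, 10]
```

The run prints:

```
di_tp: di=0.377 dice=0.767 areas 1.88/1.26 cm^2
di_fp: di=0.529 dice=0.641 areas 2.37/1.26 cm^2
di_tf: di=0.243 dice=0.862 areas 1.88/2.37 cm^2
```

Reading: on this phantom the p-map abnormality (1.26 cm² on the maximal
slice) is smaller than the T2 (1.88 cm²) and FLAIR (2.37 cm²) regions, and
the discordance indices quantify the location mismatch of each pair — the
phantom draws the edema rim with a different extent per modality precisely
to emulate that clinically observed disagreement. `glioseg cohort` on the
packaged 25-patient table reports mean DI of 0.468 (T2/p), 0.463 (FLAIR/p)
and 0.423 (T2/FLAIR), with 17 patients in the p-smallest category.

Seed points are chosen by the user (any voxel inside the bright
abnormality); phantoms ship a suggested seed per modality in their
manifest. Everything is deterministic given the config and seeds.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default 20-phantom benchmark suite from the given seed,
runs the complete segmentation pipeline on all three modality channels of
every phantom, scores the results against the ground-truth masks, and
writes the suite-level summary (mean T2 Dice; worst-modality mean
sensitivity and specificity, in percent) as JSON. It takes a few minutes on
one CPU.
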