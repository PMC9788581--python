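# Methods

## The measurement model

Each patient contributes two PET/CT studies acquired within a day of each
other: a ⁶⁸Ga-PSMA-11 study and a Na¹⁸F study, each with its own CT.  All
voxel computation happens in a canonical axis-aligned frame — value at index
`(i,j,k)` sits at physical position `origin + (i,j,k)·spacing` — to which
NIfTI input is reoriented at load.  The working grid is 4 mm isotropic, the
voxel size of the clinical acquisitions this pipeline targets.

PET voxels are body-weight standardized uptake values

    SUV_bw(v) = C(v) / (A_scan / (W·1000)),
    A_scan    = A_inj · 2^(−t_uptake / t_half),

with `C` the activity concentration (Bq/mL), `W` body weight (kg), `A_inj`
the injected activity decay-corrected to scan start.  Consoles differ in
whether they decay-correct to injection or scan start; the scan-start
convention is the default here and the uptake time is a parameter, so the
alternative is `uptake_time_min = 0`.  Scanner-exported SUV volumes bypass
the conversion entirely (`value_kind` tag).

## Registration

The skeleton is rigid over consecutive days, so the NaF study is aligned to
the PSMA study (the fixed reference, by convention) with a 6-parameter rigid
transform `T(x) = R(x−c) + c + t` driven *only* by the CT bone compartment:

1. binary bone masks `HU > 150` from both CTs;
2. masks smoothed with a 6 mm Gaussian into soft masks;
3. soft-Dice overlap `2⟨F, M∘T⟩ / (‖F‖² + ‖M∘T‖²)` maximised coarse-to-fine
   (subsampling 4×, 2×, 1×) with Powell's method, initialised at zero
   rotation and the bone-centroid translation offset.

Everything is deterministic: fixed initialisation, fixed schedule, no
stochastic optimiser.  Non-convergence is flagged (`converged_`, Dice
diagnostics), never silent.  PET volumes are resampled with trilinear
interpolation, masks and label images with nearest-neighbour (masks must
stay binary); out-of-field voxels are filled with −1000 HU (air) for CT and
0 for PET.  On noise-free phantoms with planted misalignments (≤16 mm,
≤5°), recovery is well within half a voxel and 1°; the worked numbers are
recomputed by `scripts/acceptance.py`, not quoted here.

Only rigid, bone-mask-driven registration is in scope — no deformable
models, no PET-to-PET or mutual-information objectives.

## The eight VOIs and burden metrics

All masks use strict thresholds and pure boolean algebra — no morphological
cleanup, since any erosion/smoothing would silently change the reported
volumes:

| VOI | predicate |
| --- | --- |
| `Skeleton` | HU > 150 |
| `Skeleton600` | HU > 600 (sclerotic/dense bone) |
| `PSMA_PET_3` | SUV_PSMA > 3.0 ∧ HU > 150 |
| `NaF_PET_10` | SUV_NaF > 10 ∧ HU > 150 |
| `NaF10_PSMA3` | `PSMA_PET_3` ∩ `NaF_PET_10` |
| `Scl_PSMA3` | `PSMA_PET_3` ∩ `Skeleton600` |
| `Scl_NaF10` | `NaF_PET_10` ∩ `Skeleton600` |
| `Scl_NaF10_PSMA3` | all three |

The PET-pathological VOIs are intersected with the skeleton: the analysis
quantifies pathological volume *in bone*, and the restriction also removes
extra-skeletal physiological uptake (no further organ exclusions are
applied).  Thresholds live in one `SegmentationConfig`; the defaults are the
clinical operating points above.

Per-patient metrics: volume `N_vox · s_x s_y s_z / 1000` mL; arithmetic mean
SUV over the VOI (an empty VOI has *undefined* mean — propagated as NaN, not
zero — so lesion-free controls stay representable); and the TLG-analogue
burden scores TEA (PSMA) and TBA (NaF), `volume(L) × SUVmean`, zero for an
empty VOI.  The L·SUV unit follows from the magnitudes these scores take on
liter-scale skeletal volumes.  Three percentage families are reported:
nested fractions of `Skeleton` and of `Skeleton600` (in [0, 100] by
construction) and the non-nested pathological-to-sclerosis ratios, which can
exceed 100%.

## Cohort statistics

Group summaries are mean, **population** standard deviation (divisor n — the
convention that reproduces the reference cohort's printed age summary), min
and max.  M-vs-N comparisons use the two-sided Mann–Whitney U test: the
exact permutation distribution when `n₁+n₂ ≤ 25` and the samples are
tie-free, otherwise the normal approximation with midrank tie correction and
continuity correction.  Two groups with all values identical return p = 1
with a warning.  No multiple-testing correction is applied; raw p-values are
reported.

Correlations against serum PSA are sample Pearson r on raw (not
log-transformed) values, computed within each group separately for the
pathological PSMA, pathological NaF, and CT sclerosis volumes.  The
SUV_PSMA threshold sweep rebuilds the skeletal pathological PSMA mask at
{3, 4, 6, 10}, reporting per-patient volumes (non-increasing in the
threshold by strictness of the predicate) and the within-M volume–PSA
correlation per threshold.

## Synthetic phantoms: what they emulate, and what they do not

The generator exists because the patient scans are not distributable.  A
phantom is a stylised scaled-down skeleton — a vertebral column of stacked
cylinders (20 mm bodies, 4 mm gaps), a pelvic torus, paired long bones, each
with a 4 mm cortical shell — on a default 40×40×64 grid at 4 mm.  Numerical
choices that matter:

- **Compartment HU levels** (background 20, trabecular 300, cortical 500,
  sclerotic 800; texture sd 25).  The cortical level is deliberately below
  600: at 4 mm a thin cortical shell partial-volumes far below intrinsic
  cortical density, and keeping it below the sclerosis threshold lets
  discrete sclerotic patches control the dense-bone fraction (~12–20% of
  skeleton, the clinically observed scale).
- **Truncated noise.**  All texture noise is Gaussian clipped at ±4 sd, so
  compartments can never cross thresholds: control patients have *exactly*
  zero pathological volume, and ground-truth masks are unambiguous.
- **Lesions** are spheres centred on skeleton voxels.  A concordance
  parameter ρ (default 0.6) sets the probability a lesion is pathological on
  both tracers; the rest split evenly into PSMA-only and NaF-only, matching
  the observed partial overlap of the two tracers.  Pathological SUVs are
  log-normal (medians 8 PSMA / 25 NaF, log-sd 0.4, floored just above
  threshold); sub-threshold assignments keep lesions visible but
  non-pathological.  Half the lesions are sclerotic (HU set to the sclerotic
  level).
- **Cohorts** default to 14 M + 12 N.  M patients receive 6–30 lesions and
  a per-patient log-normal scale on lesion radii (log-sd 0.45): patient
  burden in this disease is heavily skewed (reported dispersions have
  CV > 2), and lesion count alone cannot reproduce that.  Serum PSA follows
  `psa = α·V·exp(σε)` with V the true pathological PSMA volume in mL,
  α = 1 µg/L/mL and σ = 0.3, so the noiseless limit is exactly r = 1;
  N-group PSA is burden-independent log-normal (median 5 µg/L).
- **Misalignment.**  The planted transform displaces the whole NaF-study
  anatomy (PET and its CT are rendered at inverse-mapped points, sharing the
  aligned render's PET noise field), so registration recovers the planted
  transform in the resampling convention.
- **Determinism.**  One `numpy` Generator per spec seed; equal specs give
  bit-identical volumes, and every phantom carries its own per-voxel
  predicate masks and volumes as ground truth.

What the phantoms do *not* model: PET physics (point-spread, partial-volume
at lesion boundaries, reconstruction noise correlations), attenuation,
anatomical skeleton shape, physiological tracer uptake patterns
(kidney/bladder spillover), or couch/contrast CT artifacts above 150 HU.
Passing tests therefore demonstrate the correctness of the mask algebra,
metrics, statistics, and registration machinery under the stated geometry —
not robustness to scanner physics or segmentation edge cases in real CTs.
A body-mask pre-crop hook for couch artifacts exists in concept but no
artifact model is generated; real-data use should validate thresholds per
scanner.

## Problem sizes in tests and the acceptance script

Oracle-equivalence checks run on 16×16×24 grids, where per-voxel Python-loop
oracles are exact and fast; registration recovery and cohort structure
recovery run on the default 40×40×64 grid with 10 and 20 seeded replicates
respectively.  These sizes exercise every code path at full fidelity — the
computations are resolution-independent — while keeping a complete run of
the suite plus `scripts/acceptance.py` to a few minutes on one CPU.

## Known limitations

- Rigid registration assumes the skeleton dominates the HU > 150 mask; a
  real CT with contrast or couch structures above 150 HU needs pre-cropping.
- Sclerosis is defined strictly from CT (HU > 600); PET plays no role in the
  dense-bone compartment.
- The DICOM reader is minimal (pixel data, spacing, slice positions,
  rescale, single-frame CT/PET series); no RTSTRUCT, registration objects,
  or multi-frame support.
- Percentage ratios with an empty denominator VOI (no sclerotic bone) are
  undefined and propagate as NaN with a warning.
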