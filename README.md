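# skelburden

Volumetric skeletal tumor-burden analysis for dual-tracer
(⁶⁸Ga-PSMA-11 + Na¹⁸F) PET/CT in metastatic prostate cancer.

Bone is the dominant metastatic site in advanced prostate cancer, and the two
tracers see different biology: PSMA uptake reflects tumor-cell membrane
enzyme activity, NaF uptake reflects bone mineralisation/remodeling.  Given a
patient's co-acquired PSMA-PET/CT and NaF-PET/CT studies, this package

1. rigidly coregisters the two studies using only the CT bone compartment
   (HU > 150) — the skeleton does not change between consecutive-day scans;
2. builds eight threshold-defined volumes of interest by boolean mask
   algebra: `Skeleton` (HU > 150), `Skeleton600` (sclerotic bone, HU > 600),
   `PSMA_PET_3` (SUV > 3.0 in the skeleton), `NaF_PET_10` (SUV > 10 in the
   skeleton), and their intersections `NaF10_PSMA3`, `Scl_PSMA3`,
   `Scl_NaF10`, `Scl_NaF10_PSMA3`;
3. computes per-patient metrics: VOI volumes (mL), mean SUV_bw, the
   TLG-analogue burden scores TEA = V·SUVmean (total enzyme activity, PSMA)
   and TBA (total bone demineralisation activity, NaF), both in L·SUV, and
   percentage-volume ratios against `Skeleton` and `Skeleton600`;
4. aggregates a metastatic (M) vs control (N) cohort: group summaries,
   two-sided Mann–Whitney U tests per metric, Pearson correlations of
   pathological volumes against serum PSA within each group, and a
   SUV_PSMA threshold sweep over {3, 4, 6, 10}.

Patient scans cannot be redistributed, so the package ships a synthetic
module (`skelburden.synthetic`) that generates stylised dual-tracer phantoms
and whole M/N cohorts with exact voxel-level ground truth, plus the packaged
clinical characteristics table of the 26-patient reference cohort
(`skelburden.load_reference_cohort`).

## Worked example

```python
import skelburden as sb
from skelburden.synthetic import CohortSpec, make_cohort

cohort = make_cohort(CohortSpec(seed=1))          # 14 M + 12 N patients
config = sb.RunConfig(register=False)             # phantoms are pre-aligned
result, table, statuses = sb.run_cohort(config, list(cohort.studies))

row = result.tests.set_index("metric").loc["volume_ml_PSMA_PET_3"]
print(f"pathological PSMA volume, M vs N: U={row.U:.0f} p={row.p:.2e}")
corr = result.correlations.query("metric=='volume_ml_PSMA_PET_3' and group=='M'")
print(f"M-group r(PSMA volume, PSA) = {float(corr.r.iloc[0]):.2f}")
print(result.sweep.to_frame().to_string(index=False))
```

prints

```
pathological PSMA volume, M vs N: U=168 p=6.14e-06
M-group r(PSMA volume, PSA) = 0.92
 suv_psma_threshold  pearson_r_m
                3.0     0.917000
                4.0     0.917914
                6.0     0.901572
               10.0     0.766584
```

U = 168 = 14·12 means every metastatic patient carries more pathological
PSMA volume than every control (controls are exactly zero by construction);
the correlation of pathological PSMA volume with serum PSA is strong at the
SUV 3.0 operating point and degrades at high thresholds as lesion voxels are
lost.

A command-line surface wraps the same stages:

```bash
skelburden simulate --kind study --lesions 8 --seed 3 --out study/
skelburden register --fixed study/ct.nii.gz --moving other_ct.nii.gz
skelburden segment study/
skelburden metrics study/ --out metrics.csv
skelburden run-all --seed 1 --out run/
```

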