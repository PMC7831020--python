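# bmmap — voxel-wise brain-metastasis mapping and outcome analysis

Brain metastases (BMs) are not scattered uniformly through the brain: their
spatial distribution varies with the primary tumor, its proliferative
activity, and patient characteristics, and infratentorial (posterior-fossa)
involvement carries prognostic weight. `bmmap` implements the full voxel-wise
analysis chain used to study these questions on cohorts of segmented,
template-registered lesion masks:

- **Lesion metrics** — connected-component labeling of binary lesion masks
  (6/18/26-connectivity, default 26), per-lesion centroids, normalized
  volumes (voxel count × voxel volume, default 0.08 mm³), and
  winner-takes-all assignment of each lesion to an atlas region; per-patient
  number / total volume (TV) / volume of the single lesion (VSL) summaries.
- **Frequency heatmaps** — voxel-wise counts of patients with a lesion at
  each voxel.
- **ADIFFI** (analysis of differential involvement) — at every voxel a 2×2
  contingency table of lesion presence between two patient phenotypes A and
  B, tested with a two-sided Fisher exact test

  p = (a+b)!·(c+d)!·(a+c)!·(b+d)! / (a!·b!·c!·d!·n!),

  summed over all tables with the observed margins whose point probability
  does not exceed the observed table's; significant voxels (p < α) are
  grouped into directed clusters.
- **Relative metastatic risk** — per region x,
  RMR_x = (N_x/N_p/V_x) / (Σᵢ (N_i/N_p/V_i)/N_R),
  the patient-level metastasis rate per unit region volume normalized so the
  across-region mean is 1 (RMR > 1 = susceptible region).
- **Survival** — Kaplan–Meier estimates with log-rank tests over the
  standard stratifications (age, sex, primary, lesion number 1/2/≥3, TV,
  infratentorial involvement, Ki-67, treatment) and univariate /
  multivariate Cox proportional-hazards regression with Efron tie handling.

Because clinical MRI cohorts of this kind are rarely shareable, the package
ships a first-class synthetic-cohort generator: a toy 18-region atlas
(8 left/right pairs + 2 midline structures, with an infratentorial
compartment), spherical lesions placed with per-region weights, lesion
counts matching the published 49.4 / 17.0 / 33.6 % split for 1 / 2 / ≥3
lesions, and exponential survival whose hazard rises with infratentorial
involvement (generating hazard ratio 1.473) and lesion number. Every
downstream stage is therefore testable end to end without patient data.

## Worked example

```bash
bmmap run-all --seed 3 --out demo_run     # 60 synthetic patients, ~1 s
```

The run directory contains the atlas, per-stage CSVs and NIfTI maps, and a
`manifest.json` with parameter echo and output hashes. Highlights from the
run above:

`rmr.csv` (first rows) — region 1 is hit by 2 of 60 patients but is small,
so its per-unit-volume risk is 1.62× the across-region average, while
region 2 was never hit (RMR 0):

```
 region_id  n_patients_with_bm  volume_mm3  per_volume_risk      rmr
         1                   2        6.08         0.005482 1.619406
         2                   0        6.08         0.000000 0.000000
         3                   3       22.88         0.002185 0.645498
```

`cox.csv` — the multivariate fit recovers an elevated hazard for the 19
patients with infratentorial involvement (HR 3.59, 95% CI 1.75–7.37,
p = 5.0e-4; at n = 60 the estimate is noisy — across ten n = 2000 cohorts
the mean recovered HR is 1.46–1.49 against the generating 1.473):

```
        factor level  n       hr   ci_low  ci_high        p         mode
infratentorial  with 19 3.590729 1.748381 7.374442 0.000499 multivariate
```

`km_medians.csv` — median OS 3.8 months with infratentorial involvement vs
12.8 months without (log-rank p = 4.7e-5). `adiffi_clusters.csv` is empty
for this run: the demo splits phenotypes by sex, which does not influence
lesion placement in the generator, so no voxel survives α = 0.05 — the
expected null behaviour. Planting a 4-fold infratentorial placement weight
in group A (see `bmmap.weighted_spec`) produces A-direction clusters whose
voxels are predominantly infratentorial.

The same stages are available as library calls (`bmmap.adiffi_map`,
`bmmap.relative_metastatic_risk`, `bmmap.cox_regression`, …) and as single
CLI subcommands (`bmmap simulate`, `bmmap summary`, …).

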