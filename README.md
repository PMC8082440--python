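# autobeam

Desk-scale toolkit for studying radiotherapy **beam-configuration choice with
automated planning**, aimed at mediastinal-lymphoma-like geometries. It
generates synthetic female-thorax phantoms, computes analytic beamlet dose
influence, produces Pareto-optimal IMRT plans by prioritized ("wish-list")
multi-criteria optimization with integrated greedy beam-angle optimization
(BAO), evaluates DVH-based plan parameters against clinical goals, and runs a
population comparison of 24 beam configurations per patient:

- `CP_x` — coplanar plans, x = 5..15 patient-specific optimized beams;
- `NCP_x` — non-coplanar plans, x = 5..15 optimized beams on the gantry-couch
  sphere;
- `VMAT` — a 21-beam equiangular coplanar class solution (full-arc surrogate);
- `BVMAT` — the 20-beam "butterfly" class solution (two coplanar 60° arcs plus
  one couch-90 arc).

The dose engine is a transparent analytic substitute (Gaussian pencil
beamlets, exponential attenuation along radiological depth, parallel
geometry) — adequate for comparing beam *directions*, not for clinical
dosimetry.

## Layout

| module | role |
| --- | --- |
| `autobeam.phantoms` | seeded synthetic thorax cohort generation (PTV, lungs, heart, breasts, patient) |
| `autobeam.beams` | beam directions (IEC 61217 convention), candidate sets, class solutions |
| `autobeam.dose` | beamlet grids, sparse dose-influence matrices, dose accumulation |
| `autobeam.wishlist` | prioritized epsilon-constraint fluence optimization (LP stages via HiGHS) |
| `autobeam.bao` | greedy beam-angle selection with lexicographic candidate scoring |
| `autobeam.metrics` | DVH, plan parameters (V95%, CI, Dmean, V5Gy, ...), goal checking |
| `autobeam.study` | the 24-configuration population protocol, Wilcoxon signed-rank tests, beam-direction histograms |

## CLI

A single `autobeam` entry point with subcommands:

```sh
autobeam generate-cohort --out cohort/ --seed 1 --n-patients 25
autobeam beams --set bvmat --out bvmat.csv
autobeam plan --patient cohort/patient_000 --beams bvmat.csv --out plan/
autobeam plan --patient cohort/patient_000 --bao ncp --x 9 --out plan_ncp9/
autobeam evaluate --dose plan/dose.nii --patient cohort/patient_000 --out metrics.json
autobeam compare --config study.yaml --out study/
autobeam report --table study/comparison_table.csv --out report/
```

Patients are stored as per-structure NIfTI masks plus a YAML sidecar; beam
sets as CSV; wish-lists as YAML (the default protocol ships as
`autobeam/data/wishlist_default.yaml`); plans as NIfTI dose + fluence +
objective JSON.

## Notes on scale

Everything is configurable by grid resolution and beamlet size. Unit tests
run on 8–16 mm voxel phantoms; `autobeam.study.reduced_study_config()` gives
the coarse settings used for full population runs. Counts, exclusion
accounting and trend directions are resolution-independent; absolute
dosimetric values are not meant to reproduce any clinical dataset.
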