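# rtverify

Independent calculation-based verification of paired radiotherapy dose
distributions, built for VMAT-SBRT lung plans: a primary planning system's
dose grid is checked against an independent recalculation (and optionally a
cylindrical diode-array measurement) without requiring any clinical data.

The package provides:

- **`rtverify.dose_model`** — dose grids, CT volumes, planar-contour
  structure sets and voxel masks, with file I/O (a plain-array RT Dose
  dialect with grid scaling), contour rasterization, isotropic margin
  expansion, trilinear resampling and point-dose queries.
- **`rtverify.comparison_metrics`** — global dose-difference maps (DD3%,
  DD5%), generalized gamma-index maps (2%/2 mm, 3%/2 mm, 3%/3 mm) with an
  exhaustive fine-lattice search and azimuthal wrap-around on unwrapped
  cylindrical detector maps, passing rates above a 10% isodose threshold,
  and fail-point extraction. A brute-force gamma oracle
  (`gamma_brute_force`) with independent interpolation ships alongside the
  optimized search.
- **`rtverify.fri_similarity`** — Simpson's Faunal Resemblance Index
  |X∩Y| / min(|X|, |Y|) over fail-point sets, with explicit exclusion of
  comparisons that have no fail points, and cohort FRI tables.
- **`rtverify.dvh_verification`** — cumulative DVHs by exact voxel
  counting, D- and V-indices (D99/D95/Dmean/D2/Dmax, V20/V10/V5), lung =
  lung minus iGTV, dosimetric/volumetric errors
  DE = (D_s − D_p)/D_p × 100, tolerance levels (mean ± SD), Pearson
  correlation with strength classes, and paired t-tests with degenerate
  -case markers.
- **`rtverify.synthetic_data`** — seeded generators: phantom-mode triplets
  (primary, secondary, measurement) on a cylindrical diode layout, and
  patient-mode cases (lung-like HU volume, spherical tumor, iGTV + 3 mm →
  ITV + 5 mm → PTV margins, prescription-normalized conformal dose, and a
  density-coupled secondary-dose perturbation).
- **`rtverify.pipeline_cli`** — orchestration of the two workflows, cohort
  summary tables, and the `rtverify` command-line interface.

## CLI

```bash
# generate seeded synthetic cases (plain-array .npz bundles)
rtverify synth-phantom --seed 1 --n 5 --out cases/
rtverify synth-patient --seed 1 --n 5 --out cases/

# verify bundles and write report.json + tables/*.csv
rtverify verify-phantom cases/phantom_*.npz --criteria dd3,dd5,g2/2,g3/2,g3/3 --out out/
rtverify verify-patient cases/patient_*.npz --out out/

# end-to-end synthetic cohort (both modes)
rtverify cohort --mode both --n 20 --seed 1 --out cohort_out/
```

Phantom reports contain per-pattern passing rates (pattern 1 = primary vs
secondary with the primary as reference; patterns 2/3 = each system vs
measurement with the measurement as reference) and FRI tables for the
dose-difference criteria. Patient reports contain the DVH index sets of
both grids, DE/VE records, cohort tolerance levels, paired t-tests, and
correlations of the target DEs against PTV size and HU statistics.

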