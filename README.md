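# earlyframe

Early-phase amyloid-PET perfusion-surrogate optimization, re-implemented as
a tested, reusable pipeline and exercised end to end on synthetic dynamic-PET
cohorts with known ground truth.

The pipeline covers:

- **Synthetic data** — mesh-based cohorts (two icosphere hemispheres, 68
  parcels, vulnerable patch, reference-region patches, medial wall) whose
  10 one-minute early frames follow a perfusion-weighted delivery curve plus
  a late-onset amyloid-binding term; volumetric shell phantoms for PVC and
  projection testing. Full ground-truth bookkeeping and seed determinism.
- **Preprocessing** — enumeration of the 34 early time windows
  (start 0–3 min, end 1–10 min), frame averaging, intensity scaling by seven
  reference-region schemes (region mean after 4 mm erosion and tissue
  masking, or global proportional scaling to 6.5 mg/100 mL/min), and
  amyloid-status calling at the 1.22 neocortical SUVR cutoff.
- **PVC & surface operations** — three-compartment Müller-Gärtner
  partial-volume correction; robust depth-weighted surface projection
  (35–65 % of cortical thickness, Gaussian weights centered on the central
  surface); FWHM-calibrated, mass-conserving heat-kernel smoothing on the
  mesh graph; area-weighted parcel means.
- **Correlation statistics** — vertex-wise within-/inter-subject Pearson
  correlations, the t-to-r conversion
  `r = sign(t) sqrt(t² / (N − rank(M) + t²))`, permutation p-values, and
  optimal-window selection by maximal cortical surface area.
- **Rank comparison** — tie-corrected Friedman test, Nemenyi critical
  difference, CD-diagram grouping (and optional SVG rendering).
- **Pattern overlap** — Freedman–Lane permutation GLM with nuisance
  covariates, surface TFCE, max-statistic FWE correction, balanced-accuracy
  overlap of binarized patterns swept over 91 thresholds (p = 0.05 → 0.001),
  and Friedman ranking of reference regions.
- **Classification** — repeated stratified hold-out nested CV of a linear
  SVM on parcel-mean features (80 % of the smallest class per training
  split, class-balanced), BACC metric, paired splits across modality
  configurations.
- **Orchestration** — a manifest-driven pipeline (`run_pipeline`) with
  schema-validated YAML configuration, per-stage hashing, no-op reruns and
  dependency-aware recomputation, plus correlation-based homogeneity QC.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (window count,
Eq.-oracle, PVC recovery, TFCE oracle, FWE calibration, Friedman oracle,
optimal-window and reference-region parameter recovery, classifier
calibration, smoothing checks). The full suite takes roughly 15 minutes on
one CPU; the recovery tests dominate.

## CLI

```bash
earlyframe windows                          # list the 34 early windows
earlyframe synth-cohort --seed 1 --out dir/ # synthetic cohort (GIFTI + CSV)
earlyframe synth-phantom --out dir/         # shell phantom (NIfTI)
earlyframe scale --ref pons --mesh dir/mesh --in map.shape.gii --out out.gii
earlyframe friedman --in scores.csv --svg cd.svg
earlyframe qc --maps maps.npz --out qc.csv
earlyframe all --config cfg.yaml --seed 1 --out run/
```

Exit codes: 2 = validation error, 3 = computation error.

A minimal pipeline config:

```yaml
mesh_subdivisions: 3
cohort: {n_yhc: 4, n_ehc: 16, n_amci: 10, n_add: 10}
n_permutations: 200
cv_iterations: 50
```

## Layout

```
src/earlyframe/
  mesh.py        meshes, icospheres, parcels, geodesic erosion
  synthetic.py   cohort + phantom generators (ground truth kept)
  preproc.py     windows, reference scaling, amyloid calling
  pvc.py         Müller-Gärtner PVC, projection, smoothing, ROI means
  corrstats.py   within/inter-subject correlation, window selection
  ranking.py     Friedman / Nemenyi / CD diagrams
  overlap.py     permutation GLM, TFCE, FWE, BACC overlap sweep
  classify.py    nested-CV linear SVM, configuration comparison
  qc.py          homogeneity QC
  pipeline.py    manifest-driven orchestration
  io.py          GIFTI / NIfTI / CSV / YAML readers and writers
  cli.py         click command group
```
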