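# audiotwin

Twin-cohort simulation and variance-component analysis of age-related hearing
phenotypes.

The package provides a fully synthetic, end-to-end reimplementation of a
classical twin analysis of hearing ability:

- **`audiotwin.simulate`** — synthetic twin cohorts (MZ/DZ pairs plus
  singletons) whose audiograms and speech-reception thresholds (SRT) have a
  known additive-genetic / common-environment / unique-environment (A/C/E)
  structure, age trends, and a controllable cross-trait genetic correlation.
- **`audiotwin.staircase`** — a 1-down/1-up adaptive digit-triplet
  speech-in-noise test simulator (2 dB steps) estimating each listener's SRT.
- **`audiotwin.phenotypes`** — scalar hearing phenotypes from per-frequency
  thresholds: pure-tone average (PTA), better-ear hearing level (BEHL),
  correlation-matrix PCA scores (PC1 = overall level, PC2 = audiogram shape),
  and the PC1−PC2 composite; phenotype ranking by age correlation and
  shape capture; Kruskal-Wallis group comparison.
- **`audiotwin.univariate`** — maximum-likelihood ACE/AE/CE/E
  variance-component fits for twin pairs, closed-form (Falconer) oracle,
  likelihood-ratio model comparison with relative AIC, profile-likelihood
  confidence intervals, age adjustment.
- **`audiotwin.bivariate`** — two-trait correlated-factors AE model
  estimating the genetic (`r_a`) and environmental (`r_e`) factor
  correlations and the genetic share of the phenotypic correlation.
- **`audiotwin.validation`** — screening validation: ROC by direct counting,
  Youden-optimal operating points, Bland-Altman repeatability with Pitman's
  variance test, phenotype-score correlations.
- **`audiotwin.pipeline` / `audiotwin.cli`** — orchestration with seeded,
  reproducible stages and CSV/JSON/YAML artifacts.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(model-comparison arithmetic, Falconer/ML equivalence, univariate and
bivariate parameter recovery with CI coverage, staircase accuracy, ROC
oracle agreement, Kruskal-Wallis calibration, PCA structure). The full
suite runs in under two minutes on one CPU.

## CLI

```sh
audiotwin simulate --n-mz 250 --n-dz 250 --seed 1 --out cohort.csv
audiotwin phenotype cohort.csv --out phenotypes.csv
audiotwin rank phenotypes.csv
audiotwin heritability phenotypes.csv --column pta --column pc1_minus_pc2
audiotwin bivariate phenotypes.csv --trait-x pc1_minus_pc2 --trait-y snr
audiotwin staircase cohort.csv
audiotwin validate phenotypes.csv --rule pta_gt:40
audiotwin run-all --seed 1 --out report_dir
```

`run-all` executes every stage (simulate → phenotype → rank → univariate →
bivariate → validate) and writes a report directory with cohort and
phenotype CSVs, ranking and model-fit tables, bivariate and validation
JSON, and run metadata (seeds, stage durations).

Cohort CSVs use one row per subject (`subject_id, pair_id, zygosity, age,
sex, thr_L_<kHz>..., thr_R_<kHz>..., snr`) with a YAML config sidecar and a
`*.latent.csv` sidecar holding generating-truth factors (used only by
recovery tests, never by estimators).

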