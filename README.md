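# peptipanel

Discovery and evaluation of urinary-peptide diagnostic panels from CE-MS
intensity matrices. The package implements a complete workflow for
separating primary from secondary focal segmental glomerulosclerosis
(pFSGS vs sFSGS) with urine peptide profiles:

- **`peptipanel.data`** — data model and TSV IO for samples × peptides
  intensity matrices (0 = not detected), plus packaged reference tables:
  the 93-peptide diagnostic panel (PTM-annotated sequences, parental
  proteins, stage p-values, group mean intensities), the matched and
  independent other-CKD etiology tables, and per-group clinical summary
  statistics.
- **`peptipanel.simulate`** — seeded synthetic-cohort generator. Intensities
  are zero-inflated log-normal, calibrated so each peptide's analytic group
  mean equals the packaged panel means exactly; clinical covariates
  (proteinuria, eGFR, age, sex, IFTA) are drawn from the published group
  summaries.
- **`peptipanel.discovery`** — three-stage biomarker filter: Wilcoxon
  rank-sum screen against normal controls with Benjamini–Hochberg
  adjustment, then unadjusted significance plus identical direction of
  change against disease controls and other-CKD patients.
- **`peptipanel.svmpanel`** — linear soft-margin SVM panel on
  `ln(1 + x)`-transformed standardized intensities, leave-one-out
  cross-validation (fold-local transforms, no leakage), greedy backward
  feature elimination scored by LOO-CV AUC, and Youden-index cutoff
  selection.
- **`peptipanel.evalstats`** — ROC/AUC with DeLong variance, confidence
  intervals and paired difference tests, independent-cohort specificity,
  multivariable logistic covariable screen, a two-term score + proteinuria
  nomogram, and cohort-table hypothesis tests (Student's t, Mann–Whitney,
  Yates-corrected chi-square).
- **`peptipanel.cli`** — the `peptipanel` command with `simulate`,
  `discover`, `train`, `evaluate` and `report` subcommands.

## CLI workflow on synthetic data

```sh
peptipanel simulate --seed 7 --out runs/sim --config config.yaml
peptipanel discover --data runs/sim/training.tsv --out runs/discovery.tsv
peptipanel train    --data runs/sim/training.tsv \
                    --discovery runs/discovery.tsv --out runs/model
peptipanel evaluate --panel runs/model/panel.json \
                    --data runs/sim/training.tsv \
                    --independent runs/sim/independent.tsv \
                    --out runs/evaluation.json
peptipanel report   --evaluation runs/evaluation.json
```

`config.yaml` is optional; recognized keys are `cohort` (group sizes,
`sigma`, `n_background_peptides`, `detection_m0`), `discovery`
(`alpha`, `method`), `svm` (`C`) and `elimination` (`enabled`). Unknown
keys are rejected. With elimination enabled on large panels, training
performs one LOO-CV evaluation per candidate removal per round, which can
take minutes for ~100 features.

## Intensity file format

Wide UTF-8 TSV, one row per sample:
`sample_id  group  [etiology]  [proteinuria egfr age sex ifta]  <peptide columns...>`
with `group` one of `pFSGS`, `sFSGS`, `NC`, `CKD_other`. Optional dataset
metadata travels in a `<name>.tsv.meta.json` side-car. Reading uses
round-trip float parsing, so write → read reproduces matrices bit-exactly.
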