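# qsarflow

A small, tested implementation of the classical 2D-QSAR workflow used to
design acetylcholinesterase (AChE) inhibitors for Alzheimer's-disease
research: build a multiple-linear-regression activity model from molecular
descriptors, validate it internally, externally and against chance
correlation, delimit its applicability domain, predict activities of newly
designed candidates, and filter those candidates with rule-based
drug-likeness and pharmacokinetic gates.

It is aimed at medicinal/computational chemists who have a descriptor table
(compound id, descriptors, IC50 or pIC50) and want the full
model-building-and-validation protocol as a reproducible library and CLI
rather than a spreadsheet.

## The model and its validation statistics

Activity is modelled as ordinary least squares with intercept over k
selected descriptors,

    pIC50 = β₀ + β₁·PSA + β₂·µ + β₃·MW + ε,

where pIC50 = −log₁₀(IC50 in mol/L), PSA is the polar surface area (Å²),
µ the dipole moment (Debye) and MW the molecular weight (g/mol) — the three
descriptors the workflow's correlation filter selects out of a ~50-column
table. The workflow computes:

* **R²** = 1 − RSS/TSS on the training set, with RMSE = √(RSS/n) and the
  Fisher statistic F = (R²/k) / ((1−R²)/(n−k−1));
* **Q²CV** (leave-one-out): Q² = 1 − PRESS/TSS, with PRESS evaluated both by
  n explicit refits and the hat-matrix shortcut eᵢ/(1−hᵢᵢ) (the two must
  agree to 1e−10);
* **R²test**: squared Pearson correlation of observed vs predicted on the
  held-out 20%, plus the predictive variant 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)²;
* **y-randomization**: 100 refits on scrambled activities, summarized by
  cRp² = R·√(R² − r̄²rand), required > 0.5;
* **VIF** per descriptor, 1/(1−R²ⱼ) from auxiliary regressions, flagged at 10;
* the **acceptance gate** (R² ≥ 0.6, Q²CV > 0.5, R² − Q²CV ≤ 0.3,
  n_ext ≥ 5, p < 0.05);
* the **applicability domain**: leverages hᵢ = xᵢᵀ(XᵀX)⁻¹xᵢ on the
  intercept-augmented design, cutoff h* = 3(K+1)/n, standardized residuals
  at ±3 (Williams plot);
* **screening**: candidate ranking by predicted pIC50 against a reference
  potency, Lipinski's rule of five (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10,
  ≤ 2 violations), BBB (logBB > 0.3 permeant, < −1 poor) and CNS
  (logPS > −2 penetrant, < −3 blocked) classification, and
  HIA/Caco-2/CYP2D6/AMES/hepatotoxicity/skin-sensitization gates over
  externally predicted ADMET values.

A seeded synthetic-data generator reproduces the statistical regime of the
underlying 50-compound study (three true drivers among ~47 nuisance
columns, training R² ≈ 0.64, activities ≈ 5.3–7.3), so the entire pipeline
is testable without any proprietary descriptor table. Published candidate,
drug-likeness, ADMET and activity tables ship as fixtures.

## Worked example

```
$ qsarflow simulate --seed 7 --out compounds.csv
wrote 50 compounds to compounds.csv
$ qsarflow import --data compounds.csv --split 0.8 --seed 42 --out split.csv
split 40 train / 10 test -> split.csv
$ qsarflow fit --data split.csv --out model.json
fit k=3 on n=40: R^2=0.641 RMSE=0.414
$ qsarflow validate --data split.csv --n-perm 100 --seed 7 --out validation.json
Q^2_cv=0.527 R^2_test=0.277 cRp^2=0.598 gate=PASS
$ qsarflow domain --data split.csv --out williams.csv
h*=0.300; 1 outlier(s) of 50 -> williams.csv
```

The fit found the three generating descriptors and an R² of 0.641 on the
40-compound training split; LOO cross-validation retains Q² = 0.527 (> 0.5,
internally predictive) and scrambling the activities collapses the fit
(cRp² = 0.598 > 0.5: the correlation is not chance). R²test is volatile at
n_ext = 10 — a reminder of how little a 10-compound external set
constrains a model. h* = 3·(3+1)/40 = 0.300 bounds the leverage domain.

Screening the eleven designed candidates of the published study with the
published model:

```python
>>> from qsarflow import load_fixture, screen_candidates
>>> report = screen_candidates(load_fixture("eq1_model"), load_fixture("table4_candidates"))
>>> print(report.table.head(5).to_string(index=False))
 id  predicted_pic50  improved in_domain  rank
 M1         7.744907      True      None     1
 M9         7.706560      True      None     2
M10         7.677888      True      None     3
 M2         7.649354      True      None     4
 M6         7.620183      True      None     5
```

M1 ranks first; all shown candidates beat the reference potency
pIC50 = 7.259. An end-to-end configured run
(`qsarflow run --config run.yaml`) writes `model.json`,
`validation.{json,csv}`, `williams.csv`, `screening.csv` and a
`run_log.json` echoing every threshold applied.

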