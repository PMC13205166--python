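# petct-radiomics

A tested, reusable implementation of a baseline ¹⁸F-FDG PET/CT radiomics
pipeline for predicting **early progression (EP)** in locally advanced
pancreatic cancer (LAPC). EP — radiologically confirmed progression at the
first follow-up, roughly three months into treatment — occurs in about a
third of LAPC patients and marks an aggressive phenotype that conventional
staging does not identify. The pipeline asks whether intratumoral
*heterogeneity*, quantified from baseline PET/CT texture together with PET
metabolic metrics and clinical covariates, can flag those patients before
treatment starts.

It is aimed at researchers who want a transparent, fully seeded reference
implementation of this class of small-cohort radiomics workflow — each stage
is a plain library call, and a synthetic cohort generator with a known
ground-truth class signal makes every stage testable without patient data.

## The pipeline

For each patient with co-registered CT and PET volumes and a binary tumor
mask:

1. **Preprocessing** — in-plane resampling of all volumes to the dataset
   median grid (slice count unchanged); CT on a 12-bit scale, PET in SUV.
2. **PET metrics** — SUVmax; metabolic tumor volume
   MTV = vol{v ∈ ROI : SUV(v) ≥ 0.4·SUVmax} in cm³; total lesion glycolysis
   TLG = SUVmean(MTV) · MTV.
3. **Texture features, 242 per modality** — 12 first-order intensity
   statistics; 182 GLCM features (14 Haralick statistics × 13 symmetric 3D
   offsets of the 26-neighborhood, accumulated globally over the ROI after
   32-level quantization); 48 LBP-TOP features (16-bin local-binary-pattern
   code histograms, P = 4, R = 1, on the xy/xz/yz plane families).
4. **Harmonization** — non-finite values become missing; continuous columns
   are mean-imputed, discrete columns median-imputed, with fill statistics
   fit on training rows only inside cross-validation.
5. **Feature selection** — greedy MRMR under the difference criterion
   argmax_f [ I(f; y) − mean_{s∈S} I(f; s) ], with the retained count chosen
   at the scree-curve elbow (maximum normalized chord distance).
6. **Classifier** — a two-level decision-tree cascade: a lenient tree with
   false-negative cost c_low decides when its leaf confidence exceeds the
   reliability threshold τ = 0.5; otherwise a conservative tree with cost
   c_high > c_low decides at a ROC-tuned operating threshold θ (Youden's J).
7. **Evaluation** — nested stratified cross-validation (outer CV10 for
   testing, inner CV5 for selection and tuning), pooled confusion matrix,
   accuracy and rank-based AUC.

See `docs/methods.md` for the full model description, parameter defaults,
numerical conventions, and what the synthetic generator does and does not
emulate.

## Worked example

```python
import petct_radiomics as pr

# a 120-patient synthetic cohort with a strong, known class signal
spec = pr.strong_spec(n_patients=120, seed=1)
table = pr.cohort_to_table(pr.generate_cohort(spec))

report = pr.run_nested_cv(table, config=pr.CVConfig(random_state=1))
print(f"pooled accuracy {report.accuracy:.3f}  pooled AUC {report.auc:.3f}")
print(report.confusion)
```

prints

```
pooled accuracy 0.783  pooled AUC 0.807
{'tp': 28, 'fn': 14, 'fp': 12, 'tn': 66}
```

i.e. on this seed the nested CV recovers the planted heterogeneity signal
with 78% pooled accuracy and AUC 0.81; 28 of the 42 EP patients are
identified, at 12 false positives among the 78 non-EP patients. On a null
cohort (`pr.null_spec`, no class signal) the same call yields AUC near 0.5.

The same stages are available from the shell:

```bash
petct-radiomics generate --n 57 --seed 7 --out cohort/
petct-radiomics extract --in-dir cohort/ --out features.csv
petct-radiomics pet-metrics --in-dir cohort/ --out metrics.csv
petct-radiomics harmonize --in-dir cohort/ --out table.csv
petct-radiomics run --table table.csv --seed 7 --out report.json
petct-radiomics report --in report.json
```

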