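# ramandx

Single-cell Raman spectroscopy diagnostics for B-cell acute lymphoblastic
leukemia (B-ALL): a tested re-implementation of the full chemometric
workflow — spectral simulation, preprocessing, PCA with leave-one-out
classification, and the I₁₄₄₇/I₇₈₅ band-ratio diagnostic — for people who
want to study, stress-test or extend the method without access to the
original spectra.

## The problem and the method

Raman microspectroscopy reads a label-free biochemical fingerprint from a
single cell: DNA/RNA ring-breathing bands (785, 1120, 1370, 1577 cm⁻¹),
protein bands (1004, 1310, 1337, 1447, 1485 cm⁻¹), amide I at 1659 cm⁻¹.
Leukemic B cells differ from normal B-lymphocytes in exactly these bands —
nucleic-acid bands weaken, protein bands strengthen — and the changes grow
along the maturation series RS4;11 → REH → MN60. Two decision procedures
exploit this:

1. **PCA + leave-one-out classification.** Spectra (1200 variables, 600–1799
   cm⁻¹ at 1 cm⁻¹) are aligned, background-corrected by an iterative
   third-order polynomial fit, and normalized to the amide I peak. For each
   cell, a PCA model is refit on all *other* cells; the held-out cell is
   projected onto PC1–3 and assigned to the nearest class centroid. The
   confusion matrix's trace/total is the classification *efficiency*.
2. **The intensity-ratio diagnostic.** The per-cell statistic
   R = I₁₄₄₇/I₇₈₅ (protein CH₂ over DNA ring breathing) rises with leukemic
   transformation (≈1.6 in normal B cells, up to ≈3.45 in MN60). A threshold
   scan at the Youden operating point gives sensitivity/specificity, and a
   Mann–Whitney rank-sum test the group p-value.

Because no spectra are deposited, the package ships a first-class synthetic
cohort generator (`ramandx.simulate`): pseudo-Voigt band structure, cohort
intensity variability (20 % normal B, 7.5 % cell lines, 11 % clinical),
fluorescence baselines, laser drift, and per-cohort band patterns calibrated
so each cohort's noiseless preprocessed ratio hits its reported mean. See
`docs/methods.md` for the model and every default.

## Worked example

The analysis can be driven from the numbered scripts in `analysis/`
(01 simulate → 02 preprocess → 03 PCA/LOOCV → 04 ratio diagnostics →
05 treatment response), from Python, or from the CLI. A small end-to-end
run (50 cells per cohort):

```sh
cat > cfg.yaml <<'YAML'
seed: 1
class_plan: {B_normal: 50, "RS4;11": 50, REH: 50, MN60: 50}
k: 3
roc_pairs: [[REH, B_normal]]
YAML
ramandx run --config cfg.yaml --out out/
```

prints

```
LOOCV efficiency: 100.0% (200/200)
I1447/I785 B_normal: 1.56 +- 0.25 (n=50)
I1447/I785 MN60: 3.42 +- 0.20 (n=50)
I1447/I785 REH: 2.60 +- 0.15 (n=50)
I1447/I785 RS4;11: 1.98 +- 0.18 (n=50)
REH vs B_normal: sensitivity 100.0%, specificity 100.0%, p = 7.07e-18
```

Reading this: all 200 held-out cells were assigned to their true cohort by
the PC1–3 nearest-centroid rule; the per-cohort ratio means land on the
cohort targets (1.6 / 1.98 / 2.59 / 3.45) within Monte-Carlo error; and the
ratio alone already separates REH from normal B perfectly at this sample
size, with a rank-sum p of ~1e-17. `out/` holds the raw and preprocessed
spectra matrices, PCA scores/loadings, the labeled confusion matrix, the
ratio table, the full ROC curve and a machine-readable `report.json`.

Every stage is also a subcommand (`simulate`, `preprocess`, `pca`, `ratio`,
`report`) over the same output directory, and composing them reproduces
`run` byte-for-byte.

Python API sketch:

```python
import ramandx as rx

profiles = rx.calibrated_default_profiles()
raw = rx.generate_dataset({"B_normal": 300, "REH": 300}, seed=1, profiles=profiles)
pre = rx.preprocess_set(raw)
cm = rx.loocv_classify(pre, k=3)
print(rx.efficiency(cm), rx.group_ratio_stats(pre).as_dict())
```

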