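# Methods

`ramandx` re-implements, as a tested pipeline over simulated data, the
single-cell Raman workflow used to discriminate normal B-lymphocytes from
B-cell acute lymphoblastic leukemia (B-ALL) cells: spectral preprocessing,
PCA with leave-one-out classification, and the I<sub>1447</sub>/I<sub>785</sub>
band-ratio diagnostic. This note records the model, the parameter choices
that matter, and what the synthetic data do and do not establish.

## Spectral model

A cell's spectrum lives on the fingerprint axis 600–1799 cm⁻¹ at 1 cm⁻¹
spacing — exactly 1200 variables (the half-open convention: the inclusive
600–1800 range would give 1201). Each cohort is generated as

I(ν) = g · Σ_b a_b ε_b V(ν − c_b − δ; w_b, η_b) + B(ν) + e(ν)

* **V** is a unit-peak-height pseudo-Voigt (η = 0.5 Gaussian fraction,
  fwhm 16 cm⁻¹ — line shapes are a modeling choice; band *heights*, not
  areas, are the calibrated quantities).
* Twelve bands at 743, 785, 1004, 1120, 1310, 1337, 1370, 1447, 1485, 1577,
  1617, 1659 cm⁻¹ carry the standard assignments (RNA/DNA ring breathing,
  PO₂⁻ backbone, phenylalanine, amide III/I, CH/CH₂ protein modes).
* **g** is a per-cell lognormal intensity factor with CV 0.20 (normal B),
  0.075 (cell lines) or 0.11 (clinical cohorts) — the reported overall
  intensity variability of each cohort kind.
* **ε_b** are per-band lognormal factors, default relative sd 0.05. The
  ratio pair (785, 1447) instead carries the cohort's reported per-cell
  ratio spread: each gets sd = (ratio sd / ratio mean)/√2, since the ratio
  of two independent lognormals has √2× the per-band relative sd and g
  cancels in the ratio. The 785 (denominator) factor is drawn with unit
  *inverse* mean — with both factors at unit mean the cohort mean ratio
  would converge to target·(1 + cv²_785) rather than the target.
* **δ** ~ N(0, 1 cm⁻¹), capped at ±5 cm⁻¹: rigid laser-wavelength drift.
* **B** is a random cubic with coefficients uniform in fixed ranges chosen
  so baseline magnitude is roughly 0.5–2× the median peak height.
* **e** is white noise, sd 0.004 in raw units (≈ SNR 250 at amide I). The
  noise level is deliberately small: the clipping baseline fit settles onto
  the noise floor, and a larger noise floor leaves a constant offset in
  every baseline-subtracted integral that would dilute the 20 % intensity
  CV the normal-B cohort is specified to have.

## Cohort profiles and calibration

Normal-B band heights are fixed (amide I = 1, 1447 ≈ 0.9, 785 = 0.6, …).
Leukemia cohorts move along a maturation axis with per-step factors:
785 ×(1 − 0.15·s), 1120/1370/1577 ×(1 − 0.28·s), protein bands
1310/1337/1485/1617 (and nominally 1447) ×(1 + 0.16·s), amide I
×(1 + 0.02·s), with steps s = 1.0 (RS4;11), 2.2 (REH), 3.0 (MN60) and
2.0/2.0/2.5 for the clinical cohorts Pt-1/2/3. MN60 additionally has the
RNA 743 cm⁻¹ band ×2.5 (its L3 phenotype carries abundant ribosomal RNA;
Pt-3, intermediate, gets ×1.3). The step magnitudes were calibrated once so
that the cohorts jointly reproduce the *reported* study structure — the
printed per-cohort ratio statistics, the difference-spectrum sign pattern
(nucleic-acid bands down, 1447 up), and the reported leave-one-out
separability — and then frozen. The 785 step is bounded above by an exact
consistency constraint: the calibrated 1447 amplitude equals
target_ratio × I₇₈₅ (up to normalization), so too deep a 785 suppression
would drag the leukemia 1447 band *below* normal B and flip the sign
pattern.

Each profile carries a target post-preprocessing ratio (1.6, 1.98, 2.59,
3.45, 2.56, 2.45, 2.93). `calibrate_profile` pins it by fixed-point
iteration on the 1447 amplitude: generate the noiseless, drift-free,
baseline-free spectrum, run the *full* preprocessing chain, measure the
ratio, rescale by target/measured (≤ 20 iterations, converges in 2–4
because cross-band tails are small). Drug-treated variants are derived from
the calibrated parent: MTX and 6MP multiply the nucleic-acid bands
(785/1120/1370/1577) plus 1004 and 1447 by 0.7 (direction from the study;
magnitude a free choice), ATRA copies the parent unchanged.

## Preprocessing

Order: align → baseline → normalize, each per spectrum.

1. **Alignment.** Reference = pointwise median of the set (robust to
   outliers; the original reference is unspecified). Both traces are
   detrended with a single cubic, cross-correlated over integer lags within
   ±5 cm⁻¹, and the peak refined by parabolic interpolation. Convention:
   `estimate_shift` returns s with spectrum(ν) ≈ reference(ν + s), and
   `apply_shift(spectrum, −s)` (linear interpolation, edge fill) aligns.
   Residual misalignment on simulated drifts is ≲ 0.2 cm⁻¹ RMS.
2. **Baseline.** Iterative peak-suppressing cubic ("modified polyfit"): fit
   an order-3 least-squares polynomial to a working copy, clip the working
   copy to the fit, repeat until the maximum relative change < 1e-6 (cap
   100 iterations), subtract the final fit from the *original* trace. A
   pure order-≤3 polynomial is its own fixed point (removed to ≲1e-8), and
   adding any cubic to a trace leaves the output exactly unchanged (the fit
   operator is linear and clipping commutes with a common offset).
   `max_baseline_iters=1` gives the naive single-pass fit; whether the
   original processing excluded peak regions is unknown, so both modes
   exist, with the iterative one as default.
3. **Normalization.** Divide by the maximum within 1659 ± 8 cm⁻¹ (the
   amide I band, the spectrum's highest peak). Idempotent; preserves every
   intra-spectrum intensity ratio; fails loudly if the window maximum is
   non-positive (a baseline-correction failure).

## Band metrics and the ratio diagnostic

A band intensity is the maximum within center ± 8 cm⁻¹, which tolerates the
≲1 cm⁻¹ residual drift. The diagnostic statistic is I₁₄₄₇/I₇₈₅ per cell,
summarized per cohort as mean ± sample sd (n−1). Discrimination is
quantified by a full threshold scan: candidate thresholds are midpoints
between consecutive distinct pooled values plus ±∞; sensitivity = fraction
of positives (leukemia, the higher-ratio class) strictly above, specificity
= fraction of negatives at or below. The operating point maximizes
Youden's J = sens + spec − 1, ties resolved toward the lowest threshold;
the whole curve is exported so any other operating point can be read out.
Group difference is tested with a Mann–Whitney rank-sum (midranks for
ties): exact two-sided p by full enumeration of label assignments when
n₁+n₂ ≤ 16, otherwise a normal approximation with continuity and tie
correction (two-sided p = min(1, 2·one-sided); the approximation agrees
with enumeration to < 0.02 at n₁ = n₂ = 8).

## PCA and leave-one-out classification

PCA is the SVD of the row-centered spectra matrix; loadings are sign-fixed
(largest-magnitude element positive); explained fractions are σᵢ²/Σσ².
No variable scaling — spectra are already normalized to a common band.

The classification protocol refits PCA on the n−1 remaining spectra for
*every* fold, projects training spectra and the held-out one onto the first
k = 3 PCs, and assigns the held-out spectrum to the nearest class centroid
(Euclidean; ties to the lexicographically smallest label; a Mahalanobis
variant is available but off by default — the original classifier is
unspecified, and nearest-centroid is the minimal rule consistent with
"clusters of points"). Efficiency = trace/total of the confusion matrix.

Per-fold PCA runs in the dual (Gram) space: the centered fold Gram matrix
is a rank-one-corrected submatrix of the full Gram matrix, and its leading
eigenpairs come from a block subspace iteration (block k+4) warm-started
from the full-data eigenvectors, iterated to a 1e-9 relative residual —
algebraically an exact per-fold SVD (the test suite checks bit-identical
confusion matrices against explicit refitting) at a small fraction of the
cost; 1200 folds of 1200-point spectra take well under a minute.

## Problem sizes and what the tests show

The default experiment sizes mirror the study: 300 cells per cohort, so the
4-cohort PCA dataset has 1200 spectra. The acceptance script regenerates
everything from scratch at these sizes from a single seed (per-stage seeds
are derived by CRC-mixing a stage tag, all < 2³¹).

Passing tests establish that the *pipeline* reproduces the study's numbers
on data with the reported statistical structure — they cannot establish
instrument-level realism. The generator deliberately omits cosmic-ray
spikes, detector etaloning, photon shot noise (noise is homoscedastic),
peak-shape changes (only heights vary), and any correlation between bands
beyond the shared global factor; per-band variability beyond the 785/1447
pair is an artifact choice (0.05) since only cohort-level variability is
reported. Classification efficiencies near 100 % on synthetic cohorts
should be read as "the reported separability is attainable under the
reported variability", not as a performance claim about real cells.

## Known limitations

* The 785-step/ratio-target consistency constraint means very aggressive
  nucleic-acid suppression cannot be modeled without violating the 1447
  sign pattern; the defaults sit inside that bound.
* The exact rank-sum enumeration is O(C(n₁+n₂, n₁)) and intentionally
  capped at pooled n = 16 (auto mode) / 32 (forced).
* The JCAMP-DX reader covers single-block `(X++(Y..Y))` and `XYPOINTS`
  files in 1/CM units only, and requires full axis coverage.
* `loocv_classify` assumes distinct top-k eigenvalues per fold; exact
  degeneracies (measure-zero for noisy data) would make scores, and in
  pathological cases predictions, basis-dependent.
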