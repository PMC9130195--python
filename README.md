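# chronopls

Growth-informed PLS chemometrics for time-resolved microbial LC–MS
metabolomics.

## The problem

Untargeted LC–MS profiling of a microbial culture sampled across its
incubation (lag, exponential and stationary phase) produces a matrix of
binned chromatographic intensities whose dominant axis of variation is the
organism's own growth: medium components are consumed, constitutive
metabolites accumulate, and stress responses flare transiently. Supervised
chemometrics on such data needs a quantitative response vector (Y) per
sample — and calendar time is a poor one, because replicate cultures (or a
treated vs. untreated culture) do not develop at the same pace.

`chronopls` implements a microbial-specific alternative: the response is
the **natural log of the colony diameter** measured on each harvest day,

&nbsp;&nbsp;&nbsp;&nbsp;*y*(day) = ln *d*(day)&nbsp;&nbsp;[*d* in cm],

which jointly encodes growth rate and remaining medium availability. The
package builds and validates the full analysis around that idea, for the
canonical two-group design (treated "B" vs. control "F", five harvest
days, triplicates, pooled QCs):

* **preprocessing** — retention-time trimming, asymmetric-least-squares
  (Whittaker) baseline correction, total-area normalization, generalized
  log transform g(x) = ln(x + √(x² + λ)), autoscaling, and pooled-QC RSD /
  signal-to-noise / replicate-occurrence / blank filters;
* **PLS engine** — from-scratch NIPALS partial least squares for regression
  (PLSr) and one-hot discriminant analysis (PLS-DA, with merged day
  classes), plus SVD PCA and Ward-linkage HCA for exploration;
* **validation** — leave-one-out cross-validation with per-fold re-scaling,
  RMSEC/RMSECV component selection, R²/Q², response-permutation tests
  (empirical p on Q² plus paired Wilcoxon / sign / t tests on residuals),
  ROC/AUC with Youden thresholds;
* **biomarker calls** — variable importance in projection,
  VIP*ⱼ* = √( p · Σₐ SSYₐ (w*ⱼₐ*/‖wₐ‖)² / Σₐ SSYₐ ), with the conventional
  VIP > 1 cut; trend classes (consumed / produced / transient); the
  induced-metabolite triple rule (VIP > 1 **and** Welch t-test p < 0.005
  **and** ≥ 3-fold treatment/control mean area); Spearman bin-correlation
  maps;
* **annotation** — molecular-formula parsing, monoisotopic masses, [M+H]⁺ /
  [M+Na]⁺ adduct m/z, ppm errors, and biotransformation mass-shift matching
  (hydrogenation +2.0157, hydration +18.0106, ...);
* **synthetic data** — a generator that emulates the study design with
  planted bin archetypes (medium decay, growth-linked, fed alkaloids,
  early/late stress pulses, a stress-upregulated constitutive metabolite,
  inert background) and ground truth for recovery testing, including a
  chromatogram renderer to exercise baseline correction and binning.

## Worked example

```python
from chronopls.pipeline import RunConfig, run_all

report = run_all(RunConfig(seed=1, n_perm=199))
print("winning response model :", report["ymodel"]["winner"])
b = report["plsr"]["B"]
print(f"feeding PLSr           : A={b['n_components']}  R2={b['r2']:.4f}  "
      f"Q2={b['q2']:.4f}  p={b['empirical_p']:.3f}")
da = report["plsda"]
print(f"PLS-DA (1,4,8/12,16)   : A={da['n_components']}  Q2={da['q2']:.4f}  "
      f"accuracy={da['training_accuracy']:.2f}")
print("induced bins           :", report["biomarkers"]["induced_bins"])
rec = report["recovery"]
print(f"recovery               : sens={rec['induced_sensitivity']:.2f}  "
      f"spec={rec['induced_specificity']:.2f}")
```

prints

```
winning response model : diameter_log
feeding PLSr           : A=3  R2=0.9994  Q2=0.9982  p=0.005
PLS-DA (1,4,8/12,16)   : A=4  Q2=0.9735  accuracy=1.00
induced bins           : [2, 5, 6, 8, 21, 22, 23, 25]
recovery               : sens=1.00  spec=1.00
```

Reading: among the four candidate responses (days/diameter × raw/log) the
log-diameter model wins on cross-validated R² with all permutation p-values
significant; the feeding-group PLS regression explains the time course
almost perfectly (Q² 0.998 at 3 latent variables, permutation p at the
floor of 199 permutations); the four-class PLS-DA separates the harvest
periods with 100 % training accuracy; and the induced-metabolite rule
recovers exactly the bins the generator planted as treatment-exclusive or
treatment-amplified (fed alkaloids, early/late pulses, the stress-regulated
metabolite) — sensitivity and specificity 1.0 against ground truth for this
seed.

The same stages are available from the shell:

```sh
chronopls simulate --seed 1 --out data/
chronopls annotate --formula C20H39NO2 --mz 326.3051
# C20H39NO2 [M+H]+ theoretical m/z 326.3059; experimental 326.3051 -> -2.45 ppm (within 5.0 ppm)
chronopls run-all --seed 1 --out report.json
```

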