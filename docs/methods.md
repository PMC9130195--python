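# Methods

This note records the models, numerical conventions and design choices
behind `chronopls`, in the spirit of a statistics package's methods
appendix. It documents what the code computes; every empirical figure
quoted here is one the test suite or `scripts/acceptance.py` recomputes.

## Study design and data model

The package targets a two-group microbial time course: a culture fed an
exogenous compound (group **B**) and an unfed control (**F**), harvested on
incubation days 1, 4, 8, 12 and 16 in triplicate, profiled by LC–MS and
reduced upstream (peak picking, alignment, binning are out of scope) to a
samples × bins intensity matrix. Technical rows are pooled QCs (equal-part
pool of all study samples), organic-solvent blanks (OS) and culture-medium
references (CM). Colony diameters (cm, 9 cm plate) are recorded per day.

`FeatureMatrix` carries the values with typed per-sample and per-bin
metadata and a processing-stage tag; stages through `normalized` must be
non-negative, `glogged` and `autoscaled` may be signed. On disk a matrix is
a three-file CSV dialect (features / samples / bins) written with exact
(`repr`) float serialization and read back with round-trip float parsing,
so write → read is bit-identical.

## The growth-informed response

Supervised modelling needs a per-sample response y. Four candidates are
built from the design: incubation day or colony diameter, each raw or
natural-log transformed. The log-diameter response
y(day) = ln d(day) is motivated by logistic colony growth on a plate:
ln-diameter tracks the organism's progress through lag/exponential/
stationary phase and, through the plate's fixed area, the remaining medium.
Replicates of a (group, day) share one design value; day 1 (d = 1 cm plug)
maps to exactly 0.

Candidates are compared by leave-one-out Q² with permutation guards: the
winner is the candidate with the highest Q² among those whose three
permutation p-values (below) are all < 0.05; ties break toward fewer latent
variables, then listed order. Printed-table reproduction uses
truncation-toward-zero at two decimals (ln 8 = 2.0794 prints 2.07, not
2.08) — the convention the reference day/diameter tables follow.

## Preprocessing chain

Order: RT trim → SNR filter → occurrence filter → QC-RSD filter → blank
handling → total-area normalization → g-log → autoscaling. The source
protocol fixes the order of the four transforms (trim, baseline,
normalization, g-log, autoscaling) but not where the filters sit; placing
them before normalization is this package's choice, so that filter
statistics see raw intensities.

* **RT trim**: closed interval, default [11.5, 31] min.
* **Whittaker (asymmetric least squares) baseline** for point traces: z
  minimizes Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with wᵢ = p where yᵢ > zᵢ, else 1−p;
  defaults p = 0.001, λ = 100, second-order differences, at most 10 weight
  sweeps, convergence when the weight vector stops changing (a relative
  10⁻⁹ residual tolerance keeps exact fits from oscillating on float
  noise). Corrected signal is clipped at 0. The sparse solve is tested
  against a dense direct solve (10⁻⁸) and against the λ→∞ straight-line
  limit. Equivalence with any specific vendor "automatic" variant is not
  claimed.
* **Total-area normalization**: rows sum to 1; zero-sum rows are an error.
* **g-log**: g(x) = ln(x + √(x² + λ)), λ = 0.1, applied to the unit-sum
  normalized rows — the transform is scale-dependent, so this pairing is
  part of the contract. The variant with /2 inside the log differs by the
  constant ln 2, which autoscaling removes.
* **Autoscaling**: per-column mean-centring and division by the (n−1)
  standard deviation; zero-variance columns are an error naming the bin.
* **QC-RSD filter**: drop bins with 100·sd/mean > 25 % over the pooled-QC
  rows, computed on raw intensities with an (n−1) sd; a zero QC mean is an
  undefined RSD and the bin is dropped with its own reason code.
* **SNR filter**: drop bins whose best (group, day) replicate-mean is below
  5× the noise level. The noise estimator is 1.4826 × MAD of the OS blank
  rows when present, else user-supplied (the protocol does not define one).
* **Occurrence filter**: keep a bin if at least one (group, day) cell
  detects it (above the floor) in ≥ 75 % of replicates.
* **Blank handling**: OS-listed bins are removed; CM-listed bins are kept
  but labelled `culture_medium` — medium components carry the informative
  negative growth correlation.

In the end-to-end pipeline the chain through g-log runs once on the pooled
B+F+QC matrix (filters need the full replicate/QC structure), and
autoscaling is re-estimated on each analysis subset (PLSr per group, PLS-DA
on the feeding group), since column statistics must come from the samples
actually modelled.

## NIPALS PLS, VIP, PLS-DA

The engine is classical NIPALS with X-block deflation (and Y-deflation for
multi-response): per component, w ∝ X'u (unit norm), t = Xw, q = Y't/t't,
u = Yq/q'q, iterated to ‖Δw‖ < 10⁻¹⁰ (single-response models converge in
one step); deflate X by t p' with p = X't/t't. Coefficients
B = W(P'W)⁻¹Q'. Sign convention: the largest-|w| element of each weight
vector is positive, making outputs platform-stable. Fitted values at full
rank equal ordinary least squares (10⁻⁸) and at fixed A equal scikit-learn's
independent PLS solver (10⁻⁶) — both asserted on random fixtures; loading
signs are not compared.

Explained Y sums of squares per component, SSYₐ = (t't)·q q', feed the VIP:

VIPⱼ = √( p · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ ),  Σⱼ VIPⱼ² = p identically.

Per-class VIPs restrict SSYₐ to one response column. Note a practical
limitation found during development: because the latent components are
shared, per-class VIPs of correlated classes rank variables similarly and
do **not** localize a transient bin to its expression window. Trend
classification therefore uses VIP for *relevance* and the class-mean
intensity for *attribution* (a transient bin is assigned to the day-class
where its mean expression peaks).

PLS-DA encodes incubation days one-hot, with days 8 and 12 merged into one
class (1, 4, 8/12, 16) by default — the four-phase structure of the growth
curve. Assignment is by maximum predicted response column, ties toward the
first class in encoding order (logged); ROC/AUC per class provides the
threshold-based view.

## Validation

* **LOO-CV**: for each left-out sample, centring/scaling and the model are
  re-estimated on the remainder (no leakage; the source protocol is silent
  on this). RMSEC/RMSECV per component count; the working A is the smallest
  whose RMSECV is within 1 % (parsimony tolerance) of the minimum.
  R² = 1 − SSres/SStot, Q² = 1 − PRESS/SStot; Q² may be negative and is
  never clipped.
* **Permutation test** (default 1000 permutations; 400 also used in the
  reference tables; tests and the acceptance script run 99–199 as a
  problem-size choice): rows of Y are shuffled, the model refit at fixed A.
  Empirical p = (1 + #{Q²ₚₑᵣₘ ≥ Q²ₜᵣᵤₑ})/(1 + n_perm), never 0. The three
  named tests (Wilcoxon signed-rank, sign test, paired t) compare the true
  model's per-sample |residuals| against each permuted model's, one-sided,
  for both self-prediction and CV residuals; per-permutation p-values are
  aggregated by their median and each test reports max(SP, CV). The exact
  internals of the original toolbox's "model insignificance" table are
  unpublished; this operationalization is the package's own, configurable.
  Under an exchangeable null the empirical p is uniform by construction;
  the acceptance suite verifies the 5 % rejection rate over 200 null
  replicates within the exact binomial 99 % interval. The sign test is
  coarse at n = 15 (its p-values move in steps of binomial tail masses).

## Biomarker calls

A bin is **consumed**/**produced** when PLSr-relevant (VIP > 1, strict)
with a negative/positive regression coefficient; **transient_early**/
**transient_late** when PLS-DA-relevant for the day-4 or merged-8/12 class
but not PLSr-relevant (attribution by peak class-mean, above); otherwise
**unchanged**. PLSr relevance wins conflicts (logged).

The **induced** rule is the conjunction: VIP > 1 (PLSr or any PLS-DA
class), two-sided Welch t-test p < 0.005, and mean treatment area ≥ 3× mean
control area (control mean floored at 10⁻¹² on the unit-area scale). Areas
enter at the normalized, pre-g-log stage. Two numerical choices matter:

1. The t-test is computed on **log** areas restricted to the bin's
   **occurrence window** — the days whose treatment day-mean exceeds 5 % of
   the bin's maximum day-mean. Pooled over all days, a bin expressed on a
   single day can never reach p < 0.005 (between-day variance dominates the
   denominator), which would defeat the rule's purpose for transient
   inductions; the log scale stabilizes multiplicative replicate noise.
2. The fold change stays on the raw normalized means over all study
   samples. Unit-total-area normalization deflates treatment-group values
   when that group carries more total signal, so a metabolite amplified
   ~5-fold at the raw scale can show a normalized fold near the 3× cut —
   the stress-upregulated archetype is deliberately such a borderline case,
   and single-seed recovery occasionally misses it (sensitivity ~0.95–1.0
   across seeds).

No multiple-testing correction is applied by default, matching common
practice for this rule; a Benjamini–Hochberg helper is provided for users
who want the guard. The Spearman bin-correlation map uses average-tie
ranks; constant bins are reported as 0 and flagged. Because Spearman
correlation is rank-based it is invariant under g-log, which the suite
asserts.

## Mass annotation

Monoisotopic masses use the most-abundant-isotope table (C 12 exactly,
H 1.0078250319, N 14.0030740052, O 15.9949146221, Na 22.9897692809, ...).
Adduct m/z defaults to the **neutral-atom** convention (M + 1.0078250 for
[M+H]⁺): printed annotation tables in this field typically follow it, and
the reference values for the fed alkaloids and their products reproduce to
all four printed decimals under it (with truncation, not rounding, at the
printed precision). The physically exact cation convention (proton mass,
electron subtracted) sits behind `electron_correction=True`. Printed ppm
errors are reproduced by computing against the 4-decimal printed
theoretical mass. Biotransformation matching accepts a hypothesis when the
product−precursor mass difference equals the shift within 5 ppm of the
product mass (hydrogenation +2.015650, hydration +18.010565, oxidation
+15.994915, and the obvious negatives/methylation). A few rows of the
reference annotation table are internally inconsistent with the convention
established by the alkaloid rows (garbled formula strings in the source);
those are excluded from exact-reproduction tests.

## Synthetic data generator

The generator emulates the design, not any particular instrument. Per-bin
archetypes tie mean trajectories to the normalized growth signal
gn(day) = ln d(day)/ln d(max) (d from the built-in diameter tables:
feeding 1, 3.19, 7.54, 8.41, 9 cm; control 1, 4.9, 8, 8.5, 9 cm):

| kind | feeding group B | control F | default count |
|---|---|---|---|
| media_decay | base·(1−gn) | base·(1−gn) | 5 |
| growth_linked | base·gn | base·gn | 8 |
| alkaloid | base·e^(−0.45·(day−1)) | 0 | 2 |
| early_pulse | base on day 4 | 0 | 3 |
| late_pulse | base on days 8, 12 | 0 | 2 |
| stress_upregulated | 5·base·gn | base·gn | 1 |
| inert | base | base | 4 |

Base intensities are drawn log-uniformly over half a decade around 10⁵·²;
the alkaloid decay rate 0.45/day puts the fed compounds below 1 % of their
initial level by day 12. Replicate scatter is multiplicative lognormal at
CV 0.10 (a free choice — within-class variance is not published for such
data; it sits well below the 25 % QC rejection bound) plus an additive
floor of 0.1 % of the median base intensity so raw values stay positive.
QC rows re-draw the pooled study mean with the same noise. The census
(15 linear-relevant bins in the feeding group; 13 in the control once the
feeding-only kinds drop out; shared medium/fungal core) approximates the
reference study's bin bookkeeping rather than reproducing it exactly.

Ground truth marks as **induced** the feeding-only kinds (alkaloid, both
pulse kinds) and the stress archetype when its fold ≥ 3. The fed alkaloid
bins satisfy the operational triple criterion — treatment-exclusive, high
VIP, huge fold — even though biologically they are substrates, not
products; the report distinguishes them by their `consumed` trend class.
This is the intended reading of a criterion defined purely by VIP, p-value
and fold.

The chromatogram renderer turns any matrix row into Gaussian peaks (area =
bin intensity) on an optional smooth drift; trapezoidal re-integration over
±window recovers intensities within 1 %, closing the
simulate → render → baseline-correct → bin loop for testing.

What passing tests show — and what they do not: the generator plants clean
archetypes with independent lognormal noise; real binned TIC data carry
peak convolution, retention drift, correlated (injection-order) noise,
missing values and medium batch effects that are not modelled. Recovery
results on synthetic data demonstrate the machinery is correct and
calibrated, not that real studies will achieve the same sensitivity.

## Problem sizes and determinism

All stochastic stages consume a single seed split into fixed per-stage
substreams (CRC-tagged `SeedSequence`), so reports are bit-reproducible and
stages can re-run independently. Defaults in tests and the acceptance
script: 99–199 permutations, 10–20 seeded recovery runs, 200 null
replicates for the calibration study — sizes chosen so the whole suite
completes in a few minutes on one core while keeping Monte-Carlo error well
inside the asserted margins.

## Known limitations

* PLS-DA class assignment is the maximum predicted column, not a Bayesian
  or threshold rule; ROC output provides threshold-based views.
* The permutation paired-test aggregation (median across permutations,
  max of SP/CV) is one defensible choice among several; the empirical Q²
  p-value is the primary significance measure.
* The induced rule's fold change inherits the bias of total-area
  normalization discussed above.
* OPLS variants, k-fold CV schemes other than LOO, isotope-pattern scoring
  and spectral-library lookup are out of scope.
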