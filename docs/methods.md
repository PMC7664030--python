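# Methods

This note documents the modelling choices, defaults, and numerical
details behind `qsmart`, and what the synthetic-data experiments do and
do not establish.

## Cohort assembly

A drug qualifies as a small-molecule protein kinase inhibitor when its
molecular weight is strictly below 900 Da and it either carries an
inhibitory action label (*inhibitor*, *antagonist*, *suppressor*) in the
drug–kinase association tables or has a KINOMEscan percent-of-control
strictly below 5. Both bounds are read literally as strict inequalities.

Responses assayed by both contributing centers (the `source_flag`
covariate: 1 = Wellcome Sanger, 0 = Massachusetts General Hospital) are
handled per drug: Pearson r of log-IC50 over cell lines shared by both
centers decides between merging (r > 0.7, strict) and excluding the drug
outright; fewer than three shared lines counts as insufficient overlap
and also excludes. Merged values are weighted means; the weight is the
replicate count when the input provides one and 1 otherwise, so the
merge degenerates to the arithmetic mean in the absence of replicate
information. Merging is idempotent.

Cell lines must satisfy all of: whole-genome-sequenced mutation profile,
at least 30 drug-response entries, available expression profile, and at
least one mutation mapping to a reference-PKA position. Groups are
primary sites, with two refinements: the haematopoietic-and-lymphoid
group splits on primary histology, and lung splits into NSCLC (six
histology subtypes: adenocarcinoma, non-small cell carcinoma, squamous /
large / giant cell carcinoma, mixed adenosquamous carcinoma) versus
"lung (others)". Groups under 1000 responses are excluded for low power.
Unrecognized sites become groups verbatim; there is no hard-coded site
whitelist.

## Feature engineering

Residue-level features live on the reference protein kinase A coordinate
system, one column per observed (position, property):
`PKA_<pos>_<PROP>` with PROP ∈ {MUT, CHA, POL, HYD, ASA, VOL, ENE, BLO}.
For each mutation the property delta is value(mutant) − value(wild-type);
multiple mutations of a cell line at one position are **summed**, which
keeps the deltas additive with the MUT count and makes them antisymmetric
under swapping wild type and mutant. BLO is the BLOSUM62 score of the
substitution (taken from Biopython's substitution matrices); polarity is
coded polar = 1 / nonpolar = 0 so its deltas lie in {−1, 0, 1}. The other
scales are packaged assets, swappable through `AminoAcidPropertyTable`:
unit formal charges, Kyte–Doolittle hydropathy, Tien et al. theoretical
maximum accessible surface area (Å²), Zamyatnin side-chain volumes (Å³),
and Guy transfer free energies (kcal/mol) for the per-residue energy.
Non-canonical residue letters and mutations without a mapped position
are skipped and logged.

Motif, domain, family, reaction, pathway, and GO-process features are
mutation counts: the value of entity E for a cell line is the number of
that line's kinase mutations in genes annotated to E. Gene-level
features are per-gene mutation counts plus expression and copy-number
passthrough on the scale of the input tables (no re-normalization;
missing values are zero-filled after logging so downstream products stay
defined). Sample-level categoricals are dummy-coded with k−1 indicators,
reference level lexicographically first, the mapping recorded for exact
decoding.

Drug features (fingerprint bits, descriptors) are consumed as tables.
Their priority order — later fingerprint bits (complex substructures)
before earlier ones, all fingerprints before descriptors — drives the
stepwise VIF screen, on the rationale that substructure bits are directly
interpretable whereas aggregate descriptors are not.

## Interaction terms

Candidates are products of named columns: fingerprint bit × residue
feature (`PKA_187_CHA_X_Fingerprint_805`), expression × expression for
retained PPI edges (STRING-style score strictly > 700, non-self, at least
one kinase endpoint, both expressions present), and same-namespace
count × count pairs with ancestor-related pairs removed under the
transitive closure of the ontology's child→parent edges (a cyclic
hierarchy is an error). Interaction names sort their components
lexicographically except drug×mutation, which is residue-first by
convention.

Each candidate is tested by the nested-model F-test — full model:
intercept + both components + product; reduced: intercept + both
components; F = (RSS_red − RSS_full)/(RSS_full/(n − p_full)) with p from
F(1, n − p_full) — pooled across drugs and cell lines within one cancer
group, since the group is the unit of training. Candidates with fewer
than 30 non-zero values are skipped before testing; the retention filter
is conjunctive anyway, so this changes nothing but compute. p-values are
Benjamini–Hochberg adjusted across all tested terms of the group and
terms kept at q < 0.05 with ≥ 30 non-zero values. The test's type-I
error is verified by simulation to sit at the nominal α under a Gaussian
null.

## Screening and selection

VIF screening is exact greedy: features are visited in priority order
and a candidate is accepted only if, after adding it, every kept
feature's VIF = 1/(1−R²ᵢ) stays ≤ 5 (recomputed each step, not batched).
Exactly collinear candidates hit an infinite-VIF sentinel; constant
columns are flagged as undefined and dropped. Drug features and
co-expressed genes are screened within their own blocks; residue and
count features pass through unscreened.

Lasso-BIC selection standardizes columns to zero mean and unit variance,
computes the Lasso regularization path (100 points, ratio 10⁻³), and
scores each path point by BIC = k·ln(n) − 2·ln(L̂) with k the number of
non-zero coefficients and L̂ the Gaussian likelihood, variance RSS/n, of
the **least-squares refit** on that point's support. Scoring the refit
rather than the penalized fit is deliberate: the shrinkage bias of the
penalized fit inflates its RSS, which BIC then offsets by admitting one
or two spurious extra features; the refit-scored criterion selects
supports whose BIC matches exhaustive all-subsets search to well within
one unit on small designs, while recall of planted signals is unchanged.
Reported coefficients are the Lasso coefficients of the chosen path
point, back-transformed to the original scale; the pipeline's linear
view is an OLS refit of the selected support.

The ensemble alternative ranks every feature by four criteria — absolute
Pearson correlation with the response, an RReliefF-style
nearest-neighbour relevance score (k = 5 neighbours on standardized
features), permutation importance from a plug-in regressor (default:
50-tree random forest), and Lasso path entry order — averages the ranks,
and keeps the top k with k taken from the Lasso-BIC support size. The
relevance and importance rankers are implemented in-package with
behavioural contracts (a single informative feature must rank first by
all four criteria) rather than binding any particular external
attribute-evaluator implementation. Ties break by feature name.

## The response model

The linear view is exactly affine in the selected features, so a unit
perturbation of a feature moves the mean prediction by exactly its
coefficient — the property the explanation utilities rely on.

The neural view is a fully connected feed-forward network: TanH hidden
activations, linear output, biases into hidden and output layers, hidden
widths from the geometric pyramid rule on the input count N
(single: ⌈N^½⌉; double: ⌈N^⅔⌉, ⌈N^⅓⌉; complex-double: N, ⌈N^½⌉, computed
with exact integer ceilings — floating-point powers misround perfect
powers such as 8^⅔). Inputs and the response are standardized
internally; predictions are returned on the original scale. Training
minimizes mean squared error plus an L1 penalty on weights (biases
unpenalized), smoothed as √(w² + 10⁻⁸) for differentiability, with
L-BFGS — a deterministic batch quasi-Newton method, so a fixed seed
reproduces weights bit-for-bit. "Iterations" (the 200/300 of the
escalation schedule) are optimizer iterations. Early stopping watches
the held-out fold's loss with patience 10 and tolerance 10⁻⁶, keeping
the best-validation weights; a fold that neither converges nor stops
early is flagged, never dropped. The penalty strength is chosen per fold
from the grid {10⁻⁴, 10⁻³, 10⁻²} by validation loss, and the final model
is refit on all data with the hyperparameter from the best-validating
fold. Cross-validation folds (default 10) are disjoint, exhaustive, and
seed-reproducible.

The escalation schedule tries (single, 200), (single, 300),
(double, 200), (double, 300), (complex-double, 200), (complex-double,
300) and stops at the first stage with mean CV R² ≥ 0.8; if none
reaches it, the best stage is returned with a flag in the trace.
The 0.8 threshold is interpreted as **mean cross-validated** R² — the
average performance of the ten fold models is the reported statistic —
rather than full-data R².

## Evaluation and explanation

R² = 1 − RSS/TSS and RMSE are reported per group; with multiple groups
both poolings (per-group R² and pooled residuals) are available since
the aggregation convention is genuinely ambiguous. Classification AUC
uses multiple sensitivity thresholds on actual log-IC50 (−4, −3, −2,
−1, 0), labels "sensitive" as actual < t, scores with the negated
prediction (lower predicted IC50 ⇒ more sensitive — forced by
pharmacology), and averages the per-threshold AUCs; thresholds yielding
one class are skipped and recorded. For plotted overall curves, ROC
points are interpolated onto a common false-positive grid before
averaging; the scalar contract is the AUC average.

Unit-perturbation attribution raises one feature by one unit in every
row, holds everything else fixed, and reports the change in mean
prediction (exactly the coefficient on the linear view; a finite
difference of forward passes on the network view). PPI edge impacts
tabulate this delta per expression-product term with a sign class;
|delta| ≥ 0.05 separates strong from weak, exposed in the configuration
because no principled cut exists. Model families are compared with the
two-sided Wilcoxon signed-rank test on paired per-group scores (p = 1
by convention when all differences vanish).

## Synthetic data and what it shows

The generator's defaults define the study conditions: 40 drugs × 50
cell lines = 2000 responses in one NSCLC-like group; 16 independent
Bernoulli(0.4) fingerprint bits plus two exactly collinear low-priority
copies (which the VIF screen must remove); 25 genes (15 kinases) with
log-normal expression (σ = 0.8 — wide enough that an expression product
is not numerically collinear with its two main effects, which is what
makes PPI-term recovery well-posed); 1 + Poisson(2) kinase mutations per
cell line at reference positions, plus a charge-changing hot-spot
mutation at PKA position 187 in 35% of lines; GO/reaction/pathway
annotations with one planted parent–child edge to exercise the hierarchy
exclusion. Five effects are planted — two main effects
(`Fingerprint_800` +1.0, `EXP_KIN03` +0.6), one interaction of each
buildable class (`PKA_187_CHA_X_Fingerprint_805` +1.2,
`EXP_GEN03_X_EXP_KIN07` +1.0, `GO_0030324_X_GO_0048675` +0.8) — plus an
additive assay-source batch effect (−0.5 on `From_Sanger`). Noise is
Gaussian with σ set to signal variance / 10 (SNR 10, capping attainable
R² at ≈ 0.909); the intercept (−2.0) places the log-IC50 distribution
across the classification thresholds. The planted truth (coefficients
and the realized noiseless signal) is emitted with the bundle, so every
response is recomputable from the generated features — a closure
property the tests assert.

Under these conditions the pipeline recovers the planted support with
mean recall ≈ 0.97 over 20 seeds and the single-layer pyramid network
reaches mean 10-fold CV R² ≈ 0.91. Two caveats bound what that shows.
First, the generator's response *is* the model's linear form; recovery
demonstrates the machinery (term construction, testing, screening,
selection, training) is correct and calibrated, not that the model fits
real pharmacogenomic data, whose noise is non-Gaussian, whose effects
are not sparse products, and whose assay artifacts exceed a single
additive batch shift. Second, when recall dips below 1 the miss is
essentially always the drug×mutation term being displaced by a sibling
at the same position (e.g. the polarity delta instead of the charge
delta times the same bit) — the residue property deltas at one position
are correlated by construction, and the selected sibling carries the
same biological content. The recovery harness scores exact-name
recovery and therefore understates biological recovery.

Problem sizes in the test suite and acceptance script (2000 responses,
20 recovery seeds with selection-stage models, network cross-validation
on a subset of seeds, 1000-replicate F-test calibration at n = 200) are
the package's chosen defaults balancing statistical resolution against
a desk-scale run.

## Known limitations

* Fingerprints and descriptors are consumed as tables; no structure
  processing beyond identifiers is performed.
* The reduced-training stability check resamples responses, not cell
  lines; a line-level jackknife would be stricter.
* The escalation schedule trains architectures sequentially; no warm
  starts between stages.
* With ~50 distinct cell lines, chance correlations among expression
  products are non-negligible; some statistically significant
  interaction terms in the synthetic runs are such confounds, which is
  why support precision (~0.8) trails recall.
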