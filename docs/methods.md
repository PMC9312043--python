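# Methods

## Problem and scope

Multiple-system atrophy (MSA) combines autonomic dysfunction, parkinsonism
and cerebellar ataxia in proportions that shift over the disease course. The
historical subtypes — striatonigral degeneration (SND), Shy-Drager syndrome
(SDS) and olivopontocerebellar atrophy (OPCA) — emphasise one component each.
This package reconstructs, as tested code, a diagnostic analysis over a
national registry's case-report form: encode the form's mixed-type items into
a design matrix, train an interpretable classifier that emits per-case linear
weights, estimate generalisation by nested cross-validation with one-vs-rest
AUC, and aggregate the per-case weights into per-subtype important features.

The registry itself is an anonymised government database and cannot be
shipped, so the package includes a first-class synthetic cohort generator
parameterised from the published per-subtype marginal distributions. All
full-scale results in `results/` are therefore computed on synthetic
cohorts; what that does and does not show is discussed at the end.

## Registry schema and missing data

The form (module `registry`) has 63 items: sex, age, three onset-symptom
flags, mode of onset, progression, 11 graded neurological findings (walking
capacity 1–9, standing capacity 1–8, the rest 1–5), 6 autonomic findings,
14 other neurological findings (12 binary, a 3-level tendon-reflex item, and
one free-text item), 9 brain-imaging flags, 7 graded ADL items (1–3, walking
1–4), 8 medication items and the diagnosis label. Two-level items use the
registry's convention `1 = presence, 2 = absence`. Medication, the free-text
item and the label are excluded from modelling, leaving 53 modelling items.

Erectile dysfunction is asked of males only; for female cases it is treated
as structurally absent — not missing — and encoded as the absence code. The
complete-case filter (`exclude_incomplete`) drops any case missing any
modelling item. The generator's default missingness is calibrated so that
the *per-case* probability of at least one missing answer is 157/3377
(the registry's observed exclusion pressure); internally this is spread
uniformly across items as `q = 1 - (1 - rate)^(1/m)` applied independently
per (case, item). The per-case reading was chosen over a per-item reading
because it is the quantity the exclusion step acts on and makes the
expected exclusion count exact.

## Synthetic cohort generator

Given a subtype, items are sampled independently (`synthcohort`):

* binary items as Bernoulli at the published prevalence (percentages of the
  registered arm sizes 894/377/2106); default generated arm sizes are the
  modelled 851/359/2010;
* sex from the published male:female ratio r as p_male = r/(1+r);
* age as normal(mean, sd) rounded and clipped to 30–100 years (adult-onset
  disease);
* categorical items from the published proportions (rows summing to
  0.999–1.001 from printing precision are renormalised);
* graded (ordinal) items from a normal(mean, sd) truncated to
  [lo−0.5, hi+0.5] and rounded to the nearest level. This is the simplest
  law matching a bounded scale summarised as mean ± SD, and it has
  closed-form level probabilities (`ordinal_level_probs`) that double as an
  exact testing oracle. Sampling is by inverse CDF over those probabilities,
  so draws follow the law exactly.

The CT/MRI "examination performed" flags have no published per-subtype
rates; they are set to 0.95/0.90 uniformly, reflecting near-universal
imaging in a hospital-registered cohort (they carry no class signal).
Conditional independence given subtype is a deliberate simplification —
only marginals are published. An optional Gaussian-copula layer
(`copula_rho`, default 0) can induce rank correlation among graded items
for sensitivity checks; it preserves each item's marginal law.

## Feature encoding

Two design-matrix variants (`encoding`):

* **variant a** (58 features): graded items and mode of onset keep their
  rank as a single integer column; progression and tendon reflex are
  one-hot; binary items are single indicators; age is standardised.
* **variant b** (126 features): every graded item and mode of onset is
  expanded to one-hot indicators over its full scale (neurological block
  9+8+5×9 = 62 columns, ADL 6×3+4 = 22).

Binary features are encoded as `registry code − 1`, i.e. presence → 0,
absence → 1: the indicator marks *absence*. This follows the registry's
reversed coding and fixes the published sign semantics of the model's
weights — a negative weight on such a feature means the finding's presence
pushes the case toward the subtype. Age, the only quantitative feature, is
standardised with statistics fitted on the training split only and frozen
for test folds; because standardisation is affine, cross-validation refits
fold statistics on the already-encoded column with identical results.

## The pointwise linear model

A hypernetwork maps each encoded case x(n) ∈ R^d to per-class weights
w_c(n) ∈ R^d and bias b_c(n); the class score is z_c(n) = w_c(n)·x(n) +
b_c(n) and probabilities are softmax(z). The trunk is an MLP: a linear
input layer d→H with ReLU, then `n_inner_layers` H→H ReLU layers with
dropout, then a linear head emitting C·(d+1) numbers. The head is
initialised to zero, so an untrained model predicts uniform probabilities;
the trunk uses He-normal initialisation. Input dropout is applied to the
trunk's copy of x only — the linear scoring always uses the clean input, so
the explanation identity z = w·x + b holds exactly at every point.

The loss is cross-entropy against label-smoothed targets
t_c = (1−ε)·1[c=y] + ε/C plus an elastic-net penalty on the *emitted*
per-sample weight vectors, λ(α·mean‖w(n)‖₁ + (1−α)·½·mean‖w(n)‖₂²),
averaged over the batch. Penalising the emitted weights rather than the
trunk parameters regularises the explanation surface directly; the
per-sample bias is excluded (penalising intercepts distorts calibration).
Optimisation is minibatch Adam with β₁ = the configured momentum,
β₂ = 0.999, ε = 1e−8, seeded shuffling each epoch.

Default hyperparameters (the tuned configuration): 100 epochs, 16 inner
layers of size 180, label smoothing 0.055, learning rate 1.83e−4,
β₁ 0.968, input/inner dropout 0.171/0.027, λ 9.29e−5, α 0.048. Batch size
(128), the nonlinearity (ReLU), β₂ and Adam's ε are not part of the tuned
set and are fixed at these conventional values, recorded in every config
snapshot.

Forward and backward passes are written out by hand in float32 numpy;
gradients are verified against central finite differences in the test
suite, and the forward pass against a direct matrix-product oracle. With a
zero head the trunk initially receives no gradient; the head moves first
and the trunk follows — on this near-linearly-separable problem that is
benign, and training curves are logged per epoch to confirm descent.

Two reduced modes: `constant_weights=True` bypasses the trunk (one shared
weight matrix — exactly multinomial logistic regression with elastic net;
the test suite checks it matches an independently fitted logistic
regression within 0.02 AUC), and `ovr_models=True` trains one two-class
model per subtype and renormalises the positive-class probabilities. The
default is a single softmax model: held-out probability rows summing to 1
is the behaviour the analysis reports.

## Evaluation

Folds are stratified by subtype and seeded (the 359-case SDS arm makes
unstratified 10-fold splits fragile). ROC-AUC is computed in the
Mann–Whitney form via midranks (ties get half credit) and cross-checked
against brute-force pairwise concordance and scikit-learn. Double
cross-validation uses 10 outer folds and 5 inner folds (the inner count is
a runtime-motivated package choice; it is configurable). The default grid
is the singleton tuned configuration, in which case the inner loop is
skipped as selection is trivial; with a real grid the inner CV selects by
highest mean inner test AUC. Train AUC is computed on the outer-training
split with the refit model. The held-out protocol removes 10 random cases
per subtype (3220 → 3190 at full scale), trains on the remainder and
tabulates the 30 cases' probabilities.

## Importance

For one subtype's weight matrix, s_k(n) = |w_k(n) x_k(n)|; each case
contributes its top m = ceil(0.1·d) features (ties toward the lower
codebook index, so the set is always full and deterministic); the
feature-level score is the membership rate over cases, thresholded
inclusively at 0.30. Median weights are taken over all cases by default
(`weight_population="topset"` restricts to cases whose top set contains the
feature; restriction to one subtype's cases is row selection by the
caller). Note that with absence-marking binary coding, s is zero whenever
the finding is present; a finding can still dominate because the cases
*without* it carry large |w|·1 products — the published coding note makes
this the faithful reading, and the direction is recoverable from the median
weight's sign. Features are grouped into clinical components
(A = autonomic, P = parkinsonism, C = cerebellar) by their source item via
an editable map; items without a clear single-component reading stay
"unassigned". The sign label is P (strong relationship) when the median
weight indicates a stronger association under the feature's encoding
direction — negative for absence-coded binaries, positive otherwise.

## Cohort statistics

Graded/quantitative items: mean ± SD and tie-corrected Kruskal–Wallis.
Binary/categorical items: counts (%) per subtype and Pearson chi-square;
when the omnibus test is significant at 0.05, adjusted residuals
(O−E)/sqrt(E(1−row/N)(1−col/N)) flag cells beyond ±1.96 as larger/smaller.
p-values print to three decimals, "<0.001" below that. No multiplicity
correction is applied across table rows (matching the reporting convention
the table emulates). Degenerate inputs: identical values across all groups
give H = 0, p = 1; a zero-margin contingency table is rejected.

## Numerical and design choices

* float32 training with float64 softmax/statistics; probability rows sum
  to 1 within 1e−9.
* sd floor 1e−8 in standardisation (a constant column maps to zeros).
* Importance tie-break and the ceil top-set size are fixed conventions so
  reruns are byte-identical; cohort generation, fold plans, training and
  held-out selection all derive from explicit integer seeds.
* Problem sizes in tests: protocol and property tests use cohorts of a few
  hundred cases and a small trunk; the model-performance check and the
  reproduction script run the full 3220-case cohort with the tuned
  configuration.

## What the synthetic results do and do not show

Passing tests show the *pipeline* is correct: encodings match the published
feature counts, the generator reproduces the published marginals, the model
recovers planted discriminative features, and the evaluation protocol is
leak-free (label permutation gives chance AUC). They do not certify
real-data performance. Synthetic items are conditionally independent given
subtype, which removes the redundancy and noise correlation of real
clinical data and makes the classification easier — the nested-CV AUC on
synthetic cohorts (~0.99) should be read as "at least the published
real-data level", not as a reproduction of it. Per-case probability values
and the precise importance rankings of the real cohort are likewise not
reproducible here; the package reproduces their *shape* and the statistic
definitions exactly.

## Known limitations

* No disease-course, registration-year or regional structure in the
  generator; no item-level missingness profiles (missingness is uniform).
* The trunk architecture is the minimal structure consistent with the
  tuned hyperparameter list; alternatives (residual trunks, per-class
  heads) were not explored.
* The component map covers items with a clear clinical attribution;
  ambiguous items (e.g. dysphagia, dementia) are left unassigned rather
  than forced.
* L-DOPA responsiveness and medication are outside the modelling scope.
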