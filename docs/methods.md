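# Methods

This note documents the models, the numerical choices, what the
synthetic generators do and do not emulate, and the known limitations.

## Endpoints and units

Slope factors quantify carcinogenic potency as risk per unit chronic
daily intake, (mg/kg-day)⁻¹. Incremental lifetime cancer risk is
CR = CDI × SF. Inhalation toxicity is published as a unit risk IUR in
(µg/m³)⁻¹ and is converted to the common dose scale with
ISF = IUR·BW·CF/IR, using the standard adult scenario BW = 70 kg,
IR = 20 m³/day, CF = 1000 µg/mg (so IUR = 1 maps to ISF = 3500).
Regression targets are log₁₀ SF; classification labels derive from the
presence (carcinogen) or absence (non-carcinogen) of a slope factor,
which inherits the database's convention that unevaluated ≈ inactive —
a known source of label noise discussed under limitations.

## Curation rules

Structures are parsed with RDKit. Multi-fragment inputs drop fragments
with fewer than two heavy atoms (counterions, hydration water); if more
than one distinct multi-atom fragment remains the input is an
unresolvable mixture and is rejected. The surviving parent must contain
carbon and only {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}; carbon-free
inputs are inorganic, carbon-bearing inputs with other elements are
metal species. The parent is neutralized (RDKit Uncharger) and written
as canonical SMILES, which defines structure identity for
deduplication: copies with equal endpoint values merge, copies with
conflicting values are all removed (incongruent sources are not
averaged). Standardization is idempotent by construction.

## Descriptors

The open RDKit 2D descriptor set (~210 descriptors, plus aromatic-atom,
heavy-atom and bond counts) replaces a proprietary engine; selected
descriptor names therefore differ from any prior work built on that
engine, which is why no external statistics are reproduction targets
here. Each descriptor carries a block tag; the constitutional and ring
blocks feed the classification split. Pruning removes, in order:
descriptors with missing values, constants, semi-constants (one value in
more than 95 % of compounds), and for each pair with |Pearson r| > 0.95
the name-sorted-later descriptor (greedy keep-first scan, so the
surviving set provably contains no pair above the threshold; a test
verifies this by exhaustive scan).

## Splits

*Venetian blinds (classification).* Columns of the constitutional + ring
blocks, plus the class value as one extra column, are standardized; the
first principal component (SVD, sign fixed so the largest-magnitude
loading is positive; ties in scores broken by compound id) ranks the
compounds, and every k-th ranked compound (k = round(1/(1−train_frac)),
default 5) becomes test. Degenerate input with no column variance falls
back to id order.

*Activity sampling (regression).* Compounds are sorted by endpoint and
cut into 10 equal-count bins (bin count unstated in the source
procedure; 10 matches a 10 % extraction granularity). Global subset
sizes use nearest-integer rounding with the remainder to the training
set — scheme A: |ES| = round(0.1 n), then |TrS| = round(0.8 (n−|ES|));
scheme B: |TrS| = round(0.8 n) — and are apportioned across bins by
largest remainder, filled by seeded draw within each bin, so every
subset spans the activity range. For n = 315 under scheme A this yields
226/57/32.

## Feature selection

*Forward selection with bootstrap-LDA fitness (classification).* The
first descriptor maximizes |point-biserial correlation| with the labels.
Each subsequent iteration draws one set of bootstrap resamples (default
100) shared by all candidates, fits LDA per resample, evaluates on the
out-of-bag compounds, and adds the candidate maximizing mean accuracy +
mean sensitivity + mean specificity (equal weights; the combination's
coefficients are a design choice). Ties break to the name-sorted-first
candidate; the whole procedure is bit-reproducible under its seed. The
subset size is the plateau of the fitness trace: the smallest size whose
fitness no later value exceeds by more than the tolerance (default
0.01).

*GA-PLS (regression).* Chromosomes are descriptor subsets of size 5–12.
Fitness is the r² of pooled held-out predictions under repeated double
cross-validation: inner folds choose the PLS component count (1–5) by
PRESS, outer folds assess. Paper-scale defaults are population 2000,
5000 generations, 5 outer × 5 inner folds × 3 repetitions; the
test-scale configuration uses population 200, 50 generations and
4 × 3 × 1, which preserves the double-CV structure while keeping the
planted-recovery studies inside a few minutes. The GA uses tournament
selection (size 3), uniform membership crossover with random add/drop
size repair, swap mutation (rate 0.1) and elitism of 10 distinct
subsets, so the best-so-far fitness is non-decreasing. Subset fitness is
memoized and its CV seed derives from the subset itself, making fitness
independent of visit order. The PLS core is a NIPALS implementation
exposing the full component path from a single fit (needed to keep the
GA inside its time budget); a test pins its predictions to
scikit-learn's `PLSRegression` at 1e-8.

## Learners

*CART.* Trees are grown on Gini impurity (min 5 per leaf, min 20 to
split) and pruned by weakest-link cost-complexity on misclassification
risk — the classical formulation, under which splits that do not change
the predicted class collapse at strength zero. Candidate strengths are
the geometric midpoints of the master tree's alpha sequence plus a
guaranteed root-only candidate; each is scored by pooled 10-fold
stratified cross-validated error averaged over 5 fold shufflings, and
the strongest pruning within one binomial standard error of the minimum
wins (1-SE rule). On signal-free labels this collapses the tree to the
root majority rule in roughly four of five datasets; the remainder
contain spurious structure that genuinely cross-validates, which no
data-driven pruning rule can distinguish from weak signal (the R
`rpart` reference with its own 1-SE selection collapses fewer still on
the same data).

*MLP.* One hidden layer of 10 logistic-sigmoid units, linear output.
Inputs are min-max scaled to [0, 1] with training bounds stored in the
model; out-of-range query values pass through unclipped and are left to
the applicability domain to flag. Targets are raw log₁₀ SF. Training is
100 full-batch epochs of RPROP⁻ (no weight backtracking): per-weight
step sizes start at Δ₀ = 0.1, grow by η⁺ = 1.2 on gradient-sign
agreement, shrink by η⁻ = 0.5 on disagreement (with that epoch's update
suppressed), clipped to [1e-6, 50]. Weights initialize uniform(−0.5,
0.5) from the seed. A constant descriptor in the selected set is an
error (its scale is undefined).

## Applicability domain

PCA on the standardized model descriptors of the training set; scores on
the first two components; a query is inside the domain iff both scores
lie in the closed [5th, 95th] percentile interval of the training scores
(linear-interpolation percentiles; closed ends so exact-percentile
training compounds stay inside; component signs fixed as in the splits).
By a union bound at least 80 % of any training set is inside its own
domain. The domain filters test and external statistics only — training
metrics are reported at full coverage. Out-of-domain predictions are
emitted with an "outside" flag rather than suppressed, so coverage can
be computed downstream. A simpler per-descriptor rule (outside iff any
|z| > 3) is available as `zscore_outside` for comparison; it is an
approximation, not a calibrated consensus method.

## Validation metrics

r² = 1 − RSS/TSS; RMSE; MAE as the mean absolute residual. External
validation follows the through-origin family: k = Σyŷ/Σŷ²,
k′ = Σyŷ/Σy², r₀² and r₀′² the corresponding through-origin
determination coefficients, r²m = r²(1 − √|r² − r₀²|) with r² the
squared Pearson correlation (absolute value under the root so the
expression stays real when r₀² exceeds r²), reverse r²m from swapping
the roles, plus their mean and absolute difference. CCC is Lin's
concordance correlation with 1/n moments; F = (n−2)·r²/(1−r²) of the
observed~predicted fit. Sensitivity or specificity is reported as NaN —
never zero — when its class is absent. All formulas are locked by an
independent direct-summation oracle test at 1e-6.

## Synthetic generators

The regression generator draws i.i.d. standard-normal descriptors and
y = Σwᵢxᵢ + N(0, σ²); the classification generator shifts class 1 by
s/√m along each of m informative axes so the between-class Mahalanobis
distance is exactly s. The default recovery studies use n = 200, σ = 0.3
(MLP) and n = 150, 30 descriptors, 5 informative, σ = 0.2·√5 (GA),
sizes chosen so each study completes in minutes while leaving the
planted signal comfortably above the noise floor. The toy SMILES
generator emits ~75 simple organics whose synthetic log-potency is
0.6·rings + 0.3·chlorines − 1 + N(0, 0.1), mirroring the real trend that
fused rings and halogenation track potency; endpoint values are a pure
function of structure and seed so re-drawn duplicates merge cleanly.
None of the generators emulate real descriptor distributions —
descriptors are uncorrelated Gaussians, whereas real 2D descriptors are
heavy-tailed, discrete and strongly collinear — so passing recovery
tests demonstrates algorithmic correctness, not expected performance on
chemical data. A loader for the published curated tables is provided
for user-supplied files (schema-tolerant column matching; never
downloaded automatically).

## Known limitations

- Non-carcinogen labels mean "no slope factor published", not proven
  inactivity.
- The open descriptor set differs from proprietary engines, so models
  trained here are not numerically comparable to prior published
  statistics.
- The CART noise-collapse rate is bounded by what cross-validation can
  see (above).
- The GA's paper-scale settings (2000 × 5000) are computationally heavy;
  the test-scale configuration is the practical default.
- Permanently charged organics (e.g. quaternary ammonium) are retained
  as-is after neutralization fails to produce a neutral form.
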