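# sfqsar

QSAR models for human carcinogenicity slope factors.

Risk assessors characterizing contaminated sites need two numbers for
every chemical: *is it carcinogenic?* and, if so, *how potent is it?*
Potency is expressed as a slope factor — the upper-bound slope of the
low-dose cancer dose–response curve, in (mg/kg-day)⁻¹ — with separate
values for the oral route (OSF) and the inhalation route (ISF, obtained
from the inhalation unit risk via ISF = IUR·BW·CF/IR with BW = 70 kg,
IR = 20 m³/day, CF = 1000 µg/mg). Experimental slope factors exist for
only a few hundred chemicals, so `sfqsar` builds quantitative
structure–activity relationship models that predict both answers from a
SMILES string alone, applied hierarchically: a classification tree
screens for carcinogenicity first, and a regression network estimates
log₁₀ SF only for predicted carcinogens, guarded by an applicability
domain.

## The workflow

**Curation** — structures are neutralized, counterions stripped, and
inorganics, metal species and unresolvable mixtures rejected; duplicate
structures with conflicting endpoint values are dropped rather than
averaged. Compounds with a defined slope factor are labeled carcinogenic;
compounds without one, non-carcinogenic.

**Classification branch** — RDKit 2D descriptors are pruned (missing,
constant, semi-constant, pairwise |r| > 0.95), the dataset is split by
venetian blinds on the first principal component of the constitutional
and ring descriptor blocks, descriptors are chosen by forward selection
with a bootstrap-LDA fitness (mean accuracy + sensitivity + specificity
on out-of-bag compounds) up to the fitness plateau, and a CART tree is
grown and pruned by cost-complexity with internal cross-validation.

**Regression branch** — endpoints are log₁₀-transformed and split by
activity sampling (scheme A: 10 % external set, then 80/20 train/test;
scheme B: 80/20 train/external). Descriptor subsets of 5–12 variables
are searched by a genetic algorithm scored with repeated double
cross-validated PLS r²; each elite subset trains a multilayer perceptron
(one hidden layer of 10 sigmoid units, inputs min-max scaled to [0, 1],
100 epochs of resilient backpropagation). Scheme A selects the model by
test-set r² with out-of-domain compounds excluded; scheme B by 10-fold
cross-validation on the training set. The applicability domain is a
closed [5th, 95th] percentile box on the first two principal components
of the training descriptors.

**Validation** — accuracy/sensitivity/specificity for the classifier;
r² = 1 − RSS/TSS, RMSE and MAE for the regressors, plus the external-
validation family: through-origin slopes k and k′, r²m / average r²m /
Δr²m, Lin's concordance correlation coefficient and the regression F
statistic, all with the fraction of compounds retained by the
applicability domain (coverage).

## Worked example

`examples/03_train_regression.py` trains the regression branch on a
synthetic dataset with five informative descriptors (n = 200, noise
σ = 0.5) at reduced search sizes:

```
selected descriptors: ['d000', 'd001', 'd002', 'd003', 'd004', 'd005', 'd010', 'd012', 'd019']
TrS: r2=0.929 rmse=0.557 coverage=1.00 (n=144)
TeS: r2=0.949 rmse=0.510 coverage=0.92 (n=33)
ES: r2=0.902 rmse=0.654 coverage=0.80 (n=16)
```

The GA recovered all five planted descriptors (d000–d004). TrS is the
resubstitution fit; TeS ranked the elite subsets; ES is untouched
external data — the honest estimate of predictive power. Coverage is the
fraction of evaluation compounds inside the applicability domain
(training-set statistics are never domain-filtered).

The other examples cover curation (`01`), descriptor pruning (`02`) and
hierarchical prediction (`04`). A thin CLI wraps the same library calls:

```bash
sfqsar curate  --input raw.csv --output curated.csv --rejections rejected.csv
sfqsar train   --input curated.csv --route oral --scheme A --out models/
sfqsar predict --models models/ --input smiles.csv --out predictions.csv
sfqsar metrics --input observed_predicted.csv
```

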