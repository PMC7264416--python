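# Methods

## Problem setting

The package detects prognosis risk biomarkers (PRBs) from four omics
layers measured on the same tumor cohort — gene expression and exon
expression (non-negative, log-scale), DNA methylation (beta values in
[0,1]) and somatic mutations (binary presence calls) — together with
overall survival (OS) and clinical covariates. Prognosis is treated as a
binary outcome: good (OS beyond 5 years = 1,825 days) versus poor (death
observed at or before 1,825 days). Samples censored before the threshold
have an unknowable 5-year status and are excluded from the dichotomy;
they still contribute to Kaplan–Meier/Cox analyses, which use the full
censoring information.

## Screening

Each feature is tested with a two-sided Welch (unequal-variance) t-test
between the prognosis groups. Two conventions make the screen total on
degenerate inputs: a feature with zero variance in both groups gets
p = 1 when the group means agree and p = 0 when they differ. Fold change
is oriented poor/good — FC = (mean_neg + ε)/(mean_pos + ε) with
ε = 10⁻⁸ × the layer's global mean — because planted (and, in the
motivating data, observed) risk features sit *higher* in the
poor-prognosis group; the symmetric gate (FC > 1.5 or FC < 2/3) makes
the orientation non-destructive. The top-1,000-by-p prefilter runs
before the gates, with ties broken by feature id so the screen is
invariant to input row order. Mutation features go through the same
t-test/FC machinery on their 0/1 values; this is the Welch test as a
two-proportion screen, adequate at the cohort sizes involved. Raw
p-values are used (no multiplicity correction): the screen is a ranked
prefilter feeding factor analysis, not an inferential endpoint.

## Factor reduction

Differential features of one layer are standardized and decomposed by
maximum-likelihood factor analysis with varimax rotation
(`sklearn.decomposition.FactorAnalysis`); acting on standardized data
makes the decomposition a correlation-matrix EFA, and factor scores are
the posterior means (regression-type scores). The factor count is the
Kaiser rule — eigenvalues of the feature correlation matrix strictly
above 1, floored at one factor — chosen because it is deterministic and
the default of common EFA tooling. Constant features are dropped with a
warning before eigendecomposition. Loadings are read as importance
weights: absolute value first (sign encodes direction, not magnitude),
then min-max scaling to [0,1] within each factor; a spread-less column
maps to 0.5 by convention. The top-weight feature per factor is kept as
that factor's *essential feature*, ties broken lexicographically and
duplicates collapsed, so a layer contributes at most one feature per
factor. For visual QC, factor-score matrices are concatenated across
layers, joined with log10(OS + 1) (the +1 guards zero survival times),
standardized and average-linkage clustered on Euclidean distance.

## Prognostic models and the shared split

Train/test sets come from Diverse Subset (farthest-point) sampling run
within each prognosis class on the z-scored essential-feature profile:
a seeded random first pick, then the farthest point, then repeatedly the
point with the largest mean distance to the current selection, stopping
at ceil(2/3 of the class). Ties break by sample id; the procedure is
deterministic given the seed. **One split is computed on the full
(all-omics) essential profile and shared by all 15 combination models** —
splitting per combination would hand each single-layer model a test set
central in its own feature space, which inflates every AUC to the
ceiling and destroys the single-versus-multi-omics comparison the
pipeline is designed to make. Farthest-point sampling deliberately
concentrates extremes in training; test AUCs are therefore optimistic
relative to random splits, which is a property of the sampling design
and not a defect of the classifiers.

Classifiers are scikit-learn estimators with fixed seeds where
stochastic: logistic regression (L2, C = 1), RBF SVM with probability
outputs, Gaussian naive Bayes, a single-hidden-layer (100-unit) MLP,
a 100-tree random forest, and ordinary least squares on the 0/1 labels
("LiR", scores clipped to [0,1], class at 0.5). Features are z-scored
with training-set constants only; the constants are stored on the model
and reused verbatim at prediction time (no test-set leakage). AUC is the
Mann–Whitney pair-concordance form (ties count ½), with the ROC curve
from a threshold sweep.

## Target regulation simulation

Eligible samples are the true negatives of the test set: label-negative
*and* predicted negative. Each essential feature, alone and in every
unordered pair, is clamped to the minimum of that feature over all
label-positive samples (train and test; the larger set stabilizes the
minimum). For a binary mutation feature this minimum is 0 whenever any
good-prognosis patient lacks the alteration, so "down-regulation" is
mutation removal. Clamped samples are re-standardized with the model's
stored train constants and re-predicted; a flip is a re-prediction to
good prognosis. All n + C(n,2) specs are evaluated without pruning
(n ≈ 100 features is cheap). The flip network sizes each node by the
number of distinct patients the feature affects (alone or in a pair),
weights each edge by the pair's flip count, and ranks features by the
number of flipping pairs they participate in; callers take the top-k
(the default report shows the top 3).

## Risk scoring

The prognosis risk score is an ordinary-least-squares regression of the
binary label on the biomarker panel — linear regression rather than
logistic, so the score is risk-like rather than a probability. Inputs
are standardized before fitting and the constants stored; a model can
also be instantiated directly from published coefficients, in which case
the standardization defaults to the identity. Rank-deficient (collinear)
panels are rejected. The decision threshold maximizes Youden's J over
midpoints of consecutive sorted unique scores, resolving ties to the
lowest optimal threshold.

## Survival analysis

Kaplan–Meier estimation, the one-degree-of-freedom log-rank test and Cox
proportional-hazards fits go through lifelines; Cox uses Efron tie
handling (the lifelines default). Conventions: a comparison with no
events anywhere returns statistic 0, p = 1; median splits send
ties-at-the-median to the low group; strata smaller than 4 samples are
skipped with a warning; Cox rows that fail to converge or have constant
covariates are flagged unestimable instead of raising. Clinical
covariates must be numeric — encode categoricals upstream; the age
stratification example uses the conventional cutoff of 65 years.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline expects
from a real tumor cohort without reproducing any real dataset:

- **Risk structure.** One core high-risk half of the cohort is drawn,
  then perturbed per omics layer by independent 15% sample flips. Layers
  therefore agree on most samples but each carries some layer-specific
  signal — single layers are prognostic on their own while only their
  combination tracks the core risk, the regime in which multi-omics
  integration is worth testing.
- **Planted features.** Continuous planted features are shifted upward
  by `effect_size` (default 1.5) standard deviations in the layer's
  high-risk subgroup; background features are i.i.d. normal on the
  layer's native scale (log-expression at location 1.5/1.8, scale
  1.0/1.2; methylation on the logit scale at −1.5, inverse-transformed
  to stay in [0,1]). The background locations are set so that a
  d = 1.5 shift corresponds to a group-mean ratio above the 1.5 FC gate
  even after the hazard-chain attenuation below — i.e. planted effects
  are detectable by the same two gates that real differential features
  pass.
- **Survival.** The latent risk is the standardized mean of all planted
  continuous values; OS is exponential with hazard
  `baseline_hazard × exp(risk_coefficient × latent_risk)`
  (defaults: ln2/1825 per day, putting median OS at the threshold, and
  risk_coefficient 1.5 ≈ hazard ratio 4.5 per risk SD). Censoring is
  administrative: with probability `censor_rate` (default 0.2) a uniform
  censor time replaces the event when it comes first. The definitive
  prognosis label is recomputed from the drawn OS, so planted effects
  are attenuated realistically rather than separating the groups by
  construction.
- **Mutations.** Planted mutation features are placed *after* the OS
  draw, Bernoulli(`mutation_rate_negative`, default 0.3) in definitive
  poor-prognosis samples and exactly 0 in good-prognosis samples,
  making mutual exclusivity with good prognosis hold by construction
  (and keeping mutations out of the latent risk). Background mutations
  occur at rate 0.05 in everyone.

What the generator does **not** model: inter-feature covariance beyond
the planted risk groups, linkage/co-methylation structure, batch
effects, copy-number or proteomic layers, or non-exponential hazards.
Tests passing on these cohorts demonstrate that the pipeline recovers
planted structure under its stated assumptions; they do not certify
performance on real cohorts, where effect sizes are smaller and
correlation structure richer.

## Problem sizes used in the test suite

The default synthetic cohort is 200 samples with 300/300/300/200
features per layer and 10 planted per layer. Recovery suites use 20–50
seeds per check; the null screen uses 5,000 features at a fixed seed
with a binomial 99% acceptance band around the nominal 1% level; the
multi-omics ordering check uses 20 seeded end-to-end runs. These sizes
keep the whole suite in the minutes range on one CPU while leaving the
statistical assertions well-powered.

## Known limitations

- The Kaiser rule tends to retain more factors as the feature count
  grows; parallel analysis would be a natural optional extension.
- The Welch screen on sparse binary mutation data is conservative at
  very low mutation rates; a two-proportion or Fisher screen could be
  swapped in behind the same interface.
- Farthest-point splits make test sets easier than random splits;
  reported AUCs should be read comparatively (between omics
  combinations), not as generalization estimates.
- OLS-based risk scores are not calibrated probabilities; only the
  ranking and the Youden threshold are meaningful.
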