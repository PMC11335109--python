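# Methods

This note documents the models and procedures dyadlink implements, the
choices made where the analysis design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real cohorts.

## The data model

A cohort is a table of mother–infant dyads with eight maternal indicators
(age, marital status, education level, gestation weeks, delivery mode, and
the CBTS / EPDS / HADS psychological screening scores) and six infant
indicators (behavioral class, gender, age, nightly sleep time, wake count,
sleep-onset mode). Categorical codes are 0-based; behavior classes are
quiet(0) / moderate(1) / contradictory(2) internally and shown as 1/2/3 only
in display output. Every numeric indicator carries a closed plausibility
window (e.g. gestation 28–43 weeks, CBTS 0–30); the windows serve three
roles — truncation bounds of the generator, default outlier-screening rules,
and schema validation — so "plausible" means the same thing everywhere.

Outlier screening is deliberately a transparent interval filter rather than
a statistical heuristic: a record is dropped iff at least one rule is
violated, the removed ids are reported exhaustively, and the rules are
ordinary configuration. Missing fields are handled by listwise deletion with
a logged count; no imputation model is offered.

## Spearman screening

Spearman's ρ is computed as the Pearson correlation of average (mid) ranks,
the standard tie-correct estimator; the dataset's categorical codes and
small-integer scores guarantee heavy ties, so the textbook
1 − 6Σd²/(n(n²−1)) form (exact only without ties) is retained purely as a
test oracle for tie-free inputs. Only coefficients are reported — the
screening ranks associations, it does not test them — and constant columns
yield NaN rows rather than aborting. Three-level behavior and five-level
sleep-onset mode are treated as ordinal in the correlations; for sleep-onset
mode this is a modelling convention, not a claim about the scale.

## Feature importance and selection

Importance magnitudes are the impurity-decrease importances of a seeded
500-tree random forest, normalised to sum to one. Impurity importance is
nonnegative by construction, so a "negative importance" display is
fabricated if taken from the forest alone; instead the *sign* of each
feature is reported separately as the direction of its Spearman correlation
with the target. Selection takes the top k = 4 magnitudes (ties broken by
canonical column order); k is overridable since 3–5 features perform
similarly on this kind of data. For the wake-count target the default
screening rule is the |ρ|-ranking rather than the tree ranking, mirroring
how that target is treated in practice; both rules are exposed for every
target.

## The MAE-gated ensemble

Two base learners predict the behavior class from min-max-scaled maternal
features: a one-hidden-layer MLP with logistic activation (16 hidden units
by default; trained by L-BFGS with an epoch cap treated as a training-length
choice) and a bootstrap random forest (500 trees, unlimited depth). Each
produces per-class scores and the numeric expectation Σ_c c·p_c; the
combination rule operates on the numeric predictions, which is why the
ordinal codes 0/1/2 double as the regression target for MAE and R².

The gate: with MAE₁ (MLP) and MAE₂ (RF) computed on the validation split,

    Δ = (MAE₁ − MAE₂) / max(MAE₁, MAE₂)

If Δ ≤ 0.05 the predictions are blended with Q₁ = MAE₁/(MAE₁+MAE₂),
Q₂ = 1 − Q₁; otherwise the higher-error model is discarded. Three gaps in
this rule required decisions:

- **Which split supplies the MAEs.** The validation split. Training MAE
  would be dominated by the forest's near-zero in-sample error and the gate
  would never blend.
- **The weights as stated weight each model by its own error** (a higher
  MAE yields a higher weight). They are implemented exactly so as the
  default, because that is the published form of the rule; the flag
  `inverse_error_weights` swaps to the conventional Q₁ = MAE₂/(MAE₁+MAE₂)
  for users who want error-inverse averaging.
- **Δ is signed**, so a much *better* first model still blends (Δ very
  negative). Default follows the signed form; `absolute_delta` gates on |Δ|.
- The boundary Δ = 0.05 blends (≤ wins); two exactly-zero MAEs blend evenly.

The blended numeric value is decoded to a class by round-half-down and
clamping to {0, 1, 2} — deterministic and order-preserving. The sigmoid is
the standard logistic 1/(1+e⁻ˣ). The comparison harness fits MLP, RF,
RF-MLP, RF-SVM and SVM-MLP (the SVM is an RBF SVC with sigmoid-calibrated
class scores); in a hyphenated pair "A-B" the B model plays the MAE₁ role.
Splits are a seeded uniform 50/20/30 partition with rounded train/validation
sizes and the remainder in test.

## Evaluation statistics

MAE and R² are the direct formulas; accuracy and the confusion matrix come
from exact label counts; multiclass AUC is the unweighted (macro) mean of
per-class one-vs-rest ROC areas in the rank/Mann-Whitney formulation with
ties counting one half. Classes absent from the truth vector are excluded
from the macro mean with a log message; a single-class truth vector has no
AUC. Both accuracy and AUC are reported for every model and split, since
"accuracy" tables in this literature are sometimes one and sometimes the
other.

## Fuzzy c-means sleep clustering

The three sleep indicators are min-max normalised (degenerate columns map
to 0) and clustered by hand-written FCM minimising
J(U,V) = ΣᵢΣₖ uᵢₖᵐ d²ᵢₖ with Euclidean d and memberships summing to one per
sample. The alternating updates are the classical closed forms: centers as
uᵐ-weighted means, memberships as inverse relative squared distances raised
to 1/(m−1). Numerical choices:

- Fuzzifier m = 2 (the conventional default), configurable; m → 1⁺
  approaches hard k-means, which the tests verify at m = 1.05.
- Initialisation is a seeded random row-stochastic membership matrix; 5
  restarts keep the lowest final objective.
- Convergence when the largest membership change drops below 1e-6 (or at
  300 iterations, logged).
- A sample coinciding with a center receives membership 1 there; an
  exact tie among several centers splits evenly.
- The objective trajectory is recorded and is non-increasing up to 1e-9
  slack — the monotonicity of the alternating optimisation is a tested
  invariant, not an assumption.

Cluster count is chosen by the mean silhouette of the hardened (argmax, ties
to the lowest index) labels over c = 2..6; candidates whose hardened labels
leave an empty cluster score NaN and are skipped by the argmax, and
silhouette ties resolve to the smaller c. For c = 3 the clusters are mapped
to an ordinal good/moderate/poor label by center sleep time descending, ties
broken by center wake count ascending.

## Sleep-outcome prediction

Seeded random forests predict, from maternal indicators: the FCM quality
label, the binned nightly sleep time, the wake count, and the sleep-onset
mode. Categorical targets use classification forests evaluated by
accuracy/confusion (and macro AUC); the wake count uses a regression forest
evaluated by MAE/R², since it is an open count rather than a small fixed
code set. Sleep-time bins default to the training split's tertile edges —
the bin edges used in validation tables of this kind are rarely stated — and
explicit hour edges can be supplied. Unlabeled dyads are scored by column
name (order-independent), one prediction row per input.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular real family:

- **Continuous indicators** are truncated normals on the plausibility
  windows, rounded to instrument resolution (integer scores, 0.1-hour sleep
  times), and *moment-matched*: the underlying location/scale are solved
  numerically so the rounded, truncated law has exactly the configured
  mean/SD (defaults: maternal age 30.26/4.41, gestation 39.15/1.78, CBTS
  5.99/5.01, EPDS 9.12/6.77, HADS 7.88/4.28, infant age 1.94/0.82, sleep
  time 10.11/1.45, wake count 1.47/1.62). Without moment matching the
  lower-bounded scores would recover means biased by several standard
  errors.
- **Behavior class** arises by thresholding a latent propensity — a weighted
  sum of the standardized EPDS/HADS/CBTS/education columns plus unit
  Gaussian noise — at its sample quantiles, so class proportions match the
  configured vector (default 0.35/0.45/0.20) exactly up to rounding. The
  default coefficients (0.21/0.16/0.13/0.09) were calibrated by simulation
  to reproduce weak positive rank correlations, EPDS–behavior ≈ 0.145
  foremost.
- **Sleep indicators** are drawn conditionally on a latent three-class sleep
  quality (default proportions 105:216:57). Class-conditional means are
  mean-centred offsets scaled by `sleep_separation` (in marginal-SD units)
  with the within-class SD shrunk so the mixture keeps the configured
  marginal mean/SD; the feasibility bound for the default proportions is
  separation < 1.56. The default 1.5 was calibrated once so that FCM
  clustering of the normalized sleep block recovers the planted class
  proportions to within a few percent; at that separation the planted-class
  silhouette is ≈ 0.5. Sleep-onset mode is exponentially tilted by the
  quality class (strength 1.2), good sleepers leaning toward the
  low-intervention methods.
- `inject_outliers` mutates exactly k records to violate one plausibility
  rule each, returning the mutated ids — the fixture for the 410 → 379
  cleaning scenario.

What the generator does *not* emulate: within-class correlation structure
beyond the shared latent classes, skewness/kurtosis of the real scales
(moments beyond mean/SD are whatever the truncated normal implies),
education-age dependence, or any real family's joint distribution. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that it detects signal when signal is present at the configured strengths —
not that the study's substantive findings replicate.

## Problem sizes and determinism

Default analyses run at the study scale (410 generated, 379 after cleaning,
20 held out as the unlabeled batch); replicate-based tests use 10–20 seeded
replicates at n = 379–5000, chosen so the whole suite and the acceptance
script each complete in minutes on one CPU. Every stochastic component —
generation, splitting, forests, MLP, FCM restarts — takes an explicit seed,
one per pipeline stage, and the pipeline manifest records configuration,
config hash and seeds; two runs with the same configuration are
byte-identical across all artifacts.

## Known limitations

- The published headline numbers of this analysis family (specific
  accuracies, ρ values, silhouette 0.61, exact cluster counts) depend on a
  real cohort that is not machine-readably available; the package reproduces
  the *procedures* and verifies them on synthetic cohorts with known truth.
- The gate weights' published form rewards the worse model (see above);
  faithfulness is the default and the conventional form is a flag.
- FCM with m = 2 equalises cluster sizes; strongly unbalanced planted
  mixtures are recovered with a few percentage points of proportion bias
  even at the feasibility-edge separation.
- The silhouette-based choice of c is a heuristic; on weakly separated data
  the curve is flat and the argmax unstable across seeds.
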