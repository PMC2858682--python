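# Methods

## Feature annotation

Coordinates are 0-based half-open everywhere internally; BED-convention
input is the default and a `tab1` dialect converts 1-based inclusive
tables on read. An element "lies within" a CNV when it shares at least
one base pair (any-overlap); full containment is available as an option
but is not the default, because density features would otherwise
undercount elements straddling CNV breakpoints. Densities are elements
per base pair — any fixed rescaling (per kb, per Mb) is monotone and
therefore equivalent for a tree classifier.

Gene-derived means (d<sub>S</sub>, d<sub>N</sub>,
d<sub>N</sub>/d<sub>S</sub>, expression SD) run over the overlapped
genes that carry the attribute and are **missing, never zero**, when no
gene contributes: a gene-free CNV carries no information about
evolutionary rates, and encoding that as 0 would fabricate a strong
(low-rate) signal. The same conservative treatment extends to the MGI
and KEGG flags, which are ORs over overlapped genes — a CNV whose genes
simply lack knockout data looks the same as one whose genes have
negative knockout data, so flag-based evidence is weaker than a complete
knockout catalogue would allow. The expression feature per CNV is the
*mean* of per-gene log2-intensity standard deviations; median and
minimum are reasonable alternatives (the aggregation is a parameter of
`gene_attributes` consumers in spirit, and the mean was chosen as the
least surprising default). Records lacking a probe count pass the
probe-QC rule — the ≥5-probe filter describes array calls, and
literature-curated CNVs carry no probe metadata; only an explicit count
below 5 excludes.

VIF pruning iterates: compute VIF<sub>j</sub> = 1/(1 − R²<sub>j</sub>)
for every remaining continuous feature (OLS with intercept on the
others), drop the largest until all are at or below the threshold
(default 10, the conventional cutoff; 5 available for stricter
screens). Exact collinearity yields an effectively infinite VIF,
reported capped at 1e12; ties break by dropping the feature *later* in
column order, so earlier (better-established) features survive.

## The hybrid tree/Naive-Bayes classifier

`train_nbtree` grows a decision tree whose every leaf is a Laplace-
smoothed Naive-Bayes model:

1. At a node, the utility of stopping is the accuracy of the node's own
   Naive-Bayes model under seeded k-fold cross-validation
   (`utility_folds`, default 5).
2. Candidate univariate splits are evaluated: for a continuous feature,
   thresholds at the node-level MDL cut points of that feature; for a
   categorical feature, one child per category. A candidate is viable
   only if every child keeps at least `min_node` (default 30) training
   instances. Split utility is the instance-weighted mean of the
   children's cross-validated Naive-Bayes accuracies, computed on the
   node-level discretization so candidates are compared on an equal
   footing.
3. The node splits only when the best candidate's relative error
   reduction, (err<sub>node</sub> − err<sub>split</sub>) /
   err<sub>node</sub>, reaches `min_rel_improvement` (default 0.05);
   otherwise it becomes a leaf, which then fits its own discretization
   and probability tables on its final instance set.

These defaults (5-fold utility, 5% relative improvement, 30-instance
minimum) follow the classical published NBTree induction rule; all are
exposed as parameters. Continuous attributes inside leaves use
supervised MDL discretization (recursive binary entropy partitioning
with the minimum-description-length stopping criterion) rather than
Gaussian likelihoods — pure or uninformative attributes yield no cut
points and hence a single uninformative bin. Conditional probabilities
are (count + 1)/(class total + bins) with Laplace constant 1; class
priors are smoothed the same way so every probability is strictly
positive even for a class unseen in a leaf.

Prediction routes a CNV from the root to a leaf and reports the leaf's
posterior for the pathogenic class (the MR distance). Decisions:

* Ties at distance exactly 0.5 predict **benign** — the conservative
  call for the clinically weighty label; pathogenic requires strictly
  more than 0.5.
* An instance missing an internal split attribute is routed
  **fractionally**, weighting each child's posterior by its training
  mass; the posterior stays normalised. (During training, where each
  instance must land in exactly one leaf, missing-value instances
  follow the larger child.)
* Values equal to a threshold go left (`value <= θ`), matching the bin
  convention of the discretizer.

Fold assignment for split utility is the only randomness in training;
`seed` fixes it, and identical (data, parameters, seed) give bit-
identical models. Models serialize to versioned JSON (topology, cut
points, probability tables, parameters); loading validates the format
and version explicitly.

The 13-feature final set drops the SINE count, mean d<sub>N</sub> and
mean d<sub>N</sub>/d<sub>S</sub> from the 16 candidates — in the
original cohorts their leave-one-out contribution was nil; all 16 are
always computed so the selection is re-derivable via
`feature_contribution`.

## Evaluation

The pathogenic class is positive throughout; sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn),
FNR = 1 − sensitivity, FPR = 1 − specificity. A metric with an empty
denominator is reported missing, not 0. AUC uses the Mann-Whitney rank
formulation (ties count half), equivalent to trapezoidal ROC
integration. Note that a contingency table of 43/6/69/1085 gives
FPR = 69/1154 ≈ 0.060; reports that round this to 0.05 understate it
slightly — the computed value is always reported here. Human-readable
reports print percentages to the nearest point and predictive values to
two decimals, matching conventional clinical reporting granularity;
machine-readable output keeps full precision.

## Training-design experiments

**Imbalance sweep.** The benign training count walks from half the
benign pool down to parity with the fixed pathogenic training count (82,
half of the 164 available), 30 levels by default; each run trains on
the sampled sets and scores the held-out remainder. The headline metric
is **balanced accuracy**, the mean of sensitivity and specificity. This
is a deliberate choice: the remainder test set's class mix shifts with
the level (benign CNVs moved into training leave the test set), and
plain accuracy on a ~90-95% benign test set is maximized by whatever
training prior matches the test prior — i.e. by the *most imbalanced*
level, regardless of how well the classes are actually separated.
Balanced accuracy weighs both error types equally across levels and
reproduces the expected qualitative trend (balanced training is best).
Plain natural-frequency accuracy, sensitivity and specificity are
recorded per run alongside and can be promoted to the headline metric
via the `metric` argument. Runs whose test set lacks a class are
recorded as missing and excluded from level summaries.

**Optimal-set search and jackknife.** Both repeatedly draw balanced
training sets (82 or 164 per class) and score held-out or fixed
validation data, returning the best draw and the accuracy
distribution. The jackknife asserts pool/validation disjointness on the
row index — silent overlap would leak training data into validation.

**Enrichment.** For a query CNV set, 1,000 (configurable) random region
sets are generated, each matching the query lengths exactly, with the
chromosome chosen proportionally to its placeable positions and the
start uniform among them; no assembly gaps exist in synthetic genomes so
none are excluded. Each null set is annotated and classified through
exactly the same pipeline as the query; p is the plain proportion of
null sets with at least the observed pathogenic count (a +1/(n+1)
small-sample correction is available but off by default, so p = 0 is
possible when no null set reaches the observed count).

## Synthetic data generator

The generator emulates the class-conditional structure reported for
real MR cohorts; its defaults are the package's study conditions:

| parameter | pathogenic (mr) | benign | basis |
|---|---|---|---|
| length, log-normal median | 3.5 Mb (mean ≈ 6.8 Mb) | 205 kb (mean ≈ 474 kb) | cohort means |
| length sigma (log) | 1.15 | 1.3 | wide 10 kb–multi-Mb range |
| loss fraction | 0.7 | 0.5 | pathogenic CNVs mostly deletions |
| MGI-positive target | 0.80 | 0.05 | "80% vs rarely" |
| placement multipliers | SINE 2.5, gene 2.0, LINE 0.7, segdup 0.4 | LINE 2.5, segdup 4.0, SINE 0.8, gene 0.6 | class-specific repeat enrichment |

Genomes default to three chromosomes (50/40/30 Mb) with element
densities calibrated to genome-wide human frequencies (one LINE per
~4 kb, one SINE per ~2.5 kb, ~6.5 genes per Mb, sparse segmental
duplications). Elements arrive by a homogeneous Poisson process whose
density is multiplied inside randomly placed hotspot blocks; CNV
placement is rejection-sampled with the class multipliers applied to
hotspot coverage, so the realized density contrasts are graded, not
deterministic. MGI/KEGG-flagged genes are confined to "neuro region"
blocks (25% of the genome) so that both flag-positive and flag-negative
placements exist for CNVs of any size; each CNV is constrained to
contain or avoid such a gene so the realized MGI-positive fraction
tracks the class target. Probe counts emulate a dense array (~1 target
per 2 kb). Everything derives from one integer seed.

What the generator does **not** emulate: sequence content, real
chromosome-specific repeat maps, probe-intensity noise, platform
differences between cohorts, population frequency structure, and
correlated gene attributes (d<sub>N</sub>, d<sub>S</sub>, expression SD
are drawn independently of class and position). Passing tests therefore
demonstrate that the pipeline recovers planted class structure of
realistic magnitude — not that the classifier would achieve the same
numbers on clinical data.

## Problem sizes

The shipped experiments run at the cohort scale the training data
dictates where that is cheap (164 pathogenic CNVs, 1,413 benign CNVs,
30 sweep levels) and scaled-down Monte-Carlo sizes where it is not
(50 sweep runs per level, 200 search iterations, 200 permutation
sets); all sizes are parameters, and the full published protocol
(1,000 runs, 10,000 iterations, 1,000 sets) is reachable by passing the
corresponding arguments.

## Known limitations

* The induction rule evaluates split candidates only at node-level MDL
  cut points, not at every observed value — a deliberate restriction
  that keeps utility estimation cheap and candidates well-supported.
* Split-utility cross-validation bins children with the parent node's
  discretization; final leaves refit their own. The alternative
  (refitting discretizations per candidate per fold) changes results
  only marginally but costs an order of magnitude more.
* Balanced accuracy as the sweep's headline metric is a reporting
  choice, argued above; consumers wanting the raw natural-frequency
  accuracy have it per run.
* The enrichment null places regions uniformly; real genomes would need
  gap/assembly masking, which synthetic genomes make unnecessary.
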