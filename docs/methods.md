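# Methods

## Scope and data model

The package models plant responses to nanoparticle exposure as 13
independent regression problems, one per response label (3 growth, 6
oxidative-stress/photosynthesis, 4 uptake/transport). Every record is an
independent literature-style observation on a fixed 20-feature schema
(`nanophyto.schema.FEATURES`); records reporting different labels form
different model subsets, selected by dropping rows that miss the label or
any model input (the dropped count is recorded on the model object). No
study-level clustering or publication-bias structure is modelled: records
are treated as exchangeable, which is the central statistical assumption
of the pooled nano-QSAR design.

## Encoding

* **Label transform.** Control-relative labels map to
  y′ = (y − c)/y for y > c and (y − c)/c for y < c. The y = c case is not
  defined by the piecewise formula; both branch limits are 0 there, so
  y′(c, c) = 0. The transform is sign-preserving, monotone in y, and maps
  [0, ∞) into [−1, 1). Ratio labels (RS ratio, TF, RCF, SCF) are already
  unitless and bypass the transform.
* **Type registry.** 17 nanoparticle types with class flags and IUPAC
  atomic weights to two decimals. For materials beyond the two-component
  convention, polystyrene (the nanoplastic representative) is coded as a
  macromolecular compound with backbone components C (12.01) and H (1.01);
  carbon nanomaterials (graphene, MWCNT) carry component C with no class
  flag. The registry ships as code and round-trips through an editable CSV.
* **Shape registry.** Shape names map to exactly one dimensionality class
  (granular / 1-D / 2-D); hollowness comes from the record except for
  nanotubes, which are intrinsically hollow.
* **z-scoring** applies to the 12 quantitative raw features plus
  com1/com2. Binary flags are left unscaled: scaling them destroys
  interpretability without serving the purpose of removing units.
  Scoring-time matrices (CV test folds, raster grids) always reuse the
  fitting-set mean/SD, and unseen categorical levels raise rather than
  silently producing zero rows.
* **Column order** is deterministic: canonical raw-feature order, code
  columns in fixed order, one-hot levels lexicographic. This makes
  matrices reproducible across runs and platforms.

## Forest fitting

Forests are bootstrap ensembles of variance-reduction regression trees
(scikit-learn backend), defaults *ntree* = 500, *mtry* = 20 (capped at the
encoded column count — the design encodes 20 raw features into ~47
columns, so the cap matters only for reduced matrices), `min_leaf` = 1,
unlimited depth. An optional `max_depth` exists because depth-limited
forests make co-occurrence interaction analysis sharper (unlimited trees
eventually split on nearly every column, saturating presence counts); the
default leaves depth unlimited.

Immediately after fitting, the forest is frozen into a plain-array
structure (per node: split column, threshold, children, depth, impurity,
weighted sample count; per tree: in-bag multiplicities and the implied
out-of-bag row set). All predictions and every interpretability analytic
run on this structure, and it serialises to JSON so persisted models can
be interrogated without the fitting library. Per-tree in-bag/OOB sets
partition the rows exactly; the expected OOB share is (1 − 1/n)ⁿ → 1/e.

Cross-validation uses 10 random 90/10 shuffle splits. When given raw
records it refits the encoding inside each training fold, so no z-score
statistic leaks from test rows. All four learners (forest; gradient-boosted
trees with 100 trees; RBF support-vector regression with C = 1; a
neural network with one hidden layer of width 2(n − 1) for n features,
adam optimiser) are evaluated on identical fold splits — resampling folds
per learner would confound learner differences with split luck. The
neural network is scikit-learn's multilayer perceptron; a non-finite
training outcome triggers one reseeded retry. Grid search over
(ntree, mtry) maximises mean CV R², breaking ties toward the smaller,
cheaper model.

## Validation battery

* **y-scrambling.** For each replacement ratio (20–100 %), repetition and
  fold, the stated fraction of training-fold labels is replaced by uniform
  draws from [min(y), max(y)], the forest refit, and Q² computed on the
  untouched held-out fold. The full protocol is 5 × 10 × 10 = 500 refits.
  The published criterion regresses the Q² values "against the original
  labels", which is not executable verbatim; the implemented regressor is
  the Pearson correlation between permuted and original training-label
  vectors — the standard y-scrambling abscissa — with all raw (correlation,
  Q²) pairs retained so alternative regressions can be recomputed. Verdict:
  not-overfit iff the Y-intercept < 0.05.
* **Feature shuffling** permutes one column (or all columns) across rows
  and reports the change in mean CV R²; an identity permutation is an
  exact no-op, which the tests use as a control.
* **Backward selection** greedily removes the feature whose absence
  maximises mean CV R², never below ⌈p/2⌉ features. If no subset beats
  the full set by more than 0.005 R² (configurable), the full set is kept,
  so weakly informative nanoparticle properties are not discarded on
  noise. Removal ties keep the earlier-ordered feature.

## Interpretation from tree structure

* **MSE increase**: per tree, OOB MSE after permuting one column minus
  baseline OOB MSE, averaged over trees and normalised by the SD of the
  per-tree differences. Constant columns are reported as 0 with a flag.
* **Node purity increase**: summed weighted impurity decrease of all
  splits on the column. Summing over columns reproduces the forest's
  total impurity reduction exactly (a conservation check in the suite).
* **Mean minimal depth**: per tree, the depth of the shallowest split on
  the column; trees that never use it contribute max-depth + 1 (the
  conservative convention; a `skip` alternative averages only over trees
  using the feature). 
* **P value**: one-sided binomial test of the column's total split count
  against uniform selection among p columns. This null ignores
  feature-availability effects of *mtry* and is documented as an
  approximation.
* **Interaction network**: a pair's strength is the number of trees in
  which both columns appear as split variables — presence per tree, not
  path multiplicity. The top 50 edges are kept; ties at the cut break
  lexicographically.
* **Proximity**: fraction of trees in which two rows share a leaf.
  Edges connect pairs above `threshold_multiple` (default 3) times the
  mean off-diagonal proximity; the multiple is exposed rather than
  hard-coded because published practice varies with network size.
  Cluster density is the realised within-class edge fraction.
* **Partial dependence** grids use `min + step·arange(steps)` with
  step = (max − min)/steps, so "0 to 50 mg in 100 steps of 0.5 mg" yields
  exactly 100 points (0, 0.5, …, 49.5); an endpoint-inclusive grid would
  contradict the stated step width. Grid bounds are taken in raw units
  and converted through the stored z-score statistics. The background is
  the training set, subsampled to 500 rows (seeded) for large matrices.
* **Shapley drivers**: coalition values are mean predictions over a
  background sample with coalition columns set to the record's values.
  Up to 6 candidates, all 2^k coalitions are enumerated (exact values);
  above that, permutation sampling. Either way baseline + Σφ equals the
  full-coalition value (exactly for both modes, by telescoping), and the
  main driver is the largest |φ|. The intended use is the four
  environmental layers, so the exact path is the default in practice.

## Projection

Raster stacks hold co-registered layers (row 0 = north, origin at the
upper-left corner, cell size in arcminutes — a parameter, not a constant)
with a joint validity mask; a cell missing in any layer is excluded
everywhere. Soil pH classifies as acid (< 6.5), neutral ([6.5, 7.5]),
alkaline (> 7.5). Each valid crop cell becomes one record: temperatures,
illumination and humidity from the layers, culture from the soil class,
and a fixed exposure scenario for the rest — dose 50 mg and duration 21 d
(seedling stage), root exposure, measured tissue root for growth/uptake
and leaf for oxidative stress, representative mid-range nanoparticle
physical properties (size\_TEM 30 nm, size\_DLS 150 nm, zeta −20 mV,
purity 99 %), all overridable per call.

The composite oxidative-stress index is |mean(APX, H₂O₂, MDA, SOD)| of
the transformed responses — the absolute value of the average variation;
the alternative reading (mean of absolute values) is available behind
`composite_mode`. After normalising by the maximum, cells are sorted and
split into 20 equal-count levels (vigintiles), ties broken by stable cell
order; equal-width binning is available behind a flag. Level 20 is the
highest stress; area percentages per level sum to 100 over valid cells,
and the share at levels 16–20 is the headline "high risk" number.

Temperature scenarios add per-cell or scalar offsets to the two
temperature layers only. Uncertainty maps refit the forest `runs` times
(default 200; desk-scale analyses and tests use 5–20) with consecutive
seeds and report per-cell mean, SD and SD/mean, flagging cells with
|mean| < 1e−9 as undefined rather than dividing.

## Synthetic data: what it does and does not emulate

The experiment-table generator reproduces the schema, documented value
ranges (e.g. size\_TEM up to 2 000 nm, dose up to 3 000 mg), the
control = 100 % label convention, and a *known* signal: each requested
label is 100 + Σ effect·carrier + Σ interaction·carrier·carrier +
N(0, noise_sd), clipped at 0. Carriers are raw feature values or, by
default, population-standardized ones (uniform-range moments), making
effect sizes comparable across features; `standardize=False` gives
raw-unit effects. Categorical features use sorted level indices as
carriers. Feature marginals are uniform over ranges/levels because no
empirical marginals are published; recovery experiments default to a
dominant effect of 40, a secondary effect of 20 and an interaction of 15
label-percent units against noise SD 5 — a signal-to-noise regime ≥ 2 in
which driver recovery is a fair demand.

What passing tests therefore show: the pipeline recovers planted drivers,
interactions and spatial response patterns under exchangeable, uniformly
distributed, additive-plus-interaction data. What they do not show:
performance under the real table's correlated features, skewed marginals,
study-level clustering and label-dependent missingness — headline
real-data accuracies require the curated table and are out of scope here.

The raster generator produces Gaussian-smoothed (σ = 3 cells) uniform
fields inside per-profile climate bounds (tropical / temperate / boreal
profiles with disjoint temperature ranges), ~5 % jointly missing cells, a
contiguous crop mask and a planting-month layer. It aims at plausibility
and schema fidelity, not climate realism.

## Problem sizes

Library defaults follow the published protocol (ntree 500, mtry 20, 10
folds, 5 × 10 × 10 scrambling, 200 uncertainty runs, PD backgrounds up to
500 rows). The shipped analyses and tests run the same protocols at desk
scale as the package's own configuration choices: tables of 150–400
records, forests of 10–100 trees, rasters up to ~20 × 30 cells, 5–20
uncertainty runs; the scrambling acceptance run keeps the full 500-fit
protocol at n = 300, ntree = 100.

## Known limitations

* The binomial split-count null is approximate (see above); P values are
  comparative, not calibrated significance statements.
* Forest extrapolation beyond the training feature ranges flattens to
  edge leaf values; projections into climates unlike the training data
  inherit this.
* The neural-network comparator's learning-rate-decay setting of the
  original Keras configuration has no direct equivalent in the
  scikit-learn optimiser and is not emulated.
* Proximity matrices are dense (n × n); the similarity network is
  intended for data-set-sized n (≲ a few thousand), not raster-scale
  collections.
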