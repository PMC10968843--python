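# Methods

## Interval model of ensemble evidence

The ensemble treats per-class evidence epistemically: a group of
classifiers does not produce one membership degree for class *c* but a
range of plausible degrees, represented as the closed interval from the
smallest to the largest soft label among the group's members. The
interval lattice is `L^I`, the subintervals of [0, 1] under the
componentwise partial order ⪯ (join/meet = componentwise max/min).
Because overlapping intervals are ⪯-incomparable, decisions use one of
three admissible linear orders:

* **Xu–Yager (default)** — compare `lower + upper`; on ties, the narrower
  interval precedes. It uses both bounds (equivalently: midpoint first,
  width second), which is why it is the default decision order.
* **Lex1 / Lex2** — lower bound first / upper bound first. Implemented
  for completeness; the experiments and defaults use Xu–Yager.

### Exact order keys

Order comparisons are tolerance-free: a tolerance would destroy
antisymmetry. A subtlety is that binary floating point misrepresents
decimal bounds — `0.2 + 0.4 > 0.1 + 0.5` in doubles although the decimal
sums are equal — which would misorder intervals whose bounds are written
as decimals, precisely the inputs users type and the literature prints.
The scalar comparison therefore evaluates its keys in exact rational
arithmetic over the shortest-decimal reading of each bound
(`Fraction(Decimal(repr(v)))`). This map is injective and monotone on
floats, so totality, antisymmetry and transitivity are preserved exactly.
The vectorised decision path inside the ensemble compares float keys
directly: soft labels are generic floats for which exact sum ties other
than bit-identical bounds do not arise in practice, and bit-identical
bounds are ordered the same way by both paths.

## The ten aggregations

`A1`–`A10` combine one interval per group into one interval per class.
Lower bounds use arithmetic, quadratic or cubic power means or the
geometric mean; upper bounds use arithmetic, quadratic/cubic/quartic
power means or Lehmer-type ratios `Σx^p / Σx^(p-1)` (p = 2, 3). `A2` and
`A7` mix one bound across sides: one bound-swap per position, take the
max (A2, upper) or min (A7, lower) over positions. The closed forms
`(ΣU − min(U−L))/n` and `(ΣL + min(U−L))/n` replace the explicit
enumeration in the vectorised path; the test oracle enumerates naively.

Numerical conventions:

* **0/0 := 0** in the Lehmer ratios (A3, A4, A8, A9), reachable only when
  every relevant upper bound is exactly 0. No epsilon smoothing.
* Arity n = 1 is allowed (all formulas degenerate to near-identity);
  group pruning can in principle reduce the number of groups, and the
  aggregation's arity is always the number of surviving groups.
* Results are clamped to [0, 1] only against round-off at the 1e−9 scale;
  a larger excursion raises an internal error rather than being hidden.
* Componentwise ⪯-monotonicity holds and is tested for the mean-type
  families (A1, A2, A5, A6, A7, A10). The Lehmer-ratio uppers are not
  componentwise monotone (they are monotone with respect to other
  interval orders), so A3, A4, A8, A9 are exempt from that property test;
  all ten satisfy the boundary conditions and hull containment.

## Soft labels

Members emitting calibrated probabilities (forests, MLPs, neighbour vote
fractions) pass through unchanged. If any value of a member's score
matrix leaves [0, 1] — SVM decision margins, for instance — the whole
matrix is softmax-normalised row-wise; mixing calibrated and softmaxed
rows within one member would be incoherent, so the check is per matrix.
One-dimensional binary margins are expanded to two signed columns before
the range check. Columns always follow the ensemble's fixed class order
(sorted unique training labels).

## Entropy selection

Both entropy variants score every member with mean cross-entropy loss
over repeated stratified two-fold cross-validation (default 10 repeats ×
2 folds = 20 validation folds) run **inside the training partition**.
Probabilities are clipped to [1e−15, 1 − 1e−15]: 1-NN members emit exact
0/1 labels and unclipped log loss would be infinite, leaving selection
undefined. Rules:

* **Members:** keep the two lowest-loss members of each group, plus every
  member at or below the group's average member loss. Ties keep the
  lower index.
* **Groups** (`pom_egrp` only): group means are computed over *all
  original* members — the group mean is established before member pruning
  and reused for group selection. Keep groups at or below the average of
  group means; if fewer than two qualify, keep exactly the best two.

Both rules are invariant to adding a constant to all losses and always
retain at least two members per surviving group and at least two groups.
Survivors are refitted on the full training partition: nested CV exists
to rank components, and discarding the held-out half of the training data
for the final fit would waste signal.

The CV stream is seeded by the ensemble's `random_state`
(`RepeatedStratifiedKFold`), so each repeat draws an independent,
reproducible split.

## Evaluation harness

Repeated stratified 80/20 train–test splits (default 5 repeats), min–max
scaling fitted on the training partition only. Scaled test features may
leave [0, 1] and are not clipped — clipping would distort L1 distances
for the nearest-neighbour members. Metrics: accuracy (correct/N; the
decision rule is the interval argmax, so no separate probability
threshold is involved), balanced accuracy (mean per-class recall) and
macro One-vs-One ROC AUC computed from the membership degrees, the only
probability-like output the ensemble defines. Results report mean ± SD
over repeats sorted by descending AUC; raw per-repeat scores are exported
for downstream significance testing, which is deliberately out of scope
here.

## Synthetic data generator

Emulates the three traits of bulk expression matrices that matter for
exercising the method: high dimensionality relative to sample count,
co-regulated (block-correlated) genes, and noise. Features are unit-
variance Gaussians sharing a per-block latent factor (`block_rho` is the
exact within-block correlation, default 0.5 over blocks of 20), class
labels follow a target proportion vector exactly via largest-remainder
rounding, and each class shifts its own disjoint subset of informative
features by `effect_size` noise-SDs (default 1), so every class is
separable in principle. Defaults are desk scale — 200 samples × 2000
features, four classes at (0.45, 0.28, 0.14, 0.13), an imbalance profile
typical of clinical cohorts; tens of thousands of features are available
by configuration.

What the generator does **not** emulate: heavy-tailed and probe-level
measurement artifacts, batch effects, correlated informative blocks that
straddle class boundaries, and label noise. Passing tests demonstrate
that the machinery behaves as specified on data with these idealised
properties, not that the method attains any particular performance on
real cohorts.

## Study and test problem sizes

The corrupted-group robustness study runs 50 independently seeded rounds
at the generator's default scale (200 × 2000, effect size 1). Its groups
are three lightweight informative families — forests with {10, 50}
trees, Manhattan k-NN with k ∈ {1, 3, 5}, linear/RBF SVMs — plus one
group of label-shuffled k-NN members as a no-signal control; lightweight
members keep 50 rounds of nested 10×2 cross-validation practical on a
single CPU while preserving the heterogeneous-group structure the
selection rules act on. Unit and property tests use smaller matrices
(tens to hundreds of features) chosen so each test isolates one
mechanism; the full default zoo (12 members including the three MLPs) is
exercised where the zoo itself is under test.

## Known limitations

* The MLP members cap training at 1000 epochs with seeded
  initialisation; convergence warnings are informational, not fatal.
  Exact reproducibility is prioritised over squeezing out convergence.
* The polynomial SVM kernel uses degree 3, the conventional default.
* `select_models` can keep a high-loss member when a group has only two;
  the two-member floor is structural, not quality-based.
* Interval orders beyond Xu–Yager/Lex1/Lex2, alternative entropies
  (Tsallis, Rényi), loss-weighted (rather than keep/drop) ensembles and
  One-vs-One/One-vs-Rest decomposition wrappers are out of scope.
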