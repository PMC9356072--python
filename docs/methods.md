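# Methods

## Model

`sauronrf` predicts a continuous drug response y (logarithmized IC50) and a
binary sensitive/resistant call Y jointly, from gene expression X
(samples × genes). The binary labels derive from a drug-specific threshold
t: Y = 1 iff y < t; values exactly at t are resistant. That tie rule is a
deliberate conservative choice — "sensitive" means strictly below threshold
— and it is reused everywhere a prediction is thresholded, and for forest
vote ties.

### Weighted tree growth

Each of B trees is grown on an N-sized bootstrap drawn with replacement.
At a node v with bootstrap members δ(v) and initial sample weights w*, the
node's prediction is the weighted mean of its members' responses (weights
w*_i / Σ_{δ(v)} w*), its impurity the correspondingly weighted MSE, and the
split criterion is the weighted-MSE improvement with ancestor/child node
weights equal to each node's share of importance mass. Because the ancestor
term is constant within a node, the chosen split equivalently minimizes the
summed weighted SSE of the two children. This is exactly the
impurity-decrease criterion of sklearn's `DecisionTreeRegressor` under
`sample_weight = w*`, so tree construction is delegated to it; the
equivalence is enforced by a brute-force oracle test that enumerates every
(feature, midpoint) candidate on small fixtures and checks each fitted
split under all four weight schemes. Candidate thresholds are midpoints of
consecutive distinct feature values; growth stops at `min_samples_leaf`
(counting bootstrap multiplicity) or node purity.

Split ties are resolved by the backend's randomized feature visiting order
rather than a fixed lexicographic rule; all randomness (bootstraps,
feature draws, tie resolution) derives reproducibly from the single forest
seed, so fitted models are deterministic given a seed.

### Leaf annotation and aggregation

Each leaf stores its members' weighted mean response, per-class importance
mass, raw counts, and a class label: the class with the larger importance
mass, ties resistant. Labelling by mass rather than raw counts keeps the
two countermeasure families consistent — upsampled duplicate rows
necessarily count with their multiplicity in a leaf majority, and integer
sample weights must behave identically. Under uniform weights the rule
reduces to the raw-count mode, so the unweighted baselines are unaffected.
Empirically this choice is also what lets the weighted model translate its
training-time emphasis into classification gains (see the benchmark
below).

The forest classifies by majority vote over tree leaf classes (ties →
resistant; the mode always agrees with at least one tree, so the binary
weight denominator cannot vanish). The regression output is the
tree-weighted average of reached-leaf means under five schemes: uniform
(1/B), binary (equal weight on trees agreeing with the forest vote),
binary sensitive (binary only for sensitive-predicted queries), majority
(each tree weighted by the weighted fraction of its reached leaf's members
whose class matches the *forest's* vote, normalized across trees), and
majority sensitive. The agreement indicator in the majority fraction is
defined against the forest's vote, not the tree's own leaf class.

### Imbalance countermeasures

Initial weights: uniform (baseline); simple (N_res/N_sens for sensitive
lines, giving equal per-class mass); linear/quadratic threshold-distance
weights (per-class sums exactly 0.5). Resampling alternatives: plain
upsampling (sensitive rows drawn with replacement until balanced, seeded)
and proportional upsampling (per-line copy targets = doubled linear weight
× N_res, rounded half-to-even with a largest-remainder repair so the
sensitive class lands on exactly N_res rows — the procedure itself is
deterministic). Duplicated rows get `#k`-suffixed IDs to keep sample IDs
unique. Weights and resampling are mutually exclusive in a model spec, and
are always computed from training data only.

### Feature selection

Greedy mRMR: each variable is quantile-discretized independently into
`n_bins` equal-frequency bins (default 10 — scale-free, appropriate for
expression units that differ across platforms) and plug-in mutual
information is computed in nats. The first pick maximizes MI(f, y); later
picks maximize MI(f, y) minus the mean MI with already-selected features
(difference form; a quotient form is available). Argmax ties break on the
lexicographically smallest gene ID. The plug-in estimator has a positive
bias of roughly (n_bins−1)²/(2N) nats that is shared across features, so
rankings are far less biased than the raw values; MI values should be read
comparatively.

### Baselines and evaluation

rRF is the same forest with uniform weights and uniform tree weighting,
classified by thresholding its prediction at t. HARF is the binary
tree-weighting scheme with class-annotated leaves. cRF is a Gini
classification forest whose leaves additionally store the unweighted mean
response; its derived continuous prediction averages the leaf means of the
trees agreeing with the forest vote. The hierarchical baseline routes each
query through a classification forest to one of two class-specific
regression forests.

Metrics: sensitivity, specificity, MCC (zero-denominator convention: 0),
and MSE / median squared error overall and per true class — per-class
errors are the point, since overall MSE hides minority-class failure.
Empty classes report NaN rather than 0. The experiment protocol draws a
seeded, unstratified 80/20 train/test split, runs 5-fold CV on the
training part over a hyperparameter grid (number of mRMR genes by default),
refits feature selection inside every fold, selects by mean validation MCC
for classifying models and mean validation MSE for pure regression, refits
on the full training set, and reports test metrics. Grid points that lose
a required class in a fold are skipped with a warning.

## Synthetic data

The generator emulates a single-drug GDSC-scale problem: latent class
z ~ Bernoulli(frac_sensitive = 0.09, the typical 1:10 minority), 300 genes
of which 20 are informative (shifted down by `class_shift` = 1 SD in
sensitive lines), and a response equal to a ±effect_size/2 class mode
(default separation 3.0) plus a class-centered linear combination of the
informative genes (unit variance) plus N(0, noise_sd = 1). The threshold
is the mode midpoint, so labels recover the latent class up to the
within-mode spread. With the default spread (sd ≈ √2 per mode vs
separation 3.0), ~14% of latent-resistant lines fall below t, so the
realized label imbalance is ≈1:4 while the latent mixture is 1:10; this
overlap is intentional — a cleanly separable response would make the
imbalance problem trivial. Not emulated: gene–gene correlation beyond the
shared class factor, batch effects, multimodal expression, or real GDSC
marginals. Passing tests therefore demonstrate the mechanics of the
imbalance countermeasures, not absolute performance on real screens.

The tiny hand-specified fixture (10 samples × 3 genes, both classes
present, generic tie-free values) anchors the brute-force oracle tests.

## Benchmark sizes and numerical choices

The repeated benchmark (`sauronrf.benchmarks.imbalance_benchmark`) runs 20
seeds at generator defaults with B = 100 trees, m = ⌊P/3⌋,
`min_samples_leaf` = 5, an 80/20 split per seed — sized for a
single-CPU run of a couple of minutes while keeping vote statistics
stable. The mRMR recovery study uses a strong-signal configuration (400
samples, 100 genes, 5 informative, effect 4.0, noise 0.5, class shift
1.5): per-gene signal must clear the plug-in MI bias floor at that sample
size for recovery to be the expected outcome rather than a coin flip.

Defaults: B = 500, m = ⌊P/3⌋ (regression-forest convention),
`min_samples_leaf` = 5. Tolerances: weight-vector normalizations are
checked at 1e-12; scheme-reduction identities hold bitwise where the
weight arrays coincide and to 1e-12 against the plain mean (summation
order differs in the last ulp). Serialized forests (documented JSON node
arrays plus leaf annotations) replay predictions bit-identically because
prediction runs on the package's own arrays, not the backend's.

## Known limitations

Two classes only (the leaf annotation generalizes to K classes but the
vote, tie rules and sensitive-specific schemes are binary here). The
threshold t is an input: estimating it from the IC50 mixture distribution
is out of scope. Split tie-breaking follows the backend's seeded order
rather than a value-based rule, so exact tree equality across sklearn
versions is not guaranteed (within an environment, runs are fully
reproducible). The mutual-information estimator is the binned plug-in;
kNN estimators are out of scope.
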