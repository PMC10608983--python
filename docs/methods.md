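# Methods

This note documents the models and procedures implemented in
`nmrforest`, their assumptions, the defaults that matter, and the design
choices made where more than one construction was defensible.

## Forest engine

`SurrogateForest` grows a classification forest of binary CART-style
trees:

* **Bootstrap.** Each tree draws `n` samples with replacement with
  probability proportional to the case weights. The default weights are
  `1/(K · n_c)` for a sample of class `c` (`K` classes), so every class
  contributes equally to the bootstrap in expectation regardless of
  class imbalance. Weights act on sampling only; Gini computations
  inside a node are unweighted over the in-bag multiset.
* **Splitting.** At each impure node with ≥ 2 in-bag samples, `mtry`
  candidate variables are drawn uniformly without replacement
  (default `ceil(p^(3/4))` — larger than the classification default
  `sqrt(p)`, favouring stable surrogate structure). Candidate
  thresholds are midpoints between consecutive distinct values; the
  split maximising the Gini gain wins. Growth continues to purity
  (`min_node_size = 1`).
* **Surrogates.** At every internal node the `s` best surrogate splits
  (default `round(0.05 p)`, minimum 1) are found by scanning *all*
  other variables over the node samples. A surrogate's raw agreement is
  the number of node samples its split sends to the same side as the
  primary, taking the better of the two side mappings; the *adjusted
  agreement* rescales it so the majority rule scores 0 and perfect
  mimicry 1. Only strictly positive adjusted agreements are stored,
  sorted descending.
* **Exact ordering and tie-breaks.** All scores that decide a split are
  ratios of small integers; represented as doubles these order exactly,
  so argmax tie-breaking is well defined: equal split scores resolve to
  the smaller threshold, then the smaller variable index; equal
  surrogate agreements to the smaller threshold and the un-flipped
  direction; equal adjusted agreements to the smaller variable index.
  The test suite verifies bit-for-bit equality with an exhaustive
  exact-rational enumeration on hundreds of random nodes.
* **Determinism.** Tree `t` draws from a generator seeded with
  `(seed, t)`; results are independent of build order. Identical seeds
  reproduce forests, selections and pipeline outputs byte for byte.

Out-of-bag (OOB) evaluation predicts each sample by majority vote over
the trees in which it is out-of-bag (leaf majority per tree, ties to
the first class alphabetically). Samples never OOB — possible at very
small `ntree` — are excluded with a warning rather than imputed.

### Impurity importance

`raw` importance is the node-size-weighted Gini decrease summed per
variable and divided by `ntree`. `corrected` importance removes the
bias of raw Gini importance by augmenting the data with an
independently permuted copy of every variable, refitting (without
surrogates) with `mtry` recomputed for the doubled width, and
subtracting the importance earned by each variable's permuted twin.
An OOB `permutation` importance is also provided.

**Interleaving.** In every augmented design (corrected importance, SMD
shadow fit, Boruta runs) the permuted columns are placed at
seeded-random positions among the real columns. This matters: exact
score ties are common in small deep nodes, the deterministic
tie-breaks prefer smaller column indices, and a block of shadows
appended at the end would systematically lose those ties and understate
the null.

## Surrogate minimal depth (SMD)

Per tree, a variable's depth is the minimum depth of any node where it
is the primary splitter *or* appears in the surrogate list; a variable
absent from a tree is assigned that tree's maximum internal depth + 1
(a concrete convention; the score of a variable can therefore never
exceed the absent-variable default). SMD is the mean over trees. With
`s = 0` it reduces exactly to classical minimal depth (tested).

**Selection threshold.** `n_shadow` permuted copies of randomly chosen
real variables (default `min(p, 200)`) are appended and the forest is
refitted with identical parameters and seed discipline. The threshold
is the lower-interpolation 1% quantile of the shadow SMD scores — an
actual shadow order statistic — and a variable is selected when its SMD
is strictly below it. Both the real and the shadow scores entering this
comparison are taken from the *same* augmented fit: variables in a
wider forest appear systematically later than in the original fit, so a
cross-fit comparison would be biased lenient; within one fit, real and
shadow variables are exchangeable under the null. On class-independent
noise the observed false-selection fraction is 0–6% across seeds with
mean near the nominal 1–2%; because the threshold is an order statistic
of an exchangeable null, the false-selection rate is *centred on* the
nominal quantile, not bounded above by it. A `fixed` threshold mode
bypasses the shadow machinery for exact replication against external
tools.

## Boruta

In every run a freshly permuted shadow copy of each undecided variable
is appended (permutations keyed by `(seed, run, label)`), a forest is
fitted without surrogates, and a variable scores a hit when its
corrected importance exceeds the maximum shadow importance. Hits are
tested against Bin(runs, ½) with two one-sided binomial tests at
confidence/2 each (default confidence 0.01; optional Bonferroni across
variables); confirmed variables stay in the design, rejected ones are
dropped with their shadows, and whatever is undecided at `max_runs`
remains tentative. At confidence 0.01 the earliest possible decision is
after 8 unanimous runs.

## Mean adjusted agreement relations

The relation of variable `j` to `i` is computed over all nodes where
`i` is the primary splitter: `j`'s stored adjusted agreement (0 when
`j` is not among the node's `s` surrogates), averaged within each tree
and then across the trees in which `i` splits at all; rows of variables
that never split are 0. Averaging over splitting trees (rather than all
`ntree`) is deliberate: with redundant variables competing for the
primary role, averaging zeros from trees where `i` lost the draw would
cap same-signal relations far below their true substitutability. Values
are clamped to [0, 1], the diagonal is 1, and both the directed matrix
and its symmetrisation (element-wise mean with the transpose, the
default for clustering and heatmaps) are provided.

Downstream:

* **Clustering**: Ward linkage on Euclidean distances between rows of
  the symmetrised matrix, cut at `k` clusters (default 4) or at a
  height. The cut is a reporting choice, recorded in the output.
* **Same-signal reduction**: groups of buckets carrying one multiplet
  (from annotations, or — without annotations — connected components of
  buckets within 0.02 ppm relating at ≥ 0.7; 0.02 ppm = two buckets is
  the maximal multiplet extent for J ≤ 18 Hz at 400 MHz) are reduced to
  the member with the lowest SMD, ties to the first label.
* **Superimposed buckets**: a bucket assigned to several metabolites is
  `supported` for a metabolite when its maximal relation to that
  metabolite's other buckets is ≥ 0.3, `unsupported` at ≤ 0.1, else
  `ambiguous`. The two cut-offs operationalise the qualitative
  "high" vs "around zero" distinction and were fixed a priori.
* **Correlation comparator**: plain Pearson correlation of bucket
  intensities is computed alongside, since that is the classical way of
  grouping NMR variables; the relation parameter differs from it in
  reflecting shared *classification* information rather than shared
  intensity variance.

## Synthetic data generator

The generator emulates the structure of aligned, baseline-corrected,
0.01 ppm-bucketed ¹H NMR spectra at 400 MHz:

* **Lines.** First-order multiplets with binomial intensity ratios,
  coupling constants 0–18 Hz, Lorentzian lines of 0.7–3 Hz FWHM. Each
  line is truncated at ±2.5 FWHM and renormalised — baseline correction
  removes the broad Lorentzian feet in real preprocessing, and without
  truncation the 1/x tails would smear visible intensity several
  buckets beyond the multiplet, which bucketed real spectra do not
  show. Bucket integrals use the arctangent antiderivative, so mass
  conservation and boundary cases are exact (a line on a bucket
  boundary splits exactly 50/50).
* **Concentrations.** Log-normal per class (natural-log means and sds
  per metabolite); correlated metabolite pairs share a standard-normal
  latent factor at the stated ρ. Additive Gaussian noise (sd 0.05 by
  default, against signal bucket values of order 1–10) truncated at 0.
* **Ground truth.** Every bucket's received fraction of every signal is
  recorded. A bucket is *informative* when it receives ≥ 5% of some
  signal's integral and *pure noise* when no signal deposits ≥ 0.1%;
  the faint shoulders in between are judged neither way.
* **Packaged scenario** (`truffle_like_scenario`): 80 samples in five
  classes of 28/7/12/21/12, 285 buckets over 1.50–4.35 ppm, ten
  metabolites with five-class log-concentration profiles (one dominant
  species contrast each, gaps of ≥ 5 within-class sds, so the classes
  are separable by construction). Planted phenomena: a J = 3.9 Hz
  doublet with lines on bucket boundaries (three buckets), a J = 8.1 Hz
  doublet with mid-bucket lines (two buckets around a near-empty one),
  metabolites with two separated signal regions, two doublets
  superimposed in one bucket, a ρ = 0.9 correlated acid pair, and 228
  pure-noise buckets.
* **Small scenario** (`two_group_scenario`): two two-metabolite groups
  with different class contrasts plus a baseline class. Three classes
  are essential: with two classes both contrasts reduce to the same
  split (a surrogate may mirror a split in either direction), and no
  relation method could — or should — separate them.

What the generator does *not* emulate: chemical-shift misalignment
across samples (available as an off-by-default jitter option),
second-order coupling, baseline or phase distortion, and solvent
artefacts. Passing tests therefore demonstrate correctness of the
statistical machinery on cleanly bucketed data, not robustness to
preprocessing failures.

## Problem sizes and runtime

The package's test and reproduction runs use desk-scale sizes chosen to
keep full runs in minutes while leaving all qualitative behaviour
intact: fixture forests at `ntree = 500` (production default 10000),
Boruta capped at 25 runs in the pipeline (decisions at confidence 0.01
typically complete within ~10 runs; the production cap is 157), and
null checks on 80 × 100 tables at `ntree = 150`. Scores stabilise well
below these tree counts at n = 80.

## Known limitations

* The SMD shadow threshold is an empirical-null order statistic; its
  false-selection rate on pure noise is centred on the nominal quantile
  (1%), not bounded by it. Use the Bonferroni-style Boruta path when
  strict null control matters.
* Relation values of variables that rarely act as primary splitters
  average few nodes and are noisy; the symmetrised matrix damps but
  does not remove this.
* Surrogates are used for importance and relations, not for
  missing-value prediction; tables must be complete.
* Bucket labels assume non-negative chemical shifts with two-decimal
  rendering at 0.01 ppm width.
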