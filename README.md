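# nmrforest

Random-forest analysis of bucketed ¹H NMR metabolomics data that opens
the classifier's black box: class-weighted forests with **CART surrogate
splits**, variable selection by **surrogate minimal depth (SMD)** and by
**Boruta**, and the **mean adjusted agreement** relation parameter that
groups spectral buckets by the classification information they share.

## The problem

Untargeted ¹H NMR profiling of biological samples (food authentication,
e.g. distinguishing truffle species) yields hundreds of 0.01 ppm-wide
intensity *buckets* per spectrum. A random forest classifies such tables
almost effortlessly — but a bare accuracy number says nothing about
*which* molecules drive the separation, which buckets carry the same
multiplet, or which metabolites contribute mutually exchangeable
information. This package reimplements a forest engine that stores, at
every internal node, the `s` best surrogate splits together with their
adjusted agreement

&nbsp;&nbsp;&nbsp;&nbsp;`adj(j) = (A_j − m) / (1 − m)`,

where `A_j` is the fraction of node samples that variable `j`'s best
mimicking split sends to the same side as the primary split and `m` is
the larger primary side fraction — 1 for a perfect stand-in, 0 for the
trivial majority rule. From these surrogates follow:

* **SMD**: per tree, the depth at which a variable first appears as
  primary *or surrogate* splitter (absent variables get max internal
  depth + 1); averaged over trees, lower = more important. Selection
  thresholds come from permuted shadow variables refitted under the
  same seed discipline.
* **Mean adjusted agreement**: the relation of variable `j` to `i` is
  `j`'s adjusted agreement averaged over the nodes where `i` splits
  (0 when `j` is not among the stored surrogates), then over the trees
  in which `i` splits. Same-signal buckets score near 1; unrelated
  buckets near 0. Ward/Euclidean clustering of this matrix yields
  groups of metabolites with shared classification information.
* **Boruta** (comparison selector): variables must repeatedly beat the
  best permuted shadow copy in bias-corrected Gini importance; decisions
  by two one-sided binomial tests.

Forest defaults follow the bucketed-NMR conventions: `ntree = 10000`,
`mtry = ceil(p^(3/4))`, `min.node.size = 1`, `s = round(0.05 p)`, and
case weights `1/(K·n_c)` that balance unequal class sizes in the
bootstrap.

A synthetic-data module generates bucketed spectra with full ground
truth — Lorentzian multiplets (J = 0–18 Hz, linewidths 0.7–3 Hz at
400 MHz, where one bucket is exactly 4 Hz), signals on and off bucket
boundaries, metabolites with several signals, class-specific log-normal
concentrations, correlated metabolite pairs, superimposed signals, and
hundreds of pure-noise buckets — so every stage of the analysis is
validated against known truth.

## Worked example

```python
import nmrforest as nf

# packaged scenario: 80 samples, 5 species (28/7/12/21/12), 285 buckets
table, truth = nf.truffle_like_scenario(seed=1)

params = nf.default_params(table.n_buckets, table.class_counts(),
                           ntree=500, seed=1)
results = nf.SurrogateForest.from_bucket_table(table, params).fit(seed=1)
print(results.oob_report().summary())
```

```
Out-of-bag classification report
  accuracy: 100.0%   OOB error: 0.0%

               T_aestivum  T_borchii  T_indicum  T_magnatum  T_melanosporum
T_aestivum             28          0          0           0               0
T_borchii               0          7          0           0               0
T_indicum               0          0         12          0               0
T_magnatum              0          0          0          21               0
T_melanosporum          0          0          0           0              12
```

Every species is recovered without error from the out-of-bag votes —
the prerequisite for interpreting the model. Selection and relations:

```python
sel = nf.select_variables_smd(results=results, seed=1)
print(len(sel.selected))                    # 56 of 285 buckets selected

mat = results.mean_adjusted_agreement()
print(mat.get("3.17-3.18", "3.18-3.19"))    # 1.0   — same doublet
print(mat.get("3.17-3.18", "2.22-2.23"))    # 0.0   — noise bucket

clustering = nf.cluster_relations(mat, k=4)  # metabolite groups
```

The three buckets of the boundary-straddling doublet at 3.16–3.19 ppm
relate at ≈ 1.0 (they carry the same signal), while relations to
pure-noise buckets vanish — the pattern that lets buckets be assigned
to signals, signals to metabolites, and metabolites to groups with
shared class information.

The same workflow runs from the shell:

```bash
nmrforest simulate --seed 1 --out data/
nmrforest run-all --input data/table.csv --out run/ --seed 1
```

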