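# ocm-ann

Analysis toolkit for case-control studies of one-carbon (folate) metabolism:
genotype/biomarker coding, synthetic cohort generation from published group
summaries, a classifier battery with three validation protocols, evolutionary
joint selection of variables and train/test subsets, and an
auto-contractive-map + minimum-spanning-tree "semantic connectivity map" of
variable associations.

## What it does

The pipeline replays a full study on a synthetic or user-supplied cohort of
AD / control subjects described by nine biallelic polymorphism genotypes and
three serum biomarkers (folate, homocysteine, vitamin B12):

1. **Coding** (`ocm_ann.cohort_model`) — each polymorphism becomes three
   binary indicator columns (wild type / heterozygous / mutant, exactly one
   set per record); biomarkers are min-max scaled to [0, 1]. The
   classification matrix has 30 columns; the association matrix adds a
   `_LOW` complement (1 − x) per biomarker and two class-indicator columns
   (35 columns).
2. **Synthetic cohorts** (`ocm_ann.synthetic_cohort`) — per-group genotype
   frequencies and biomarker mean / 95%-CI summaries (packaged
   parameterization, n = 40 per group) drive a moment-matched lognormal +
   categorical generator with an optional Gaussian-copula coupling between
   variables. A planted-signal generator provides selection benchmarks with
   known ground truth.
3. **Classification** (`ocm_ann.learners`, `ocm_ann.validation`) — a native
   Euclidean KNN with fully deterministic tie rules plus scikit-learn
   adapters (Logistic, J48-style tree, NaiveBayes, RandomForest, …), run
   under stratified K-fold, stratified random-split, and two-subset
   (train A / test B and vice versa, errors summed) protocols. Reports carry
   per-class accuracy, arithmetic and weighted means, and the error count.
4. **Variable selection** (`ocm_ann.twist_select`) — a seeded generational GA
   whose genome concatenates a variable mask with a record bipartition;
   fitness is the blind two-way KNN accuracy minus small parsimony and
   subset-divergence penalties.
5. **Connectivity map** (`ocm_ann.autocm_map`) — an auto-contractive map is
   trained on the 35-column association matrix; converged second-layer
   weights become distances (d = C − symmetrized weight), a deterministic
   Kruskal MST filters them, and edges carry [0, 1] link strengths with hub
   nodes flagged. Exports GraphML and DOT.

## CLI

```sh
ocm-ann simulate --n-per-group 40 --seed 1 --coupling literature --out cohort.csv
ocm-ann validate --cohort cohort.csv
ocm-ann encode   --cohort cohort.csv --matrix classification --out design.csv
ocm-ann battery  --cohort cohort.csv --protocol kfold --k 10 --out battery.csv
ocm-ann twist    --cohort cohort.csv --seed 1 --out twist/
ocm-ann autocm   --cohort cohort.csv --out map/
ocm-ann run-study --seed 1 --out study/      # full pipeline + manifest
```

`run-study` emits, in order: K-fold and random-split battery reports on all
30 variables, the selection report and evolved subsets, K-fold and two-subset
reports on the selected variables, the connectivity map
(distances/MST/GraphML/DOT), and a `manifest.json` with stage seeds and
SHA-256 hashes of every artifact. Reruns with the same config and seed are
byte-identical.

## Notes

- Biomarker SDs are derived from printed 95% CI half-widths as
  `sd = half_width × √n / 1.959964`; draws are lognormal moment-matched to
  (mean, sd) so they are positive and mean-unbiased.
- The auto-contractive map uses online per-record updates in dataset order;
  weights start at 0.01·C because exactly-zero weights are a fixed point of
  the contraction rule. `C` defaults to the number of variables.
- All stochastic stages derive their seeds from one global seed via
  `numpy.random.SeedSequence`.
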