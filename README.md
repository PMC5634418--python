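# multisol

Solution multiplicity in two-group expression classification: many genuinely
different models and feature subsets can classify a dataset equally well.
`multisol` makes that phenomenon measurable with four building blocks:

- **ELM classifier** — an Extreme Learning Machine built from scratch: a
  seeded random single hidden layer (the `n_hidden x m` weight matrix that
  identifies a model) and a minimum-norm least-squares readout.
- **t-test feature ranking** — per-feature two-sample Welch t-test (Student
  optional), deterministic tie handling, top-k selection.
- **Multiplicity screen** — thousands of seeded ELM fits on a fixed feature
  set (`Top20Features` or `AllFeatures` mode), a census of runs with test
  accuracy strictly above a cutoff, and an elementwise weight-difference
  comparison of the two best models. SVM / Naive Bayes baselines run through
  the same census machinery via adapters over scikit-learn.
- **Triplet screen** — exhaustive evaluation of every 3-feature subset of the
  top-50 ranked features (C(50,3) = 19,600 candidates) on one shared 80/20
  split, with per-metric (accuracy / precision / recall) cutoff censuses,
  best-10 summaries and rank-dispersion statistics.

A synthetic data generator with planted informative features and correlated
redundant blocks makes every stage testable offline, with `easy` and
`difficult` presets mimicking strongly and weakly separable cohorts.

## CLI

```sh
# generate a synthetic dataset (matrix.tsv + labels.tsv)
multisol simulate --preset easy --seed 1 --out data/

# rank features by two-sample t-test
multisol rank data/matrix.tsv data/labels.tsv --out ranks.tsv

# repeated-initialization model screen + best-pair weight difference
multisol screen data/matrix.tsv data/labels.tsv \
    --mode top20 --runs 500 --cutoff 0.9 --seed 3 --out screen/

# exhaustive triplet screen over the top-50 features
multisol triplets data/matrix.tsv data/labels.tsv \
    --k 50 --cutoff-acc 0.9 --seed 5 --out triplets/

# full pipeline: ranking, screens, heatmap, 3-D rank scatters, manifest
multisol report data/matrix.tsv data/labels.tsv --seed 1 --out report/
```

Input matrices are tab- or comma-delimited (features in rows, first column =
feature id, header = sample ids); the label file maps sample id to one of two
class labels. All numeric outputs are TSV; every run writes a JSON manifest
(seeds, configs, input digests) from which `multisol report` output can be
reproduced bit-identically.

## Library use

```python
from multisol import (ELMConfig, ScreenConfig, SplitSpec, generate, preset,
                      rank_features, run_screen, screen_triplets)

ds = generate(preset("easy", seed=1))
report = run_screen(ds, ScreenConfig(mode="Top20Features", n_runs=500,
                                     cutoff=0.9, base_seed=3))
print(report.n_above_cutoff, report.max_acc_above)

trip = screen_triplets(ds, rank_features(ds), k=50,
                       elm_config=ELMConfig(n_hidden=150, seed=11),
                       split_spec=SplitSpec(train_fraction=0.8, seed=5))
print(trip.census, trip.best10("accuracy").min_mean_rank)
```

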