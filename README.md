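# rumblesig

Vocal signatures in the rumbles of female elephants, analysed at four
nested social levels — individual caller, core group, bond group and
population — on synthetic data with known ground truth.

African elephants live in a tiered society: mother–offspring core groups
led by a matriarch, core groups affiliated into bond groups, bond groups
within a population. If elephants converge vocally on their associates,
their low-frequency rumbles should carry group signatures at these
levels. `rumblesig` implements the full analysis chain needed to ask that
question, together with a synthetic-data generator that plants known
signature strengths so every stage can be validated offline:

1. **Synthetic study generator** — harmonic-stack rumbles whose
   second-harmonic (f1) mean is `context base + population + bond group +
   core group + individual offsets + age·slope + noise`, plus daily
   sighting tables with hierarchically ordered joint-sighting rates and a
   pairwise genetic-relatedness table that can be decoupled from group
   membership.
2. **Acoustic features** — a 94-dimension, gain-invariant battery over a
   mel spectrogram (22 bands × 4 temporal moments + 6 global summaries),
   and the f1 contour traced by dynamic programming with nine summary
   statistics (mean, s.d., skew, kurtosis, p10, p90, and the frequency at
   25/50/75% of call duration).
3. **Social-tier inference** — simple-ratio association indices
   `x / (x + yA + yB)`, Ward clustering on `1 − index`, an automatic
   knot (elbow) cut of the cumulative-bifurcation curve for core groups,
   and the same procedure on matriarchs only for bond groups.
4. **Classification experiments** — random forests (500 trees, 6
   variables/node, 60% of observations per tree without replacement,
   fully grown) with leakage-proof hold-outs: whole callers (population
   and core-group levels), whole core groups (bond level), whole
   recording dates (individual level). Each iteration's accuracy is
   compared with a majority (zero-rate) classifier by a one-tailed exact
   binomial test `P(X ≥ k)`, and medians over many iterations summarise
   the experiment.
5. **Call similarity** — node-size-adjusted proximity scores from
   8000-tree full-data forests,
   `score(i,j) = (1/T) Σ_t [leaf_t(i)=leaf_t(j)] / size_t(leaf)`,
   modelled with a gamma mixed regression (log link, caller-dyad random
   intercept, Laplace-approximated maximum likelihood):
   `similarity ~ pair class + scaled |age difference| (+ relatedness) +
   (1 | dyad)`, with analysis-of-deviance χ² tests and Tukey-adjusted
   pairwise contrasts between pair classes.

The intended users are bioacousticians and behavioural ecologists who
want a tested, reusable implementation of this design — the grouped
hold-out + zero-rate-baseline protocol and the proximity-GLMM machinery
apply to any repeated-calls dataset, not only to elephants.

## Worked example

```python
from rumblesig.simulate import SimConfig, generate_dataset
from rumblesig.features import extract_features_table, mel_feature_names
from rumblesig.classify import run_experiment

cfg = SimConfig(n_populations=2, callers_per_population=(12, 12),
                bond_groups_per_population=2, core_groups_per_bond=2,
                calls_per_caller=8.0, sigma_pop_hz=4.0, n_days=30, seed=9)
ds = generate_dataset(cfg)
feat = extract_features_table(ds.waveforms)
calls = ds.calls.merge(ds.truth.callers[["caller_id", "bond_group",
                                         "core_group"]], on="caller_id")
res = run_experiment(feat, calls, "population", n_iter=50, seed=3,
                     feature_cols=mel_feature_names())
```

This prints (see `examples/04_classification_experiment.py`):

```
190 calls, 2 classes, 50 iterations
median accuracy          : 0.770
median majority baseline : 0.469
median binomial p        : 0.00063
test fraction            : 0.17 +/- 0.02
```

A planted +4 Hz second-harmonic offset between populations lets the
forest classify 77% of held-out callers' calls correctly, against a 47%
zero-rate baseline — the signature generalises to callers the model
never saw. The `examples/` directory holds one short script per
capability (synthesis, features, social tiers, classification,
similarity GLMMs).

## Command line

```bash
rumblesig simulate --seed 1 --out data/        # WAV + CSV tables
rumblesig features --data data/
rumblesig groups   --data data/
rumblesig classify --data data/ --seed 1
rumblesig all      --seed 1 --out results/     # everything, desk scale
```

All outputs are CSV/WAV/JSON; every table starts with a provenance
header recording the config hash and seed.

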