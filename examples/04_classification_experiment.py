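"""Can a forest tell the two populations apart better than guessing?

Generates a dataset with a +4 Hz second-harmonic offset between the
populations, runs the leakage-proof caller-holdout experiment, and
compares the forest's accuracy with the majority (zero-rate) classifier
via one-tailed exact binomial tests.
"""

from rumblesig.classify import run_experiment
from rumblesig.features import extract_features_table, mel_feature_names
from rumblesig.simulate import SimConfig, generate_dataset

cfg = SimConfig(
    n_populations=2,
    callers_per_population=(12, 12),
    bond_groups_per_population=2,
    core_groups_per_bond=2,
    calls_per_caller=8.0,
    sigma_pop_hz=4.0,
    n_days=30,
    seed=9,
)
ds = generate_dataset(cfg)
feat = extract_features_table(ds.waveforms)
calls = ds.calls.merge(
    ds.truth.callers[["caller_id", "bond_group", "core_group"]], on="caller_id"
)

res = run_experiment(feat, calls, "population", n_iter=50, seed=3,
                     feature_cols=mel_feature_names())
print(f"{res.n_calls} calls, {res.n_classes} classes, 50 iterations")
print(f"median accuracy          : {res.median_accuracy:.3f}")
print(f"median majority baseline : {res.median_baseline:.3f}")
print(f"median binomial p        : {res.median_p:.2g}")
print(f"test fraction            : {res.test_fraction_mean:.2f} "
      f"+/- {res.test_fraction_sd:.2f}")
print("\nAccuracy above the baseline with a small median p means the planted"
      " population signature generalises to callers the forest never saw.")
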