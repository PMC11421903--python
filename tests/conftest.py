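import numpy as np
import pandas as pd
import pytest

from rumblesig.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Two populations x 8 callers in 2 bonds x 2 cores; fast to generate."""
    return SimConfig(
        n_populations=2,
        callers_per_population=(8, 8),
        bond_groups_per_population=2,
        core_groups_per_bond=2,
        calls_per_caller=7.0,
        n_days=40,
        seed=101,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_annotated_calls(tiny_dataset) -> pd.DataFrame:
    cols = ["caller_id", "bond_group", "core_group", "age_years"]
    return tiny_dataset.calls.merge(tiny_dataset.truth.callers[cols], on="caller_id")


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset) -> pd.DataFrame:
    from rumblesig.features import extract_features_table

    return extract_features_table(tiny_dataset.waveforms)


def make_call_table(
    n_callers_per_stratum: dict[str, int],
    calls_per_caller: int = 6,
    n_dates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Metadata-only call table for split tests (no audio needed)."""
    rng = np.random.default_rng(seed)
    rows = []
    for stratum, n_callers in n_callers_per_stratum.items():
        for c in range(n_callers):
            caller = f"{stratum}_f{c:02d}"
            for k in range(calls_per_caller):
                rows.append(
                    {
                        "call_id": f"{caller}_r{k:02d}",
                        "caller_id": caller,
                        "population": stratum.split("_")[0],
                        "date": f"day{rng.integers(n_dates):02d}",
                        "context": "contact",
                    }
                )
    return pd.DataFrame(rows)
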