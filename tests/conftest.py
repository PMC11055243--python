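import numpy as np
import pandas as pd
import pytest

import pairhmm as ph


@pytest.fixture(scope="session")
def small_cohort() -> ph.SyntheticCohort:
    """Desk-scale synthetic cohort: 6 patients, 10 pairs, 750 genes."""
    cfg = ph.SimulationConfig(
        n_patients=6,
        pairs_per_patient=(1, 2, 3, 1, 2, 1),
        chromosome_lengths={"1": 300, "2": 250, "3": 200},
        seed=2024,
    )
    return ph.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_cohort) -> list[ph.PairProfile]:
    return ph.compute_pair_profiles(
        small_cohort.expression, small_cohort.pairs, small_cohort.annotation
    )


@pytest.fixture(scope="session")
def trained_small(small_profiles) -> ph.TrainingResult:
    return ph.baum_welch_map(
        ph.initial_parameters(),
        ph.default_priors(),
        ph.profiles_to_sequences(small_profiles),
    )


@pytest.fixture(scope="session")
def small_decodings(trained_small, small_profiles) -> list[ph.StateDecoding]:
    return [ph.decode_states(trained_small.params, p) for p in small_profiles]


@pytest.fixture()
def tiny_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD"],
            "chromosome": ["1", "1", "2", "X"],
            "start": [100, 500, 50, 10],
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
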