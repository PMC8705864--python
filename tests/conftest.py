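import dataclasses

import numpy as np
import pandas as pd
import pytest

from degnet import de, simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimConfig:
    """Scaled-down simulation world for fast unit tests (the full-size
    defaults are exercised by the acceptance suite)."""
    return simulate.SimConfig(
        n_genes=300,
        n_samples_a=6,
        n_samples_b=6,
        frac_de=0.2,
        n_terms=12,
        term_size_range=(10, 25),
        n_enriched_terms=2,
        n_planted_hubs=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """One simulated (counts, design, edges, annotations, truth) tuple."""
    return simulate.simulate_all(small_config)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    rng = np.random.default_rng(11)
    counts = rng.poisson(50, size=(40, 6)) + 1
    return pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(40)],
        columns=["a1", "a2", "a3", "b1", "b2", "b3"],
    )


@pytest.fixture()
def toy_design() -> de.Design:
    return de.Design(
        assignments={"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
        cohort_a="A",
        cohort_b="B",
    )
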