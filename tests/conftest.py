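import numpy as np
import pandas as pd
import pytest

from txconcord import CountMatrix, SampleSheet, SimulationConfig, simulate_study


@pytest.fixture
def tiny_counts():
    return CountMatrix(
        pd.DataFrame(
            [[10, 20], [30, 60]],
            index=["g1", "g2"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def two_group_sheet():
    def make(n_a, n_b, cond_a="A", cond_b="B"):
        samples = [f"{cond_a}{i}" for i in range(n_a)] + [f"{cond_b}{i}" for i in range(n_b)]
        return SampleSheet(
            pd.DataFrame(
                {"condition": [cond_a] * n_a + [cond_b] * n_b},
                index=pd.Index(samples, name="sample_id"),
            )
        )

    return make


@pytest.fixture(scope="session")
def demo_study():
    """One modest synthetic study shared across tests (strong planted effects)."""
    cfg = SimulationConfig(
        seed=421,
        n_genes=800,
        dispersion=0.05,
        de_fraction=0.15,
        lfc_abs=1.5,
        model_lfc_abs=2.0,
    )
    return simulate_study(cfg)


def random_count_matrix(rng, n_genes=5, n_samples=4, low=1, high=200):
    vals = rng.integers(low, high, size=(n_genes, n_samples))
    return CountMatrix(
        pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
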