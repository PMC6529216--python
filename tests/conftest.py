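import numpy as np
import pandas as pd
import pytest

import codonopt as co


@pytest.fixture(scope="session")
def small_scenario():
    return co.SimScenario(n_genes=400, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    """One modest synthetic dataset shared by read-only tests."""
    return co.simulate_all(small_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random in-frame CDS body of sense codons (no start/stop framing)."""
    codons = rng.choice(np.array(list(co.SENSE_CODONS)), size=n_codons)
    return "".join(codons)


@pytest.fixture()
def make_cds():
    return random_cds
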