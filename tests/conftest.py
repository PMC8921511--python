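import pandas as pd
import pytest

from expr_attributor.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=1000, seed 0) shared across tests."""
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture()
def toy_expression():
    """A tiny 3-gene x 4-patient log2 expression frame."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 5.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["A", "B", "C", "D"],
    )
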