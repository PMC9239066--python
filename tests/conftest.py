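import numpy as np
import pandas as pd
import pytest

from rhizolink.synthetic import (
    CommunityParams,
    default_planted,
    generate_design,
    simulate_counts,
)


@pytest.fixture(scope="session")
def paper_design():
    """Full sampling schedule: 6 blocks, 8 days, diel windows at both stages."""
    return generate_design()


@pytest.fixture(scope="session")
def small_experiment(paper_design):
    """One seeded count table with 5 planted growth couplings."""
    counts, truth = simulate_counts(
        paper_design, ground_truth_spec=default_planted(), seed=42
    )
    return counts, truth


@pytest.fixture()
def toy_counts():
    """5 samples x 4 features with hand-checkable structure."""
    data = pd.DataFrame(
        {
            "asvA": [10, 20, 0, 5, 1],
            "asvB": [5, 10, 2, 0, 1],
            "asvC": [0, 0, 8, 5, 8],
            "asvD": [85, 70, 90, 90, 90],
        },
        index=[f"s{i}" for i in range(5)],
    )
    return data
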