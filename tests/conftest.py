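import numpy as np
import pandas as pd
import pytest

from homesite.community_io import FeatureTable
from homesite.synthetic_data import SyntheticStudyConfig, generate_study


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 ASVs x 2 samples with per-sample totals (6, 9)."""
    return FeatureTable(
        pd.DataFrame(
            {"s1": [5, 1, 0], "s2": [0, 2, 7]},
            index=["asvA", "asvB", "asvC"],
        )
    )


@pytest.fixture
def donor_recipient_table() -> FeatureTable:
    """A donor pair plus recipients on a 6-ASV universe."""
    return FeatureTable(
        pd.DataFrame(
            {
                "dnat": [40, 30, 20, 10, 0, 0],
                "dnon": [0, 0, 15, 25, 35, 25],
                "rec1": [20, 20, 20, 20, 10, 10],
                "rec2": [5, 5, 30, 30, 15, 15],
            },
            index=[f"asv{i}" for i in range(6)],
        )
    )


@pytest.fixture(scope="session")
def neutral_study():
    """One default (fully neutral) synthetic study, shared across tests."""
    return generate_study(SyntheticStudyConfig(seed=42))


@pytest.fixture(scope="session")
def selective_study():
    """Strong positive selection (s = 5) on native-only ASVs in a load-balanced mixture.

    Equal donor loads (w = 0.5) isolate the selection signal from propagule
    pressure, making the directional expectations deterministic in sign.
    """
    config = SyntheticStudyConfig(
        seed=7,
        load_range=(1e9, 1e9),
        selection={"WT": {"native_only": 5.0}},
    )
    return generate_study(config)
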