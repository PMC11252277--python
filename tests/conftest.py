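import numpy as np
import pandas as pd
import pytest

import saprolens as sl


@pytest.fixture(scope="session")
def registry_small():
    return sl.TraitRegistry(
        [
            sl.TaxonRecord("tax-a", "Taxon a", "Ciliophora", shape="sphere",
                           length_um=10.0, saprobity_code="b"),
            sl.TaxonRecord("tax-b", "Taxon b", "Ciliophora", shape="cone",
                           length_um=20.0, width_um=10.0, saprobity_code="a"),
            sl.TaxonRecord("tax-c", "Taxon c", "Amoebozoa", shape="cylinder",
                           length_um=30.0, width_um=15.0),
        ]
    )


@pytest.fixture
def matrix_small(registry_small):
    data = pd.DataFrame(
        {
            "tax-a": [100.0, 0.0, 50.0, 20.0],
            "tax-b": [10.0, 40.0, 0.0, 30.0],
            "tax-c": [0.0, 5.0, 5.0, 0.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {"site": ["I", "I", "II", "II"], "month": [1, 2, 1, 2]},
        index=data.index,
    )
    return sl.CommunityMatrix(data, sample_meta=meta)


@pytest.fixture(scope="session")
def valence_table():
    return sl.default_valence_table()


@pytest.fixture(scope="session")
def fixture_averages():
    return sl.load_study_fixture("table4_averages")


@pytest.fixture(scope="session")
def fixture_site_means():
    return sl.load_study_fixture("table4_site_means")


@pytest.fixture(scope="session")
def fixture_registry():
    return sl.load_study_fixture("trait_registry")


@pytest.fixture(scope="session")
def campaign():
    """One default synthetic campaign shared across tests."""
    return sl.generate_campaign(sl.CampaignConfig(seed=42))
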