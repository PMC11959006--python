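import numpy as np
import pandas as pd
import pytest

from fungalnet.synth import default_template, simulate_counts
from fungalnet.tables import OTUTable, SampleMetadata, TaxonomyLineage


@pytest.fixture
def small_table() -> OTUTable:
    """Hand-built 5 OTU × 3 sample table with mixed taxonomy resolution."""
    counts = pd.DataFrame(
        {
            "FN_T901_1": [5, 3, 1, 1, 0],
            "SN_T901_1": [2, 2, 0, 4, 2],
            "TN_T901_1": [0, 1, 3, 0, 6],
        },
        index=["OTU_1", "OTU_2", "OTU_3", "OTU_4", "OTU_5"],
    )
    taxonomy = {
        "OTU_1": TaxonomyLineage.from_string(
            "k__Fungi;p__Ascomycota;c__Sordariomycetes;g__Chaetomium"),
        "OTU_2": TaxonomyLineage.from_string(
            "k__Fungi;p__Ascomycota;c__Eurotiomycetes;g__Penicillium"),
        "OTU_3": TaxonomyLineage.from_string(
            "k__Fungi;p__Mucoromycota;c__Mortierellomycetes;g__Mortierella"),
        "OTU_4": TaxonomyLineage.from_string("k__Fungi;p__Basidiomycota"),
        "OTU_5": TaxonomyLineage.from_string(""),
    }
    metadata = [
        SampleMetadata("FN_T901_1", "FN", "T901"),
        SampleMetadata("SN_T901_1", "SN", "T901"),
        SampleMetadata("TN_T901_1", "TN", "T901"),
    ]
    return OTUTable(counts, taxonomy, metadata)


@pytest.fixture(scope="session")
def synth_pair():
    """One default-template simulation shared across tests (seeded)."""
    template = default_template()
    table, planted = simulate_counts(template, samples_per_cell=3, seed=11)
    return template, table, planted


@pytest.fixture(scope="session")
def synth_table(synth_pair) -> OTUTable:
    return synth_pair[1]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
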