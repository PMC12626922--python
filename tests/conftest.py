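import numpy as np
import pandas as pd
import pytest

from rhizonet import FeatureTable, SampleMetadata, TaxonomyMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table():
    """6 samples x 5 taxa with two 3-sample groups."""
    data = pd.DataFrame(
        [
            [10, 5, 0, 2, 1],
            [12, 4, 1, 3, 0],
            [9, 6, 0, 1, 2],
            [1, 2, 20, 5, 4],
            [0, 3, 18, 6, 5],
            [2, 1, 22, 4, 3],
        ],
        index=[f"S{i}" for i in range(1, 7)],
        columns=[f"ASV_{i}" for i in range(1, 6)],
    )
    return FeatureTable(data)


@pytest.fixture
def small_metadata(small_table):
    ids = small_table.sample_ids
    return SampleMetadata(
        groups=pd.Series(["CK"] * 3 + ["T1"] * 3, index=ids),
        covariates=pd.DataFrame({"pH": [7.8, 7.9, 8.0, 7.1, 7.0, 7.2]}, index=ids),
    )


@pytest.fixture
def small_taxonomy(small_table):
    taxa = small_table.taxon_ids
    return TaxonomyMap(
        pd.DataFrame(
            {
                "kingdom": ["Bacteria"] * 5,
                "phylum": ["Proteobacteria"] * 3 + ["Firmicutes"] * 2,
                "family": ["F1", "F1", "F2", "F2", pd.NA],
                "genus": ["GenA", "GenA", "GenB", pd.NA, pd.NA],
            },
            index=pd.Index(taxa, name="taxon_id"),
        )
    )
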