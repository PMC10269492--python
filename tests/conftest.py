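import numpy as np
import pandas as pd
import pytest

from rootniche import (OtuTable, SampleMetadata, SimulationParams,
                       simulate_community_design, simulate_tree)


@pytest.fixture
def toy_table():
    """3 taxa x 4 samples with simple round numbers."""
    counts = pd.DataFrame(
        {"S1": [2, 2, 0], "S2": [0, 5, 5], "S3": [1, 2, 7], "S4": [4, 4, 4]},
        index=["OTU1", "OTU2", "OTU3"])
    tax = pd.Series(
        ["k__Bacteria;p__Actinobacteria;c__C1;o__O1;f__F1;g__G1",
         "k__Bacteria;p__Actinobacteria;c__C1;o__O2;f__F2;g__G2",
         "k__Bacteria;p__Proteobacteria;c__C2;o__O3;f__F3;g__G3"],
        index=["OTU1", "OTU2", "OTU3"])
    return OtuTable(counts, tax, "bacteria")


@pytest.fixture
def metadata18():
    """3 niches x 3 cultivars x 2 replicates."""
    rows = []
    for n in ("bulk", "rhizosphere", "endosphere"):
        for c in ("rabbiteye", "northern_highbush", "southern_highbush"):
            for r in (1, 2):
                rows.append((f"{n[:2]}_{c[:2]}_{r}", n, c))
    df = pd.DataFrame(rows, columns=["sample_id", "niche", "cultivar"])
    return SampleMetadata(df.set_index("sample_id"))


@pytest.fixture(scope="session")
def community():
    """A fixed simulated niche x cultivar community with its tree."""
    tree = simulate_tree(60, seed=7)
    params = SimulationParams(n_taxa=60, rng_seed=7, depth=5000,
                              n_replicates=2)
    table, meta = simulate_community_design(params, tree)
    return {"table": table, "tree": tree, "meta": meta, "params": params}
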