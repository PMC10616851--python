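import numpy as np
import pytest

import germbank as gb

SEED = 1234


def matrix_from_calls(calls, accession_ids=None, locus_ids=None):
    """Build a GenotypeMatrix from a nested list / array of 0/1/2/-1 calls."""
    calls = np.asarray(calls, dtype=np.int8)
    if accession_ids is None:
        accession_ids = [f"acc{i}" for i in range(calls.shape[0])]
    if locus_ids is None:
        locus_ids = [f"loc{j}" for j in range(calls.shape[1])]
    return gb.GenotypeMatrix(accession_ids, locus_ids, calls)


@pytest.fixture(scope="session")
def default_panel():
    """The standard synthetic panel: 5 diploid + 2 tetraploid species, planted
    duplicates and 5% label errors, with mapping evidence."""
    cfg = gb.default_config(SEED)
    G, records, truth = gb.simulate_panel(cfg)
    evidence = gb.simulate_evidence(cfg, truth, G)
    return cfg, G, records, truth, evidence


@pytest.fixture(scope="session")
def default_distance(default_panel):
    """Distance matrix on the filtered default panel."""
    _, G, records, truth, _ = default_panel
    G1, _ = gb.filter_accessions(G)
    Gf = gb.filter_sites(G1)
    return gb.genetic_distance(Gf)
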