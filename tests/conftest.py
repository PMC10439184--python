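import pandas as pd
import pytest

import pprscope as pp


@pytest.fixture(scope="session")
def panel():
    return pp.load_panel()


@pytest.fixture(scope="session")
def community(panel):
    """Mid-sized synthetic community shared by recovery tests.

    10% of unigenes are truncated inside the helix C--F span so the
    completeness filter has something to reject.
    """
    cfg = pp.SimulationConfig(seed=11, n_unigenes=500, truncated_fraction=0.1)
    return pp.simulate_community(cfg, panel)


@pytest.fixture(scope="session")
def ground_truth(community) -> pd.DataFrame:
    return community.ground_truth.unigenes.set_index("unigene_id", drop=False)


@pytest.fixture(scope="session")
def catalog(community, panel) -> pd.DataFrame:
    return pp.identify_rhodopsins(community.aa_seqs, panel)


@pytest.fixture(scope="session")
def calls(catalog, community, panel) -> pd.DataFrame:
    return pp.classify_catalog(catalog, community.aa_seqs, panel)


@pytest.fixture(scope="session")
def calls_with_domain(catalog, calls) -> pd.DataFrame:
    """Calls joined with best-hit lineage columns for grouping."""
    return calls.merge(
        catalog[["unigene_id", "domain_call", "supergroup"]], on="unigene_id"
    )
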