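import numpy as np
import pandas as pd
import pytest

from xreact import ase_bulk, gene_level, synthetic


@pytest.fixture(scope="session")
def fixture_config():
    """The 200-gene recovery cohort: 3 cell types x 4 replicates, ~480x group depth."""
    return synthetic.default_config(n_genes=200, seed=7)


@pytest.fixture(scope="session")
def bulk_fixture(fixture_config):
    counts, sites, truth = synthetic.simulate_bulk_allelic_counts(fixture_config)
    return counts, sites, truth


@pytest.fixture(scope="session")
def variant_calls(bulk_fixture):
    counts, sites, _ = bulk_fixture
    return ase_bulk.classify_bulk(sites, counts)


@pytest.fixture(scope="session")
def gene_calls(variant_calls):
    return gene_level.call_genes(variant_calls)


def make_summaries(rows):
    """Build a pooled-summary frame from (variant_id, cell_type, no_ref, no_total)."""
    df = pd.DataFrame(rows, columns=["variant_id", "cell_type", "no_ref", "no_total"])
    ratio = df["no_ref"] / df["no_total"]
    df["allelic_ratio"] = ratio
    df["xi_prob_hat"] = np.minimum(ratio, 1 - ratio)
    df["xi_count"] = np.minimum(df["no_ref"], df["no_total"] - df["no_ref"])
    df["testable"] = df["no_total"] >= 20
    return df
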