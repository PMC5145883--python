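import numpy as np
import pandas as pd
import pytest

from stressmodes import SimConfig, StressResponseModel, simulate_dataset


def make_de_table(genes, log2fc, qvalue, alpha=0.05):
    """Build a minimal DE contrast table for toy tests."""
    log2fc = np.asarray(log2fc, dtype=float)
    qvalue = np.asarray(qvalue, dtype=float)
    significant = qvalue < alpha
    direction = np.where(
        significant, np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")), "none"
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": np.full(len(log2fc), 0.3),
            "pvalue": qvalue / 2,
            "qvalue": qvalue,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(genes, name="gene_id"),
    )


def random_de_tables(rng, n_genes=40, alpha=0.05):
    """Random DE triple over a shared gene universe, for oracle tests."""
    genes = [f"g{i}" for i in range(n_genes)]
    tables = {}
    for c in ("CT", "DT", "CD"):
        tables[c] = make_de_table(
            genes,
            rng.normal(0, 2, n_genes),
            rng.uniform(0, 0.2, n_genes),
            alpha=alpha,
        )
    return tables


@pytest.fixture(scope="session")
def planted_run():
    """A mid-size planted simulation fitted once and shared across tests.

    Default mode composition, |L| = 2, phi = 0.1, 3 replicates.
    """
    cfg = SimConfig(n_genes=1500, rng_seed=42)
    truth, design, counts = simulate_dataset(cfg)
    results = StressResponseModel(counts, design).fit()
    return cfg, truth, design, counts, results
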