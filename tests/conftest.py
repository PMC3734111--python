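import numpy as np
import pandas as pd
import pytest

import epicore as ec


@pytest.fixture(scope="session")
def config():
    return ec.AnalysisConfig()


@pytest.fixture(scope="session")
def table1_atlas():
    return ec.load_table1_atlas()


@pytest.fixture(scope="session")
def table1_profile(table1_atlas):
    return ec.aggregate_replicates(table1_atlas)


@pytest.fixture(scope="session")
def table1_genelist():
    return ec.load_table1_genelist()


@pytest.fixture(scope="session")
def table2_enrichment():
    return ec.load_table2_enrichment()


@pytest.fixture(scope="session")
def default_synthetic():
    """Default synthetic atlas at a fixed seed, with its ground truth."""
    atlas, truth = ec.generate_atlas(ec.SimConfig(), seed=0)
    return atlas, truth


@pytest.fixture(scope="session")
def default_synthetic_profile(default_synthetic):
    atlas, _ = default_synthetic
    return ec.aggregate_replicates(atlas)


def random_enrichment(rng, n_genes=20, tissues=("t1", "t2", "t3"),
                      missing_rate=0.0):
    """A small random EnrichmentTable for oracle-equivalence tests."""
    idx = pd.Index([f"p{i}" for i in range(n_genes)], name="probe_id")
    fc = pd.DataFrame(
        rng.lognormal(0.5, 1.0, (n_genes, len(tissues))),
        index=idx, columns=list(tissues))
    if missing_rate:
        mask = rng.random(fc.shape) < missing_rate
        fc = fc.mask(mask)
    symbols = pd.Series([f"g{i % max(n_genes - 2, 1)}" for i in range(n_genes)],
                        index=idx, name="gene_symbol")
    return ec.EnrichmentTable(fold_change=fc, gene_symbols=symbols,
                              reference_tissue="ref", floor=1.0)


def toy_profile(mean, tissues, probe_ids=None, symbols=None,
                present_fraction=None):
    """Build a TissueProfile from a plain value matrix."""
    mean = np.asarray(mean, dtype=float)
    n = mean.shape[0]
    idx = pd.Index(probe_ids if probe_ids is not None
                   else [f"p{i}" for i in range(n)], name="probe_id")
    mean_df = pd.DataFrame(mean, index=idx, columns=list(tissues))
    pf = (pd.DataFrame(np.asarray(present_fraction, dtype=float), index=idx,
                       columns=list(tissues))
          if present_fraction is not None
          else pd.DataFrame(np.nan, index=idx, columns=list(tissues)))
    nrep = pd.DataFrame(1, index=idx, columns=list(tissues))
    syms = pd.Series(symbols if symbols is not None else list(idx),
                     index=idx, name="gene_symbol")
    return ec.TissueProfile(mean_df, pf, nrep, syms)
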