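import numpy as np
import pandas as pd
import pytest

from isletepi import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.SimConfig(seed=7, genome_length=1_000_000, n_chroms=2,
                         n_regions=20, snps_per_region=50, n_umr=6, n_lmr=16)


@pytest.fixture(scope="session")
def small_methylome(small_config):
    return syn.generate_methylome(small_config)


@pytest.fixture(scope="session")
def pooled_methylome(small_methylome):
    from isletepi.methylome import pool_samples
    table, _ = small_methylome
    return pool_samples(table)


def make_region_df(ln_abf, annot, region_id=0, chrom="chr1"):
    """Single-region SNP table for likelihood oracles."""
    n = len(ln_abf)
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chrom": chrom,
        "pos": np.arange(n) * 100,
        "ln_abf": np.asarray(ln_abf, dtype=float),
        "region_id": region_id,
        "annot_A": np.asarray(annot, dtype=float),
    })
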