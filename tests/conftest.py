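import numpy as np
import pandas as pd
import pytest

from xppav import (
    GenotypePanel,
    SampleMeta,
    SimConfig,
    SnpMeta,
    simulate_two_pop,
)


def make_panel(codes, snp_ids=None, sample_ids=None, alleles=None, chrom="1"):
    """Construct a small panel from a genotype matrix (rows = samples)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    snp_ids = snp_ids or [f"s{j+1}" for j in range(m)]
    sample_ids = sample_ids or [f"i{i+1}" for i in range(n)]
    alleles = alleles or [("A", "B")] * m
    snps = [
        SnpMeta(sid, chrom, 1000 * (j + 1), a1, a2)
        for j, (sid, (a1, a2)) in enumerate(zip(snp_ids, alleles))
    ]
    samples = [SampleMeta(s) for s in sample_ids]
    return GenotypePanel(samples=samples, snps=snps, genotypes=codes)


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-population dataset shared across tests (seeded)."""
    cfg = SimConfig(n1=120, n2=180, m=400, seed=20240)
    return simulate_two_pop(cfg)


@pytest.fixture
def toy_phenotypes():
    def _make(panel, trait, sex=None, parity=None):
        n = panel.n_samples
        return pd.DataFrame(
            {
                "sample_id": panel.sample_ids,
                "trait": trait,
                "sex": sex if sex is not None else [1] * n,
                "parity": parity if parity is not None else [1] * n,
            }
        ).set_index("sample_id")

    return _make
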