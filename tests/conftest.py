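import numpy as np
import pandas as pd
import pytest

import condconj as cc


def make_pairs(p1, p2, chrom="1", start_pos=1000, spacing=1000, z1=None, z2=None):
    """Minimal harmonized-pair frame from p-value arrays."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n = len(p1)
    if z1 is None:
        z1 = cc.p_to_z(p1)
    if z2 is None:
        z2 = cc.p_to_z(p2)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n),
            "a1": "A",
            "a2": "G",
            "z1": z1,
            "p1": p1,
            "z2": z2,
            "p2": p2,
            "direction_defined": True,
        }
    )


def singleton_ld(ids):
    """LD reference where every SNP is its own block."""
    return cc.LDReference.from_blocks(pd.Series(range(len(ids)), index=pd.Index(ids)))


@pytest.fixture(scope="session")
def shared_sim():
    """One moderately sized simulated dataset with shared signal."""
    cfg = cc.SimConfig(n_snps=30_000, seed=11)
    return cfg, cc.simulate_pair(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """Pure-null simulation: no causal effects in either trait."""
    cfg = cc.SimConfig(n_snps=200_000, pi=(1.0, 0.0, 0.0, 0.0), seed=5)
    return cfg, cc.simulate_pair(cfg)
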