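import numpy as np
import pandas as pd
import pytest

import mrmediate as mm


@pytest.fixture
def toy_trait():
    """Five well-behaved SNPs on separate chromosomes."""
    return mm.table_from_arrays(
        "toy",
        snp_id=[f"rs{i}" for i in range(1, 6)],
        effect_allele=["A", "A", "C", "A", "G"],
        other_allele=["G", "C", "T", "G", "T"],
        beta=[0.05, -0.04, 0.03, 0.06, -0.02],
        se=[0.005, 0.006, 0.004, 0.005, 0.007],
        pvalue=[1e-20, 1e-12, 1e-9, 1e-25, 1e-3],
        chr=["1", "2", "3", "4", "5"],
        pos=[1_000_000] * 5,
        eaf=[0.3, 0.2, 0.4, 0.25, 0.35],
        n=[400_000] * 5,
    )


@pytest.fixture
def toy_hset():
    """Three instruments with hand-friendly numbers."""
    return mm.HarmonizedSet.from_arrays(
        beta_exposure=[0.10, 0.20, 0.15],
        se_exposure=[0.01, 0.02, 0.015],
        beta_outcome=[0.05, 0.08, 0.045],
        se_outcome=[0.02, 0.03, 0.025],
    )


@pytest.fixture
def null_hset():
    """Fifty simulated instruments with no pleiotropy, theta = 0.1."""
    cfg = mm.SimConfig(n_snps=50, theta=0.1, seed=11)
    exposure, outcome, _ = mm.simulate_uvmr(cfg)
    return mm.harmonize(exposure, outcome)
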