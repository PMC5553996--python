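import numpy as np
import pandas as pd
import pytest

from hrhm.panel import GenotypePanel, qc_filter
from hrhm.simulate import SimConfig, simulate_dataset
from hrhm.blocks import BlockSet


def make_panel(dosages, positions=None, chrom=1, a1=None, a2=None):
    """Small hand-built panel helper used across module tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = 1000 + 100 * np.arange(m)
    snps = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": positions,
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"I{i}" for i in range(n)], "iid": [f"I{i}_0" for i in range(n)], "sex": 1}
    )
    return GenotypePanel(dosages, snps, samples)


@pytest.fixture(scope="session")
def family_sim():
    """One family-structured cohort with a causal block, shared across tests."""
    cfg = SimConfig(
        n_families=40, family_size=4, n_unrelated=240, n_blocks=25, snps_per_block=8,
        haplotypes_per_block_pool=6, causal_block_index=0, hg2_region=0.15,
        hg2_polygenic=0.2, prevalence=0.3, seed=20,
    )
    gdr, covars, truth, keep = simulate_dataset(cfg)
    return cfg, gdr, covars, truth


@pytest.fixture(scope="session")
def family_panel_qc(family_sim):
    """QC-filtered panel and matching BlockSet for the shared cohort."""
    _, gdr, _, _ = family_sim
    panel = qc_filter(gdr.panel, maf_min=0.01, missing_max=1.0)
    # remap block membership after QC by position intervals
    from hrhm.blocks import assign_snps

    blockset = assign_snps(gdr.block_table, panel, policy="drop")
    return panel, blockset
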