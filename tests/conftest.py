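import numpy as np
import pandas as pd
import pytest

from linepanel.genotypes import GenotypeMatrix
from linepanel.simulate import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """25-line desk-scale panel: 5 x 2 Mb chromosomes, 400 SNPs each."""
    cfg = SimulationConfig(
        n_lines=25, n_founder_haplotypes=120, n_chromosomes=5,
        chromosome_length_bp=2_000_000, snps_per_chromosome=400,
        wolbachia_lost_lines=0, outlier_lines=0, broods_per_line=10, seed=7,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def flagged_panel():
    """34-line panel with wolbachia-lost and outlier metadata flags."""
    cfg = SimulationConfig(
        n_lines=34, n_founder_haplotypes=120, n_chromosomes=2,
        chromosome_length_bp=1_000_000, snps_per_chromosome=150,
        broods_per_line=6, seed=11,
    )
    return simulate_panel(cfg)


def toy_matrix(calls, chrom="chr1", line_ids=None, start=100, spacing=50):
    """Small GenotypeMatrix from an explicit int call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_snps = calls.shape
    if line_ids is None:
        line_ids = [f"L{i+1:02d}" for i in range(n_lines)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_snps,
            "pos": start + spacing * np.arange(n_snps),
            "ref": ["A"] * n_snps,
            "alt": ["C"] * n_snps,
        }
    )
    return GenotypeMatrix(line_ids, sites, calls)
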