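import numpy as np
import pandas as pd
import pytest

from heatgs.simpop import SimConfig, simulate_phenotypes, simulate_ssd_population
from heatgs.variantio import GenotypeMatrix


def make_matrix(dosage, chrom=None, pos=None, ref=None, alt=None, line_ids=None):
    """Build a small GenotypeMatrix from a dosage array with default metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    markers = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["Chr01"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        "id": [f"m{j}" for j in range(m)],
        "ref": ref if ref is not None else ["A"] * m,
        "alt": alt if alt is not None else ["G"] * m,
    })
    lines = line_ids if line_ids is not None else [f"L{i:03d}" for i in range(n)]
    return GenotypeMatrix(lines, markers, dosage)


@pytest.fixture(scope="session")
def small_pop():
    """A moderate simulated SSD population shared across tests."""
    cfg = SimConfig(n_chrom=3, chrom_length_cM=100.0, n_markers=300, n_lines=120,
                    generations=("F2", "F4", "F5", "F6"), seed=42)
    mats, truth = simulate_ssd_population(cfg)
    return cfg, mats, truth


@pytest.fixture(scope="session")
def small_pop_pheno(small_pop):
    cfg, mats, truth = small_pop
    pheno = simulate_phenotypes(mats["F4"], truth, cfg, "F4")
    return cfg, mats, truth, pheno
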