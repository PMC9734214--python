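import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from genebankgp.genotype_qc import GenotypeMatrix
from genebankgp.kernels import build_kernels
from genebankgp.popstructure import AdmixtureResult
from genebankgp.synthetic_data import SimulationConfig, TraitArchitecture, simulate_genotypes, simulate_trait


@pytest.fixture(scope="session")
def small_panel():
    """Unstructured inbred panel, no missing data."""
    cfg = SimulationConfig(
        n_samples=80, n_markers=200, k_pops=1, admixture_concentration=1.0, seed=101
    )
    g, q = simulate_genotypes(cfg)
    return g, q


@pytest.fixture(scope="session")
def structured_panel():
    """Two diverged clusters with low admixture."""
    cfg = SimulationConfig(
        n_samples=150, n_markers=400, k_pops=2, fst_like_divergence=0.3,
        admixture_concentration=0.05, seed=103,
    )
    g, q = simulate_genotypes(cfg)
    return g, q


@pytest.fixture(scope="session")
def additive_trait(small_panel):
    g, q = small_panel
    arch = TraitArchitecture(n_additive_qtl=60, heritability=0.7, seed=105)
    blues, truth = simulate_trait(g, q, arch)
    return blues, truth


@pytest.fixture(scope="session")
def small_kernels(small_panel):
    g, _ = small_panel
    return build_kernels(g)


def truth_admixture(q: np.ndarray) -> AdmixtureResult:
    """Wrap a true admixture matrix as an estimation result."""
    return AdmixtureResult(
        Q=q, ancestral_freqs=np.full((q.shape[1], 1), 0.5), k=q.shape[1],
        cross_entropy=0.0, labels=q.argmax(axis=1),
    )


def y_aligned(blues, g: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Trait values aligned with panel positions ``idx``."""
    lookup = blues.set_index("sample_id")["value"]
    return lookup.loc[[g.sample_ids[i] for i in idx]].to_numpy(dtype=float)
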