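import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from cnapath import BacClone, Gene, GenomicInterval
from cnapath.simulate import SimulationConfig


@pytest.fixture
def toy_bacs():
    """Disjoint BACs with mixed anchoring on one chromosome."""
    return [
        BacClone("B1", GenomicInterval("chr1", 100_000, 140_000)),
        BacClone("B2", GenomicInterval("chr1", 400_000, 430_000), left_anchored=True),
        BacClone("B3", GenomicInterval("chr1", 800_000, 920_000),
                 left_anchored=True, right_anchored=True),
        BacClone("B4", GenomicInterval("chr1", 1_300_000, 1_350_000),
                 right_anchored=True),
    ]


@pytest.fixture
def toy_genes():
    return [
        Gene("g1", GenomicInterval("chr1", 110_000, 120_000)),
        Gene("g2", GenomicInterval("chr1", 405_000, 425_000)),
        Gene("g3", GenomicInterval("chr1", 850_000, 900_000)),
        Gene("g4", GenomicInterval("chr1", 1_310_000, 1_340_000)),
    ]


@pytest.fixture
def small_sim_config():
    """Small cohort for fast end-to-end tests."""
    return SimulationConfig(
        seed=11, G=300, n_pathways=20, pathway_size_range=(2, 30), n_samples=30
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
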