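import numpy as np
import pytest

from breedsim.map_tools import build_bins
from breedsim.synthetic import (
    FounderConfig,
    TraitArchitecture,
    default_trait_architecture,
    simulate_founders,
)


@pytest.fixture(scope="session")
def tiny_panel():
    """Small phased founder panel with a linkage map (seconds-scale)."""
    cfg = FounderConfig(
        n_individuals=24,
        n_chromosomes=2,
        chrom_lengths_cm=(60.0, 40.0),
        n_markers=120,
        ld_scale_cm=15.0,
        n_ancestors=4,
        seed=11,
    )
    pop, lmap, anchors = simulate_founders(cfg)
    return pop, lmap, anchors


@pytest.fixture(scope="session")
def tiny_binned(tiny_panel):
    _, lmap, _ = tiny_panel
    return build_bins(lmap)


@pytest.fixture(scope="session")
def ld_panel():
    """Mid-size structured panel for kinship/GWAS calibration tests."""
    cfg = FounderConfig(
        n_individuals=200,
        n_chromosomes=4,
        chrom_lengths_cm=(120.0, 110.0, 100.0, 90.0),
        n_markers=2000,
        ld_scale_cm=20.0,
        n_ancestors=8,
        seed=3,
    )
    pop, lmap, _ = simulate_founders(cfg)
    return pop, lmap
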