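import numpy as np
import pytest

from laminarpy.synthetic_cortex import (PhantomConfig, make_ribbon_phantom,
                                        voxelize)
from laminarpy.bold_simulator import BlockDesign


@pytest.fixture(scope="session")
def flat_slab():
    """Small flat-slab phantom: surfaces, tissue grid and depth truth."""
    cfg = PhantomConfig(fov_mm=(10.0, 10.0, 8.0), fold_amplitude_mm=0.0,
                        mesh_edge_mm=0.7)
    pair = make_ribbon_phantom(cfg)
    tissue, truth = voxelize(pair, cfg)
    return cfg, pair, tissue, truth


@pytest.fixture(scope="session")
def curved_phantom():
    """Default folded ribbon at acquisition resolution."""
    cfg = PhantomConfig()
    pair = make_ribbon_phantom(cfg)
    tissue, truth = voxelize(pair, cfg)
    return cfg, pair, tissue, truth


@pytest.fixture(scope="session")
def small_curved_phantom():
    """Coarse curved phantom cheap enough for exhaustive oracles."""
    cfg = PhantomConfig(fov_mm=(10.0, 10.0, 8.0), fold_amplitude_mm=1.0,
                        fold_wavelength_mm=14.0, mesh_edge_mm=0.7)
    pair = make_ribbon_phantom(cfg)
    tissue, truth = voxelize(pair, cfg)
    return cfg, pair, tissue, truth


@pytest.fixture(scope="session")
def block_design():
    """The standard two-condition 16 s on/off design (168 TRs)."""
    return BlockDesign(tr_s=2.0, block_s=16.0, cycles=10.5,
                       condition_labels=("intact", "scrambled"))


@pytest.fixture(scope="session")
def single_condition_design():
    return BlockDesign()
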