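import numpy as np
import pytest

from molfc import SimulationConfig, make_atlas, simulate_subject, tissue_layout


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(grid_shape=(12, 12, 12), n_timepoints=60,
                            n_templates=2, n_per_group=(2, 2, 2), seed=3)


@pytest.fixture(scope="session")
def tiny_subject(tiny_config):
    """One simulated subject with its atlases, layout and ground truth."""
    atlases = [make_atlas(tiny_config, k)
               for k in range(tiny_config.n_templates)]
    scan, motion, gt = simulate_subject(tiny_config, atlases, "CU", seed=0)
    return {"config": tiny_config, "atlases": atlases, "scan": scan,
            "motion": motion, "gt": gt,
            "layout": tissue_layout(tiny_config.grid_shape)}
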