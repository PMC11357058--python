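import numpy as np
import pytest

from dessol import synthetic


@pytest.fixture(scope="session")
def cfg():
    return synthetic.GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def corpus(cfg):
    return synthetic.generate_corpus(cfg)


@pytest.fixture(scope="session")
def grid_library(cfg, corpus):
    temps = sorted({r.temperature for r in corpus})
    compounds = list(synthetic.DEFAULT_SHAPES)
    return synthetic.generate_grid_library(cfg, compounds, temps)


@pytest.fixture(scope="session")
def recovery_setup():
    """n=200 subsample with noise 0.1 on log10 x, fixed seed."""
    cfg = synthetic.GeneratorConfig(seed=3, noise_sigma=0.1)
    records = synthetic.generate_corpus(cfg)
    rng = np.random.default_rng(3)
    idx = rng.choice(len(records), 200, replace=False)
    sub = [records[i] for i in idx]
    temps = sorted({r.temperature for r in records})
    grids = synthetic.generate_grid_library(
        cfg, list(synthetic.DEFAULT_SHAPES), temps
    )
    return cfg, sub, grids
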