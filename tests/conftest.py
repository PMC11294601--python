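import numpy as np
import pytest

from cyclecell import core, pipeline, simgen


@pytest.fixture(scope="session")
def honeycomb_sample():
    """One deterministic 256x256 honeycomb sample with ground truth."""
    return simgen.generate_training_sample(rng_seed=42, index=0)


@pytest.fixture(scope="session")
def noiseless_params():
    return simgen.NoiseParams(speckle_sigma=0.0, blob_density=0.0,
                              illum_amplitude=0.0, membrane_contrast=1.0)


@pytest.fixture(scope="session")
def micro_cfg():
    """Tiny training recipe used by the training tests."""
    return core.desk_config(epochs=30, checkpoint_interval=10, rng_seed=5,
                            batch_size=4)


@pytest.fixture(scope="session")
def micro_pools(micro_cfg):
    """16 images at 64x64: 6 raw-like, 6 enhanced, 4 binary."""
    pcfg = pipeline.PipelineConfig(rng_seed=5, gan=micro_cfg)
    return pipeline.make_training_pools(pcfg, 6, 6, 4, shape=(64, 64))


@pytest.fixture(scope="session")
def micro_run(micro_cfg, micro_pools):
    """A 30-epoch micro training run shared across training tests."""
    rcm, gab, binary = micro_pools
    checkpoints, log = core.train(micro_cfg, rcm, gab, binary)
    return checkpoints, log
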