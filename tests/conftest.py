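import dataclasses

import numpy as np
import pytest

from dttl import RunConfig, SyntheticConfig, make_cohort


@pytest.fixture(scope="session")
def small_synth_cfg() -> SyntheticConfig:
    """Small cohort for fast structural tests."""
    return SyntheticConfig(n_source_majority=40, n_source_minority=10,
                           n_target_majority=40, n_target_minority=10, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_synth_cfg):
    return make_cohort(small_synth_cfg)


@pytest.fixture(scope="session")
def clean_cfg() -> SyntheticConfig:
    """Noise-free, shift-free configuration (no domain gap)."""
    return SyntheticConfig(n_source_majority=40, n_source_minority=40,
                           n_target_majority=40, n_target_minority=40,
                           noise_sd=0.0, shift_contrast=1.0,
                           shift_brightness=0.0, seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def tiny_run_config(seed: int = 0, **synth_kwargs) -> RunConfig:
    """A fast-running pipeline configuration for plumbing tests."""
    synth = SyntheticConfig(image_size=16, n_source_majority=24,
                            n_source_minority=8, n_target_majority=24,
                            n_target_minority=8, lesion_radius_range=(2, 4),
                            seed=seed, **synth_kwargs)
    cfg = RunConfig(synthetic=synth, seed=seed)
    cfg.cda = dataclasses.replace(cfg.cda, max_epochs=3)
    cfg.cmt = dataclasses.replace(cfg.cmt, max_epochs=2)
    cfg.btl = dataclasses.replace(cfg.btl, max_epochs=2)
    return cfg
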