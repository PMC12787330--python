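import numpy as np
import pytest

from gearvoc import (
    SimulationConfig,
    assemble_tensor,
    pooled_channel_scale,
    preprocess_recording,
    synthesize_dataset,
)

# targets in the study's severity ordering but with gaps wide relative to
# the estimator's per-seed scatter, for recovery-property checks
SEPARATED_TARGETS = {
    "Longline": 140.0,
    "Hook and line": 160.0,
    "Gillnet (two panels)": 180.0,
    "Gillnet (single panel)": 200.0,
    "Gillnet (three panels)": 220.0,
    "Trawl": 240.0,
    "Purse seine": 260.0,
    "Aquaculture": 280.0,
}


def make_config(**kwargs) -> SimulationConfig:
    """Reduced-scale study configuration for fast tests."""
    defaults = dict(
        n_time=150,
        n_channels=35,
        n_replicates=2,
        true_rank=3,
        seed=11,
        noise_sd=0.03,
        missing_rate=0.01,
        outlier_rate=0.004,
        replicate_jitter_sd=0.02,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def clean_config(**kwargs) -> SimulationConfig:
    """Noiseless, injection-free variant (exact low-rank recordings)."""
    defaults = dict(
        noise_sd=0.0, missing_rate=0.0, outlier_rate=0.0, replicate_jitter_sd=0.0
    )
    defaults.update(kwargs)
    return make_config(**defaults)


def pipeline_tensor(config: SimulationConfig):
    """simulate -> clean -> pooled scale -> assemble, returning tensor+truth."""
    recordings, truth = synthesize_dataset(config)
    processed = [preprocess_recording(r, scale="center") for r in recordings]
    processed, _ = pooled_channel_scale(processed)
    tensor = assemble_tensor(processed, gear_order=config.gear_labels)
    return tensor, truth


@pytest.fixture(scope="session")
def clean_dataset():
    cfg = clean_config()
    recordings, truth = synthesize_dataset(cfg)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def noisy_dataset():
    cfg = make_config()
    recordings, truth = synthesize_dataset(cfg)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
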