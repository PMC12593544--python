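import numpy as np
import pytest

from faersig.synthetic import SyntheticConfig, generate_frames


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A fast synthetic quarter: 2,000 reports, ~40-report cohort."""
    defaults = dict(
        seed=seed,
        n_reports=2_000,
        target_share=0.02,
        duplicate_rate=0.20,
        signals=(("Dysphonia", 10.0),),
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_quarter():
    """Frames + ground truth for a small deterministic quarter."""
    cfg = small_config()
    frames, truth = generate_frames(cfg)
    return cfg, frames, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
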