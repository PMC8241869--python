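import numpy as np
import pytest

from wakewave.synthgen import SessionConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """One small but complete synthetic session (EEG + pupil included)."""
    cfg = SessionConfig(n_tasks=2, n_blocks_per_task=1, n_probes_per_block=4,
                        seed=11)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
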