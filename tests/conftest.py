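import io

import numpy as np
import pytest

from drivedaq.codec import write_session
from drivedaq.layout import ModuleSample, SampleMetadata
from drivedaq.simulate import SimConfig, generate_session


def random_sample(rng: np.random.Generator, index: int = 0) -> ModuleSample:
    """A fully randomized but format-valid module sample."""
    meta = SampleMetadata(
        experiment_id=int(rng.integers(0, 2**64, dtype=np.uint64)),
        module_id=int(rng.integers(0, 2**32, dtype=np.uint32)),
        sample_index=index % 2**32,
        chip_live=int(rng.integers(0, 2**32, dtype=np.uint32)),
    )
    return ModuleSample(
        meta,
        rng.integers(0, 2**16, size=1024, dtype=np.uint16),
        rng.integers(0, 2**16, size=96, dtype=np.uint16),
    )


def session_bytes(config: SimConfig) -> bytes:
    buf = io.BytesIO()
    write_session(generate_session(config), buf)
    return buf.getvalue()


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def small_session():
    """A 256-sample, 2-chip quiet session shared across read-only tests."""
    config = SimConfig(n_chips=2, n_units=0, duration_samples=256, seed=11)
    return config, session_bytes(config)
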