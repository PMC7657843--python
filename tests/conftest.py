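import numpy as np
import pytest

import dnamix as dm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_specs():
    """A tiny fast model stack for round-trip tests."""
    return ["2:1:1:0:0.9/0:0:0"]


@pytest.fixture(scope="session")
def hetero_fixture():
    """Piecewise-stationary 1e5-base fixture: uniform background, plain
    repeats, inverted repeats and a two-letter low-complexity segment."""
    rng = np.random.default_rng(42)
    return np.concatenate(
        [
            rng.integers(0, 4, 20000, dtype=np.uint8),
            dm.generate_synthetic(dm.SynthSpec(30000, 1000, 20, 0.0, 0.02, seed=1)),
            dm.generate_synthetic(dm.SynthSpec(30000, 1000, 20, 1.0, 0.005, seed=2)),
            (rng.integers(0, 2, 20000) * 3).astype(np.uint8),
        ]
    )


@pytest.fixture(scope="session")
def repeat_fixture():
    """Repeat-rich fixture: 60 kb, 2 kb source block copied 25 times, 30%
    of copies inverted, 5% substitutions."""
    return dm.generate_synthetic(
        dm.SynthSpec(60000, 2000, 25, 0.3, 0.05, seed=21)
    )


@pytest.fixture(scope="session")
def five_model_specs():
    return [
        "2:1:0:0:0.9/0:0:0",
        "5:1:1:0:0.9/0:0:0",
        "8:4:1:0:0.92/0:0:0",
        "11:32:1:4:0.95/2:8:0.95",
        "14:64:1:8:0.95/3:16:0.95",
    ]
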