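"""Shared fixtures: small synthetic recordings and reduced-scale configs.

Fixtures are session-scoped where generation is expensive; every fixture
is seeded so the suite is deterministic.
"""

import numpy as np
import pytest

from ictalert.annotate import HorizonConfig
from ictalert.models import DCAEConfig
from ictalert.preprocess import WindowSet
from ictalert.synthetic import SimSpec, generate_recording


@pytest.fixture(scope="session")
def tiny_dataset():
    """1-hour 3-channel recording with one signature-bearing seizure."""
    spec = SimSpec(
        duration=3600.0,
        n_channels=3,
        seizure_onsets=(3000.0,),
        signature_strength=2.0,
        gap_spec=((100.0, 200.0),),
        artifact_rate=6.0,
        seed=42,
    )
    return generate_recording(spec)


@pytest.fixture(scope="session")
def small_dcae_cfg():
    return DCAEConfig(n_channels=3, input_len=2560, enc_filters=(4, 4, 8, 8, 16, 16),
                      dec_filters=(8, 8))


@pytest.fixture
def horizon():
    return HorizonConfig()


def grid_windows(n: int, valid=None, t0: float = 0.0) -> WindowSet:
    """A WindowSet with 10-s spacing and dummy signal content (for tests
    that only exercise timing/label logic)."""
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return WindowSet(
        windows=np.zeros((n, 1, 4), dtype=np.float32),
        start_times=t0 + np.arange(n) * 10.0,
        valid=valid,
        fs=0.4,  # 4 samples / 10 s, so window_seconds == 10
    )


@pytest.fixture
def make_grid_windows():
    return grid_windows
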