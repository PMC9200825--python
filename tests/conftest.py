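import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaze_trial():
    """A minimal gaze trial record (dict duck-types a schedule row)."""
    return {
        "task": "gaze",
        "trial_id": 0,
        "condition": "experimental",
        "trial_type": "neutral",
        "validity_block": 80,
        "salient_side": "none",
        "target_side": "right",
        "soa_ms": 150.0,
        "cue_eccentricity_deg": 5.0,
    }
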