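import numpy as np
import pytest

from duoflow import AIFParams, BTEXParams, generate_aif


@pytest.fixture(scope="session")
def times_90s():
    """One sample per heartbeat at 60 bpm over 90 beats."""
    return np.arange(0, 90.0, 1.0)


@pytest.fixture(scope="session")
def stress_aif(times_90s):
    return generate_aif(AIFParams.default_cmr("stress"), times_90s)


@pytest.fixture(scope="session")
def canonical_btex():
    """The reference parameter point used throughout the kinetic tests."""
    return BTEXParams(Fp=1.0, PS=1.2, Vp=0.05, Visf=0.2, delay=2.0)
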