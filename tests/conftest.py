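import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def toy_msa():
    """Four-row gapless toy alignment with known diagnostic columns."""
    from aarscan.io import Msa

    # column:      0123456
    return Msa(
        [
            ("s1", "MRGFIEA"),
            ("s2", "MRGFVEA"),
            ("s3", "MQGFDEA"),
            ("s4", "MKGFEEA"),
        ]
    )
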