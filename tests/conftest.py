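import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_db():
    """10 in-group sequences (7 perfect sites, 3 with 2 mismatches), 5 out-group."""
    from cladeprimer.synthetic import SyntheticConfig, generate_reference_db

    config = SyntheticConfig(
        seed=11,
        in_group_size=10,
        out_group_size=5,
        template_length=500,
        fwd_start=100,
        rev_end=286,
        mismatch_schedule=((0.7, 0), (0.3, 2)),
    )
    return generate_reference_db(config)
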