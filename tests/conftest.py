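import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_cohort():
    """A tiny deterministic simulated cohort shared across tests."""
    from mrdseq.synthetic import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        seed=11,
        n_patients=6,
        n_blocks=300,
        tumor_hyper_fraction=0.2,
        n_donors=25,
        recurrence_fraction=1 / 3,
        ramp_alpha_start=0.02,
    )
    return simulate_cohort(cfg)
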