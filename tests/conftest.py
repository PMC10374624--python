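import pytest
from hypothesis import HealthCheck, settings

from wormquant.synth import SpontaneousConfig, generate_spontaneous
from wormquant.traces import correct_pipeline

settings.register_profile(
    "repro", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


@pytest.fixture(scope="session")
def spontaneous_set():
    """100 default-condition traces with truth and their corrected outputs.

    Shared across the baseline-recovery and event-recovery tests; building
    it once keeps the suite fast.
    """
    out = []
    for seed in range(100):
        cfg = SpontaneousConfig(seed=seed)
        raw, truth = generate_spontaneous(cfg)
        nt = correct_pipeline(raw)
        out.append((cfg, raw, truth, nt))
    return out
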