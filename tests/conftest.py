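import pytest

import ribotrace as rt


@pytest.fixture(scope="session")
def ut50_preset():
    return rt.make_preset("UTu1", 50, 1.0)


@pytest.fixture(scope="session")
def ut50_cohort(ut50_preset):
    """Default-noise cohort pushed through the full pipeline."""
    return rt.run_condition(ut50_preset, 400, seed=101, keep_events=True)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free, bleach-free cohort: detection should be exact."""
    cfg = rt.EmissionConfig(noise_sd=0.0)
    preset = rt.make_preset("UTu1", 50, 1.0, bleach_rate_green=0.0, bleach_rate_red=0.0)
    return rt.run_condition(preset, 60, seed=7, emission_cfg=cfg, keep_events=True)
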