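import numpy as np
import pytest

from dgmoco.phantom import (
    PhantomSpec,
    generate_cardiac_triggers,
    generate_respiratory_trace,
)
from dgmoco.pipeline import PipelineConfig, SignalConfig, run_pipeline


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-size phantom that keeps the moving heart fully inside the grid."""
    return PhantomSpec(shape=(48, 48, 32), spacing_mm=(2.73, 2.73, 2.73),
                       r_endo_mm=16.0, r_epi_mm=24.0, si_amplitude_mm=8.0)


@pytest.fixture(scope="session")
def sinusoid_trace():
    """Noiseless 25-cycle sinusoid, sampling incommensurate with the period."""
    return generate_respiratory_trace(duration=125.0, period=5.0, seed=0,
                                      sampling_rate=24.7)


@pytest.fixture(scope="session")
def constant_triggers():
    return generate_cardiac_triggers(duration=125.0, mean_hr=60.0, sd_hr=0.0)


@pytest.fixture(scope="session")
def default_pipeline_results():
    """One full default-seeded pipeline run shared by the ordering tests."""
    cfg = PipelineConfig(
        phantom=PhantomSpec(shape=(56, 56, 40), spacing_mm=(2.73, 2.73, 2.73)),
        signals=SignalConfig(duration_s=120.0),
        seed=7,
    )
    return run_pipeline(cfg)
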