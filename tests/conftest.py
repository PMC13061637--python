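import numpy as np
import pytest

from darkox.chamber import ChamberExperiment
from darkox.synthetic import ChamberSimConfig, ProfileSimConfig


@pytest.fixture
def clean_chamber_config():
    """Noise-free, drift-free, undamped chamber at the study geometry."""
    return ChamberSimConfig(
        noise_sd=0.0,
        drift_rate=0.0,
        initial_o2_sd=0.0,
        saturation_shape=0.0,
        seed=11,
    )


@pytest.fixture
def clean_profile_config():
    return ProfileSimConfig(noise_sd=0.0, seed=11)


@pytest.fixture
def experiment_for(request):
    def make(config: ChamberSimConfig, **kw) -> ChamberExperiment:
        kw.setdefault("id", "test-chamber")
        kw.setdefault("chamber_area", config.chamber_area)
        kw.setdefault("water_depth", config.water_depth)
        kw.setdefault("ambient_o2", config.ambient_o2)
        kw.setdefault("syringe_volume_ml", config.syringe_volume)
        return ChamberExperiment(**kw)

    return make
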