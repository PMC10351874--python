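import pytest

from myoankle import FeatureSet, MuscleSet, SynthConfig, WindowSpec, generate_trial
from myoankle.synthetic_gait import Burst, MusclePhasing


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free generator: no EMG noise floor, no measurement noise."""
    return SynthConfig(noise_floor=0.0, angle_noise_sd=0.0, moment_noise_sd=0.0)


@pytest.fixture(scope="session")
def trial(synth_config):
    return generate_trial(synth_config, speed=1.2, trial_id="T_fix", seed=3)


@pytest.fixture(scope="session")
def wspec():
    return WindowSpec()


@pytest.fixture(scope="session")
def all_muscles():
    return MuscleSet(["TA", "SO", "MG", "PL", "RF", "VM", "BF", "GMax"])


@pytest.fixture(scope="session")
def iemg_wl():
    return FeatureSet(["IEMG", "WL"])


def single_burst_config(center=45.0, width=5.0, amp=1.0, tonic=0.0, **kwargs):
    """A config whose muscles all carry one identical burst (for envelope tests)."""
    params = {
        m: MusclePhasing((Burst(center, width, amp),), tonic=tonic)
        for m in ("TA", "SO", "MG", "PL", "RF", "VM", "BF", "GMax")
    }
    return SynthConfig(muscle_params=params, **kwargs)
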