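import numpy as np
import pytest

from sstkit import (EventSchedule, RecordingConfig, StimulusSpec,
                    SyntheticParams, cosine_smooth, generate_participant,
                    single_cycle_coefficients)


@pytest.fixture(scope="session")
def stimulus():
    return StimulusSpec()


@pytest.fixture(scope="session")
def schedule():
    return EventSchedule()


@pytest.fixture(scope="session")
def montage():
    return RecordingConfig()


@pytest.fixture(scope="session")
def two_channel_config():
    """FC5 + C3 montage for simulation studies that need nothing else."""
    return RecordingConfig(channel_labels=("FC5", "C3"))


@pytest.fixture(scope="session")
def noiseless_params():
    """Pure 13 Hz carrier at zero phase: no noise, no dip."""
    return SyntheticParams(noise_pink_amplitude=0.0, alpha_amplitude=0.0,
                           cycle_noise_sd=0.0, carrier_phase=0.0)


@pytest.fixture(scope="session")
def dip_params():
    """Noiseless carrier with a fixed 0.3 rad FC5 dip (width 1 s)."""
    return SyntheticParams(noise_pink_amplitude=0.0, alpha_amplitude=0.0,
                           cycle_noise_sd=0.0, carrier_phase=0.0,
                           dip_channels={"FC5": 0.3}, dip_width=1.0,
                           participant_depth_sd=0.0)


@pytest.fixture(scope="session")
def dip_series(dip_params, schedule, two_channel_config, stimulus):
    """Smoothed SSVEP series of one noiseless dip participant (seed 7)."""
    rec = generate_participant(dip_params, schedule, two_channel_config,
                               stimulus, participant_seed=7)
    return cosine_smooth(single_cycle_coefficients(rec, stimulus))
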