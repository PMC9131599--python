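import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Compact simulated study: 3 participants x 4 conditions x 20 s."""
    from pedalemg import SyntheticStudyConfig, simulate_study

    cfg = SyntheticStudyConfig(n_participants=3, duration_s=20.0,
                               master_seed=7)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def processed_trial(small_study):
    """First trial of the small study run through segmentation + envelopes."""
    from pedalemg import (compute_crank_angle, cut_and_resample,
                          offline_envelope, segment_cycles)
    from pedalemg.synth import MUSCLES

    trial = small_study.trials[0]
    trace = segment_cycles(compute_crank_angle(trial.markers))
    sets = {}
    for m in MUSCLES:
        env = offline_envelope(trial.emg.channel(m), fs_hz=trial.emg.fs_hz)
        sets[m] = cut_and_resample(env, trace.cycle_bounds, muscle=m,
                                   participant=trial.participant,
                                   condition=trial.condition)
    return trial, trace, sets


@pytest.fixture()
def rng():
    return np.random.default_rng(20220525)
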