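import numpy as np
import pytest

from fearlfp.session import EventTable, SpikeTrain, Timeseries
from fearlfp.synth import (NoiseSpec, ProtocolSpec, SessionSpec, SpikeGenSpec,
                           constant_state, default_oscs, gen_lfp, gen_session)

FS = 500.0  # test sampling rate; coarser than production to keep suites fast


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def quiet_noise():
    """Pink+line background without artifacts."""
    return NoiseSpec(pink_exponent=1.0, pink_scale=1.0, line_amp=0.2,
                     artifact_rate_per_min=0.0)


@pytest.fixture(scope="session")
def freeze_lfp(quiet_noise):
    state = constant_state(60.0, 0, fs=FS)
    return gen_lfp(state, default_oscs(), quiet_noise, fs=FS,
                   regions=("PL", "HPC"), seed=11)


@pytest.fixture(scope="session")
def move_lfp(quiet_noise):
    state = constant_state(60.0, 1, fs=FS)
    return gen_lfp(state, default_oscs(), quiet_noise, fs=FS,
                   regions=("PL", "HPC"), seed=12)


@pytest.fixture(scope="session")
def laser_session_events():
    """One continuous 120 s laser epoch for entrainment tests."""
    return EventTable.from_records([(0.0, 120.0, "laser", 0),
                                    (0.0, 120.0, "session", -1)])


@pytest.fixture()
def small_bundle():
    """A short retrieval-style synthetic session with spikes."""
    proto = ProtocolSpec.retrieval(laser="sine", n_trials=3,
                                   baseline_duration=30.0)
    spec = SessionSpec(protocol=proto, noise=NoiseSpec(),
                       spike_specs=[SpikeGenSpec(base_rate=8.0, kappa=3.0)],
                       fs=FS, regions=("PL", "HPC"))
    return gen_session(spec, seed=5)


def make_timeseries(samples, fs=FS, region="PL"):
    return Timeseries(np.asarray(samples, float), fs, 0.0, "ch0", region)
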