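import numpy as np
import pytest

from pdgait.preprocess import Recording, SessionRecording
from pdgait.synthetic import GaitProfile, SessionSimulation


def session_from_sim(sim) -> SessionRecording:
    """Wrap a lossless simulation into a SessionRecording (no gaps)."""
    session = SessionRecording(fs_hz=sim.fs_hz)
    for name, sig in sim.signals.items():
        session.sensors[name] = Recording(
            sensor_id=name,
            t0_s=0.0,
            fs_hz=sim.fs_hz,
            acc_g=sig,
            gap_mask=np.zeros(sig.shape[0], dtype=bool),
        )
    return session


@pytest.fixture
def healthy_profile() -> GaitProfile:
    return GaitProfile(
        step_frequency_hz=2.0,
        stride_time_cv=0.02,
        com_excursion_m=0.05,
        leg_length_m=1.0,
        asymmetry=0.0,
        harmonic_noise_sd=0.03,
    )


@pytest.fixture
def pd_profile() -> GaitProfile:
    return GaitProfile(
        step_frequency_hz=1.8,
        stride_time_cv=0.10,
        com_excursion_m=0.04,
        leg_length_m=1.0,
        asymmetry=0.15,
        harmonic_noise_sd=0.05,
    )


@pytest.fixture
def noiseless_profile() -> GaitProfile:
    return GaitProfile(
        step_frequency_hz=2.0,
        stride_time_cv=0.0,
        com_excursion_m=0.05,
        leg_length_m=1.0,
        asymmetry=0.0,
        harmonic_noise_sd=0.0,
    )
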