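import numpy as np
import pytest

import wmcoupling as w


@pytest.fixture(scope="session")
def coupled_recording():
    """60-s single-channel recording with full-strength 6->60 Hz coupling."""
    return w.generate_recording(
        montage=["Cz"],
        duration_s=60.0,
        fs_hz=250.0,
        couplings=[w.CouplingSpec("Cz", "Cz", strength_chi=1.0, noise_sd=0.5)],
        seed=11,
    )


@pytest.fixture(scope="session")
def uncoupled_recording():
    """Same construction with chi = 0 (constant-envelope carrier)."""
    return w.generate_recording(
        montage=["Cz"],
        duration_s=60.0,
        fs_hz=250.0,
        couplings=[w.CouplingSpec("Cz", "Cz", strength_chi=0.0, noise_sd=0.5)],
        seed=11,
    )


@pytest.fixture(scope="session")
def cross_coupled_recording():
    """Full-montage recording with a planted FT9 -> Cz cross-channel coupling."""
    return w.generate_recording(
        duration_s=40.0,
        fs_hz=250.0,
        couplings=[w.CouplingSpec("FT9", "Cz", strength_chi=0.9, noise_sd=0.5)],
        seed=5,
    )


@pytest.fixture(scope="session")
def behavior_table():
    """Two-factor behavioral table, r = 0.65, n = 200 participants."""
    return w.generate_behavior(
        w.BehaviorGenSpec(n_participants=200, inter_factor_r=0.65, seed=3)
    )


@pytest.fixture
def annotated_recording():
    rec = w.generate_recording(montage=["Cz", "Pz"], duration_s=120.0, fs_hz=250.0,
                               couplings=[], seed=0)
    w.generate_events(rec, n_trials=8, seed=1)
    return rec
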