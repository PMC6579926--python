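import numpy as np
import pytest

from dfcstates.coupling import mode_index
from dfcstates.spectral import BandSignals
from dfcstates.synthetic import (Coupling, SimulationConfig, StateSpec,
                                 generate_roi_signals)


@pytest.fixture(scope="session")
def theta_pair_recording():
    """4-ROI noiseless recording: theta-theta pair (0,1) and a theta->gamma1
    phase-amplitude pair (2,3), constant state, with band signals."""
    cfg = SimulationConfig(n_rois=4, duration=10.0, snr_db=None, seed=11)
    state = StateSpec(1, (Coupling(0, 1, mode_index(1, 1)),
                          Coupling(2, 3, mode_index(1, 6))))
    signals, truth = generate_roi_signals(
        cfg, [state], np.ones(cfg.n_segments, dtype=int))
    bs = BandSignals.from_broadband(signals, cfg.fs)
    return cfg, signals, truth, bs


@pytest.fixture(scope="session")
def uncoupled_recording():
    """3-ROI recording with no couplings at all (background only)."""
    cfg = SimulationConfig(n_rois=3, duration=8.0, snr_db=None, seed=5)
    state = StateSpec(1, ())
    signals, truth = generate_roi_signals(
        cfg, [state], np.ones(cfg.n_segments, dtype=int))
    bs = BandSignals.from_broadband(signals, cfg.fs)
    return cfg, signals, truth, bs
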