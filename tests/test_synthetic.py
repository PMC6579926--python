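import numpy as np
import pytest
from scipy.signal import welch

from dfcstates.coupling import CouplingContext, mode_index, mode_iplv_vector
from dfcstates.spectral import BandSignals, DEFAULT_BANDS, bandpass_bank
from dfcstates.synthetic import (Coupling, GroupSpec, SimulationConfig,
                                 StateSpec, generate_group_dataset,
                                 generate_roi_signals,
                                 generate_state_schedule)


class TestScheduleGenerator:
    def test_absorbing_state_stays_put(self):
        seq = generate_state_schedule(np.eye(3), 5, start_state=2, seed=0)
        assert seq.tolist() == [2, 2, 2, 2, 2]

    def test_deterministic_cycle(self):
        tp = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        seq = generate_state_schedule(tp, 6, start_state=1, seed=0)
        assert seq.tolist() == [1, 2, 3, 1, 2, 3]

    def test_empirical_transitions_converge_to_input(self):
        tp = np.array([[0.5, 0.3, 0.2],
                       [0.1, 0.6, 0.3],
                       [0.4, 0.4, 0.2]])
        seq = generate_state_schedule(tp, 100_000, 1, seed=1)
        counts = np.zeros((3, 3))
        np.add.at(counts, (seq[:-1] - 1, seq[1:] - 1), 1)
        est = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(est - tp).max() <= 0.01

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError):
            generate_state_schedule(np.array([[0.5, 0.6], [0.5, 0.5]]), 10)

    def test_reproducible_given_seed(self):
        tp = np.full((2, 2), 0.5)
        a = generate_state_schedule(tp, 100, 1, seed=7)
        b = generate_state_schedule(tp, 100, 1, seed=7)
        assert np.array_equal(a, b)


class TestConfigValidation:
    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fs=150.0)  # below twice the gamma2 edge

    def test_carrier_outside_band_rejected(self):
        carriers = dict(theta=9.0, delta=2.5, alpha1=9.0, alpha2=11.5,
                        beta1=16.5, beta2=25.0, gamma1=40.0, gamma2=70.0)
        with pytest.raises(ValueError):
            SimulationConfig(band_carriers=carriers)

    def test_coupling_validation(self):
        with pytest.raises(ValueError):
            Coupling(1, 1, 2)
        with pytest.raises(ValueError):
            Coupling(0, 1, 37)
        with pytest.raises(ValueError):
            Coupling(0, 1, 2, strength=1.5)


class TestSignalGeneration:
    def test_uncoupled_recording_keeps_dominant_modes_empty(
            self, uncoupled_recording):
        """With all couplings absent the recording is pure background:
        fast-band phase differences sit at the i.i.d. noise floor and the
        surrogate-filtered dominant mode stays 0 at roughly the alpha rate."""
        from dfcstates.coupling import build_dfcg
        _, _, _, bs = uncoupled_recording
        ctx = CouplingContext(bs)
        grid = bs.window_grid(1.0, 1.0)
        m_gamma = mode_index(7, 7) - 1
        vals = [mode_iplv_vector(bs, i, j, (int(s), grid.width_samples),
                                 ctx=ctx)[m_gamma]
                for i, j in ((0, 1), (0, 2), (1, 2))
                for s in grid.starts[:3]]
        assert np.median(vals) < 0.1  # gamma2: many cycles per window
        snaps = build_dfcg(bs, grid, n_surrogates=49, seed=1, ctx=ctx)
        modes = np.stack([s.mode for s in snaps])
        iu, ju = np.triu_indices(3, k=1)
        assert np.mean(modes[:, iu, ju] != 0) <= 0.15

    def test_planted_intra_coupling_has_near_unit_iplv(
            self, theta_pair_recording):
        _, _, _, bs = theta_pair_recording
        ctx = CouplingContext(bs)
        grid = bs.window_grid(1.0, 1.0)
        m = mode_index(1, 1) - 1
        vals = [mode_iplv_vector(bs, 0, 1, (int(s), grid.width_samples),
                                 ctx=ctx)[m] for s in grid.starts]
        assert np.median(vals) > 0.9

    def test_planted_pac_coupling_detected(self, theta_pair_recording):
        _, _, _, bs = theta_pair_recording
        ctx = CouplingContext(bs)
        grid = bs.window_grid(1.0, 1.0)
        m = mode_index(1, 6) - 1
        vals = [mode_iplv_vector(bs, 2, 3, (int(s), grid.width_samples),
                                 ctx=ctx)[m] for s in grid.starts]
        assert np.median(vals) > 0.8

    def test_band_power_concentrates_at_carriers(self):
        cfg = SimulationConfig(n_rois=3, duration=40.0, snr_db=None,
                               active_bands="all", seed=2)
        signals, truth = generate_roi_signals(
            cfg, [StateSpec(1, ())], np.ones(cfg.n_segments, dtype=int))
        nb = bandpass_bank(signals, cfg.fs)
        for r in range(cfg.n_rois):
            for b, band in enumerate(DEFAULT_BANDS):
                f, p = welch(nb[r, b, 500:-500], fs=cfg.fs, nperseg=4096)
                inband = (f >= band.low) & (f <= band.high)
                carrier = truth.carriers[r, b]
                near = np.abs(f - carrier) <= 1.0
                frac = p[near & inband].sum() / p[inband].sum()
                assert frac >= 0.8, (band.name, r, frac)

    def test_ground_truth_window_states(self):
        cfg = SimulationConfig(n_rois=2, duration=4.0, snr_db=None, seed=0)
        schedule = np.array([1, 2, 2, 1])
        states = [StateSpec(1, ()), StateSpec(2, ())]
        _, truth = generate_roi_signals(cfg, states, schedule)
        seg = cfg.segment_samples
        assert truth.window_state(0, seg) == 1
        assert truth.window_state(seg, seg) == 2
        assert truth.window_state(seg // 2, seg) in (1, 2)

    def test_schedule_length_mismatch_rejected(self):
        cfg = SimulationConfig(n_rois=2, duration=4.0)
        with pytest.raises(ValueError):
            generate_roi_signals(cfg, [StateSpec(1, ())], np.ones(3, int))

    def test_duplicate_band_target_rejected(self):
        cfg = SimulationConfig(n_rois=3, duration=2.0)
        m = mode_index(1, 1)
        state = StateSpec(1, (Coupling(0, 2, m), Coupling(1, 2, m)))
        with pytest.raises(ValueError):
            generate_roi_signals(cfg, [state], np.ones(2, int))

    def test_expected_adjacency_of_star_state(self):
        cfg = SimulationConfig(n_rois=4, duration=2.0)
        state = StateSpec(1, (Coupling(0, 1, 3), Coupling(0, 2, 3)))
        _, truth = generate_roi_signals(cfg, [state], np.ones(2, int))
        adj = truth.expected_adjacency(1)
        assert adj[0, 1] == pytest.approx(1.0)  # |sin(pi/2)|
        assert adj[0, 2] == pytest.approx(1.0)
        assert adj[1, 2] == pytest.approx(0.0, abs=1e-12)  # zero-lag leaves
        assert adj[3].sum() == 0


class TestGroupDataset:
    def _specs(self):
        tp = np.array([[0.8, 0.2], [0.3, 0.7]])
        a = GroupSpec("A", (StateSpec(1, (Coupling(0, 1, 2),)),
                            StateSpec(2, (Coupling(1, 2, 3),))), tp)
        b = GroupSpec("B", (StateSpec(1, (Coupling(0, 2, 5),)),
                            StateSpec(2, (Coupling(2, 3, 6),))), tp)
        return a, b

    def test_bookkeeping(self):
        a, b = self._specs()
        cfg = SimulationConfig(n_rois=4, duration=6.0, seed=0)
        subs = generate_group_dataset(a, b, 3, seed=1, config=cfg)
        assert len(subs) == 6
        assert [s.label for s in subs] == ["A"] * 3 + ["B"] * 3
        assert len({s.subject_id for s in subs}) == 6

    def test_same_seed_bit_identical(self):
        a, b = self._specs()
        cfg = SimulationConfig(n_rois=4, duration=6.0, seed=0)
        s1 = generate_group_dataset(a, b, 2, seed=3, config=cfg)
        s2 = generate_group_dataset(a, b, 2, seed=3, config=cfg)
        for x, y in zip(s1, s2):
            assert np.array_equal(x.signals, y.signals)
            assert np.array_equal(x.ground_truth.schedule,
                                  y.ground_truth.schedule)

    def test_identical_repertoires_rejected(self):
        a, _ = self._specs()
        twin = GroupSpec("B", a.states, a.schedule_tp)
        with pytest.raises(ValueError):
            generate_group_dataset(a, twin, 2)

    def test_empty_group_rejected(self):
        a, b = self._specs()
        with pytest.raises(ValueError):
            generate_group_dataset(a, b, 0)
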