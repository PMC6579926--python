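import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfcstates.coupling import (CouplingContext, CouplingSnapshot, N_MODES,
                                build_dfcg, comodulogram, dominant_mode,
                                iplv, mode_bands, mode_index, mode_is_cross,
                                mode_iplv_vector, pac_iplv,
                                surrogate_null_for_pair, SurrogateNull)
from dfcstates.spectral import DEFAULT_BANDS


class TestModeEnumeration:
    def test_eight_intra_plus_twentyeight_cross(self):
        intra = [m for m in range(1, N_MODES + 1) if not mode_is_cross(m)]
        cross = [m for m in range(1, N_MODES + 1) if mode_is_cross(m)]
        assert len(intra) == 8 and len(cross) == 28 and N_MODES == 36

    def test_bijection_between_indices_and_descriptors(self):
        seen = set()
        for m in range(1, N_MODES + 1):
            lo, hi = mode_bands(m)
            assert mode_index(lo, hi) == m
            seen.add((lo, hi))
        assert len(seen) == 36

    def test_fixed_order_anchors(self):
        assert mode_bands(1) == (0, 0)      # delta
        assert mode_bands(2) == (1, 1)      # theta
        assert mode_bands(8) == (7, 7)      # gamma2
        assert mode_bands(9) == (0, 1)      # delta-theta
        assert mode_bands(36) == (6, 7)     # gamma1-gamma2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mode_bands(0)
        with pytest.raises(ValueError):
            mode_bands(37)


class TestIplv:
    def test_closed_forms(self):
        n = 500
        assert iplv(np.zeros(n), np.zeros(n)) == pytest.approx(0.0)
        assert iplv(np.zeros(n), np.full(n, -np.pi / 2)) \
            == pytest.approx(1.0)
        assert iplv(np.zeros(n), np.full(n, np.pi)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_null_scales_as_inverse_sqrt_t(self):
        rng = np.random.default_rng(0)
        t = 1000
        draws = rng.uniform(-np.pi, np.pi, size=(500, t))
        vals = np.abs(np.mean(np.exp(1j * draws), axis=1).imag)
        assert np.mean(vals < 0.08) >= 0.99

    def test_self_coupling_is_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(-np.pi, np.pi, 300)
        assert iplv(p, p) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iplv(np.zeros(10), np.zeros(11))

    @given(st.floats(-np.pi, np.pi), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_common_phase_offset(self, c, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-np.pi, np.pi, 200)
        b = rng.uniform(-np.pi, np.pi, 200)
        assert iplv(a + c, b + c) == pytest.approx(iplv(a, b), abs=1e-9)
        assert iplv(b, a) == pytest.approx(iplv(a, b), abs=1e-12)


class TestPacIplv:
    FS = 250.0
    THETA = DEFAULT_BANDS[1]

    def _phase(self, f, seconds):
        t = np.arange(int(seconds * self.FS)) / self.FS
        return 2 * np.pi * f * t

    def test_quarter_cycle_modulation_detected(self):
        phi = self._phase(6.0, 8)
        env = 1 + np.cos(phi - np.pi / 2)
        val = pac_iplv(np.angle(np.exp(1j * phi)), env, self.THETA, self.FS)
        assert val > 0.8

    def test_zero_lag_modulation_invisible(self):
        phi = self._phase(6.0, 8)
        env = 1 + np.cos(phi)
        val = pac_iplv(np.angle(np.exp(1j * phi)), env, self.THETA, self.FS)
        assert val < 0.1

    def test_independent_envelope_below_coupled_value(self):
        rng = np.random.default_rng(3)
        phi = self._phase(6.0, 8)
        env = 1 + 0.5 * rng.normal(size=phi.size)
        val = pac_iplv(np.angle(np.exp(1j * phi)), env, self.THETA, self.FS)
        coupled = pac_iplv(np.angle(np.exp(1j * phi)),
                           1 + np.cos(phi - np.pi / 2), self.THETA, self.FS)
        assert val < 0.5 * coupled

    def test_flat_envelope_warns_and_returns_zero(self):
        phi = self._phase(6.0, 4)
        with pytest.warns(UserWarning):
            val = pac_iplv(phi, np.ones_like(phi), self.THETA, self.FS)
        assert val == 0.0


class TestModeVectorAndNull:
    def test_vector_length_and_planted_argmax(self, theta_pair_recording):
        _, _, _, bs = theta_pair_recording
        ctx = CouplingContext(bs)
        grid = bs.window_grid(1.0, 1.0)
        w = (int(grid.starts[2]), grid.width_samples)
        v = mode_iplv_vector(bs, 0, 1, w, ctx=ctx)
        assert v.shape == (36,)
        assert (v >= 0).all() and (v <= 1).all()
        assert v.argmax() + 1 == mode_index(1, 1)
        v_pac = mode_iplv_vector(bs, 2, 3, w, ctx=ctx)
        assert v_pac.argmax() + 1 == mode_index(1, 6)

    def test_surrogate_null_deterministic_and_planted_p_minimal(
            self, theta_pair_recording):
        _, _, _, bs = theta_pair_recording
        ctx = CouplingContext(bs)
        grid = bs.window_grid(1.0, 1.0)
        w = (int(grid.starts[1]), grid.width_samples)
        null1 = surrogate_null_for_pair(bs, 0, 1, w, n_surrogates=49,
                                        seed=7, ctx=ctx)
        null2 = surrogate_null_for_pair(bs, 0, 1, w, n_surrogates=49,
                                        seed=7, ctx=ctx)
        assert np.array_equal(null1.p_values, null2.p_values)
        assert (null1.p_values > 0).all() and (null1.p_values <= 1).all()
        m = mode_index(1, 1)
        # the locked mode attains the minimal achievable p
        assert null1.p_values[m - 1] == pytest.approx(
            1 / (null1.n_surrogates + 1))

    def test_too_few_surrogates_rejected(self, theta_pair_recording):
        _, _, _, bs = theta_pair_recording
        grid = bs.window_grid(1.0, 1.0)
        w = (int(grid.starts[0]), grid.width_samples)
        with pytest.raises(ValueError):
            surrogate_null_for_pair(bs, 0, 1, w, n_surrogates=5)


class TestMaxStatisticConvention:
    def test_all_null_equal_observed_gives_p_one(self):
        from dfcstates.coupling import _mode_pvalues
        obs = np.full(36, 0.5)
        null = np.full((49, 36), 0.5)
        assert np.all(_mode_pvalues(obs, null) == 1.0)

    def test_observed_above_all_null_gives_minimal_p(self):
        from dfcstates.coupling import _mode_pvalues
        rng = np.random.default_rng(0)
        null = rng.uniform(0, 0.5, (99, 36))
        obs = np.full(36, 0.9)
        assert np.all(_mode_pvalues(obs, null) == 1 / 100)


class TestDominantMode:
    def _null(self, p):
        return SurrogateNull(n_surrogates=99, null=np.zeros((99, 36)),
                             p_values=np.asarray(p), seed=0)

    def test_no_significant_mode_gives_zero(self):
        v = np.random.default_rng(0).uniform(0, 1, 36)
        mode, s = dominant_mode(v, self._null(np.ones(36)))
        assert (mode, s) == (0, 0.0)

    def test_single_significant_mode_wins(self):
        v = np.zeros(36)
        v[4] = 0.6
        p = np.ones(36)
        p[4] = 0.01
        assert dominant_mode(v, self._null(p)) == (5, 0.6)

    def test_strongest_significant_wins_and_ties_go_low(self):
        v = np.zeros(36)
        v[2], v[10] = 0.4, 0.6
        p = np.ones(36)
        p[2] = p[10] = 0.01
        assert dominant_mode(v, self._null(p)) == (11, 0.6)
        v[2] = 0.6  # exact tie -> lower index
        assert dominant_mode(v, self._null(p)) == (3, 0.6)


class TestBuildDfcg:
    def test_shapes_symmetry_and_mode_strength_consistency(
            self, theta_pair_recording):
        _, _, _, bs = theta_pair_recording
        grid = bs.window_grid(1.0, 1.0)
        snaps = build_dfcg(bs, grid, n_surrogates=19, seed=3)
        assert len(snaps) == len(grid)
        for s in snaps[:3]:
            assert s.strength.shape == (4, 4)
            assert np.array_equal(s.strength, s.strength.T)
            assert np.array_equal(s.mode, s.mode.T)
            assert (np.diag(s.strength) == 0).all()
            assert ((s.mode == 0) <= (s.strength == 0)).all()

    def test_planted_pairs_dominate_uncoupled_pairs_stay_empty(
            self, theta_pair_recording):
        _, _, _, bs = theta_pair_recording
        grid = bs.window_grid(1.0, 1.0)
        snaps = build_dfcg(bs, grid, n_surrogates=49, seed=3)
        modes = np.stack([s.mode for s in snaps])
        assert np.mean(modes[:, 0, 1] == mode_index(1, 1)) >= 0.8
        assert np.mean(modes[:, 2, 3] == mode_index(1, 6)) >= 0.8
        uncoupled = [(0, 2), (0, 3), (1, 2), (1, 3)]
        fp = np.mean([np.mean(modes[:, i, j] != 0) for i, j in uncoupled])
        assert fp <= 0.15

    @pytest.mark.parametrize("step", [1.0, 0.25])
    def test_streaming_equivalence_bit_for_bit(self, theta_pair_recording,
                                               step):
        """One window at a time equals the batch run exactly, for disjoint
        and overlapping window grids alike."""
        _, _, _, bs = theta_pair_recording
        grid = bs.window_grid(1.0, step)
        batch = build_dfcg(bs, grid, n_surrogates=19, seed=5)
        ctx = CouplingContext(bs)
        for w in (0, 3, len(grid) - 1):
            single = build_dfcg(bs, grid.subset([w]), n_surrogates=19,
                                seed=5, ctx=ctx)[0]
            assert np.array_equal(single.strength, batch[w].strength)
            assert np.array_equal(single.mode, batch[w].mode)


class TestComodulogram:
    def _snap(self, mode_matrix):
        m = np.asarray(mode_matrix)
        return CouplingSnapshot(0, (m > 0).astype(float), m)

    def test_single_mode_concentrates(self):
        m = np.zeros((3, 3), dtype=int)
        m[0, 1] = m[1, 0] = 3  # alpha1 intra
        com = comodulogram([self._snap(m)])
        assert com[2, 2] == 1.0 and com.sum() == pytest.approx(1.0)

    def test_uniform_modes_match_combinatorial_share(self):
        rng = np.random.default_rng(0)
        n = 40
        snaps = []
        for w in range(120):
            m = np.zeros((n, n), dtype=int)
            iu, ju = np.triu_indices(n, k=1)
            draw = rng.integers(1, 37, iu.size)
            m[iu, ju] = draw
            m[ju, iu] = draw
            snaps.append(self._snap(m))
        com = comodulogram(snaps)
        # every mode lands in one matrix cell; each should be ~1/36
        occupied = com[com > 0]
        assert occupied.size == 36
        assert np.allclose(occupied, 1 / 36, atol=0.01)
        assert com.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_modes_rejected(self):
        with pytest.raises(ValueError):
            comodulogram([self._snap(np.zeros((3, 3), dtype=int))])

    def test_cross_modes_fill_lower_triangle(self):
        m = np.zeros((3, 3), dtype=int)
        m[0, 1] = m[1, 0] = mode_index(1, 6)  # theta -> gamma1
        com = comodulogram([self._snap(m)])
        assert com[6, 1] == 1.0  # row = high band, col = low band
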