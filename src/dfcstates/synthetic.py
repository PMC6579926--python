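"""Coupled-oscillator surrogate recordings with known ground truth.

Each ROI can carry one narrowband oscillator per frequency band: a
frequency-modulated carrier whose instantaneous frequency wobbles inside
the band (smoothed Gaussian modulation).  Band carriers are spread across
ROIs — regional peak frequencies differ in real rhythms — and by default
an oscillator is expressed only where the state repertoire engages it,
over a weak broadband background.  A hidden Markov schedule switches the
active network state once per fixed-width segment; each state specifies a
set of pairwise couplings:

* intra-frequency couplings share a latent phase process between ROIs with a
  constant phase offset (the lag, default pi/2 where the imaginary PLV is
  maximal; zero-lag coupling is invisible to iPLV by construction).
  Couplings targeting the same band form a forest per state whose members
  all inherit the root oscillator's phase with accumulated lags; partial
  strength s mixes the shared and private oscillators with amplitude
  weights (s, sqrt(1 - s^2)).
* cross-frequency couplings modulate the high-band amplitude of the target
  ROI by the low-band phase of the source ROI,
  A_high(t) = (1 + s cos(phi_low - lag)) / sqrt(1 + s^2/2).

White Gaussian noise is added in the broadband domain at a configurable SNR
defined on each ROI's total signal variance.  The returned ground-truth
record exposes the schedule, the per-state expected adjacency (what an
ideal coupling detector would see) and its OMST-filtered Laplacian
eigen-profile, so every downstream stage can be validated against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import graphs
from .coupling import mode_bands, mode_is_cross, N_MODES
from .spectral import BandDefinition, DEFAULT_BANDS

__all__ = [
    "Coupling",
    "StateSpec",
    "SimulationConfig",
    "GroupSpec",
    "GroundTruth",
    "Subject",
    "generate_state_schedule",
    "generate_roi_signals",
    "generate_group_dataset",
    "DEFAULT_CARRIERS",
]

#: One carrier per band, placed away from the band edges.
DEFAULT_CARRIERS: dict[str, float] = {
    "delta": 2.5, "theta": 6.0, "alpha1": 9.0, "alpha2": 11.5,
    "beta1": 16.5, "beta2": 25.0, "gamma1": 40.0, "gamma2": 70.0,
}


@dataclass(frozen=True)
class Coupling:
    """One pairwise coupling: ROI i drives ROI j in coupling mode `mode`."""

    roi_i: int
    roi_j: int
    mode: int
    lag: float = np.pi / 2
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.roi_i == self.roi_j:
            raise ValueError("coupled ROIs must differ")
        if not 1 <= self.mode <= N_MODES:
            raise ValueError(f"mode must be in 1..{N_MODES}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")


@dataclass(frozen=True)
class StateSpec:
    """A network state: the couplings active while the state holds."""

    state_id: int
    couplings: tuple[Coupling, ...]

    def __post_init__(self) -> None:
        if self.state_id < 1:
            raise ValueError("state_id must be >= 1")
        object.__setattr__(self, "couplings", tuple(self.couplings))


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale generator configuration.

    Defaults: 10 ROIs at 250 Hz for 60 s, 20 dB SNR, one-second state
    segments and 0.2 Hz oscillator linewidth; `snr_db=None` disables noise.
    """

    n_rois: int = 10
    fs: float = 250.0
    duration: float = 60.0
    snr_db: float | None = 20.0
    band_carriers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIERS))
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    segment_width: float = 1.0
    freq_dev_hz: float = 0.4
    freq_mod_hz: float = 2.0
    carrier_spread: float = 0.3
    background_db: float = -30.0
    active_bands: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        high = max(b.high for b in self.bands)
        if self.fs <= 2 * high:
            raise ValueError(f"fs={self.fs} must exceed twice the highest "
                             f"band edge {high}")
        if self.duration < self.segment_width:
            raise ValueError("duration shorter than one segment")
        for b in self.bands:
            f = self.band_carriers.get(b.name)
            if f is None:
                raise ValueError(f"no carrier for band {b.name!r}")
            if not (b.low <= f <= b.high):
                raise ValueError(
                    f"carrier {f} Hz outside band {b.name!r} "
                    f"({b.low}-{b.high} Hz)")
        if self.active_bands not in ("auto", "all"):
            raise ValueError("active_bands must be 'auto' or 'all'")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_width * self.fs))

    @property
    def n_segments(self) -> int:
        return self.n_samples // self.segment_samples


def _validate_transition_matrix(tp: np.ndarray) -> np.ndarray:
    tp = np.asarray(tp, dtype=float)
    if tp.ndim != 2 or tp.shape[0] != tp.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(tp < 0):
        raise ValueError("transition probabilities must be non-negative")
    if np.any(np.abs(tp.sum(axis=1) - 1) > 1e-12):
        raise ValueError("transition-matrix rows must sum to 1 (+-1e-12)")
    return tp


def generate_state_schedule(schedule_tp, n_windows: int, start_state: int = 1,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None
                            ) -> np.ndarray:
    """Sample a Markov state sequence of length `n_windows` over states 1..k."""
    tp = _validate_transition_matrix(schedule_tp)
    k = tp.shape[0]
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if not 1 <= start_state <= k:
        raise ValueError(f"start_state must be in 1..{k}")
    if rng is None:
        rng = np.random.default_rng(seed)
    cum = tp.cumsum(axis=1)
    seq = np.empty(n_windows, dtype=int)
    seq[0] = start_state
    for t in range(1, n_windows):
        u = rng.random()
        seq[t] = int(np.searchsorted(cum[seq[t - 1] - 1], u,
                                     side="right")) + 1
    return seq


def _band_index(bands: Sequence[BandDefinition], idx: int) -> int:
    return idx


def _intra_forest(couplings: list[Coupling], n_rois: int
                  ) -> dict[int, tuple[int, float, float]]:
    """Resolve a band's intra couplings into {target: (root, offset, s)}.

    Each ROI may be the target of at most one coupling per band and state;
    lags accumulate along chains so every member holds the root's phase
    minus its accumulated offset.  Cycles are rejected.
    """
    incoming: dict[int, Coupling] = {}
    for c in couplings:
        if c.roi_j in incoming:
            raise ValueError(
                f"ROI {c.roi_j} is the target of two couplings in the same "
                f"band and state")
        incoming[c.roi_j] = c
    resolved: dict[int, tuple[int, float, float]] = {}
    for target in incoming:
        node, offset, hops = target, 0.0, 0
        while node in incoming:
            edge = incoming[node]
            offset += edge.lag
            node = edge.roi_i
            hops += 1
            if hops > n_rois:
                raise ValueError("cyclic intra-frequency coupling chain")
        resolved[target] = (node, offset, incoming[target].strength)
    return resolved


@dataclass
class GroundTruth:
    """What the generator actually realized: the key to every later stage."""

    schedule: np.ndarray
    segment_samples: int
    states: dict[int, StateSpec]
    config: SimulationConfig
    carriers: np.ndarray | None = None  # (n_rois, n_bands) realized Hz

    def window_state(self, start_sample: int, width_samples: int) -> int:
        """State occupying the majority of a window's samples."""
        seg = self.segment_samples
        first = start_sample // seg
        last = (start_sample + width_samples - 1) // seg
        best, best_overlap = -1, -1
        for s in range(first, last + 1):
            if not 0 <= s < self.schedule.size:
                continue
            lo = max(start_sample, s * seg)
            hi = min(start_sample + width_samples, (s + 1) * seg)
            if hi - lo > best_overlap:
                best_overlap, best = hi - lo, int(self.schedule[s])
        return best

    def window_states(self, starts, width_samples: int) -> np.ndarray:
        return np.array([self.window_state(int(s), width_samples)
                         for s in np.asarray(starts)])

    def expected_adjacency(self, state_id: int) -> np.ndarray:
        """Pairwise iPLV an ideal detector would report for a state.

        Within every intra-frequency phase cluster, members p and q with
        accumulated offsets o_p, o_q and mixing strengths s_p, s_q couple at
        s_p * s_q * |sin(o_p - o_q)|; a PAC coupling contributes
        s * |sin(lag)|.  Per pair, the strongest mode wins.
        """
        n = self.config.n_rois
        adj = np.zeros((n, n))
        spec = self.states[state_id]
        by_band: dict[int, list[Coupling]] = {}
        for c in spec.couplings:
            lo, hi = mode_bands(c.mode)
            if mode_is_cross(c.mode):
                w = c.strength * abs(np.sin(c.lag))
                i, j = c.roi_i, c.roi_j
                adj[i, j] = adj[j, i] = max(adj[i, j], w)
            else:
                by_band.setdefault(lo, []).append(c)
        for band, couplings in by_band.items():
            resolved = _intra_forest(couplings, n)
            clusters: dict[int, list[tuple[int, float, float]]] = {}
            for target, (root, offset, s) in resolved.items():
                clusters.setdefault(root, []).append((target, offset, s))
            for root, members in clusters.items():
                nodes = [(root, 0.0, 1.0)] + members
                for a in range(len(nodes)):
                    for b in range(a + 1, len(nodes)):
                        p, op, sp = nodes[a]
                        q, oq, sq = nodes[b]
                        w = sp * sq * abs(np.sin(op - oq))
                        adj[p, q] = adj[q, p] = max(adj[p, q], w)
        return adj

    def expected_eigen_profile(self, state_id: int) -> np.ndarray:
        """OMST-filtered L_sym spectrum of the state's expected adjacency."""
        adj = self.expected_adjacency(state_id)
        if adj.max() == 0:
            return np.zeros(self.config.n_rois)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", graphs.DisconnectedGraphWarning)
            filt = graphs.omst_filter(adj)
        return graphs.normalized_laplacian_eigenvalues(filt.adjacency)


def generate_roi_signals(config: SimulationConfig,
                         state_specs: Sequence[StateSpec],
                         state_schedule,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, GroundTruth]:
    """Render broadband ROI signals realizing the scheduled couplings.

    Returns `(signals, ground_truth)` with signals shaped
    (n_rois, n_samples).  The schedule must hold one state id per
    `segment_width` segment of the configured duration.
    """
    schedule = np.asarray(state_schedule, dtype=int)
    states = {s.state_id: s for s in state_specs}
    if len(states) != len(state_specs):
        raise ValueError("duplicate state ids")
    unknown = set(schedule.tolist()) - set(states)
    if unknown:
        raise ValueError(f"schedule references unknown states {unknown}")
    if schedule.size != config.n_segments:
        raise ValueError(
            f"schedule length {schedule.size} != {config.n_segments} "
            f"segments of {config.segment_width} s in {config.duration} s")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, fs = config.n_rois, config.fs
    n_bands = len(config.bands)
    t_total = config.n_segments * config.segment_samples
    t = np.arange(t_total) / fs

    # Latent oscillator phases: frequency-modulated carriers.  Regional
    # peak frequencies differ in real rhythms, so each band's carriers are
    # spread deterministically over the central `2*carrier_spread` fraction
    # of the band (assignment to ROIs permuted at random): every pair of
    # independent same-band oscillators then carries a guaranteed frequency
    # offset whose rotation strictly bounds its windowed phase coherence
    # below that of a truly phase-locked pair.  Each carrier additionally
    # wobbles as a smoothed Gaussian frequency modulation, decorrelating
    # phases within a fraction of a second while keeping the line
    # concentrated near the carrier.  A pure tone would instead stay
    # spuriously phase-locked to any time-shifted copy of itself.
    from scipy.signal import butter, sosfiltfilt
    sos_mod = butter(2, config.freq_mod_hz, btype="lowpass", fs=fs,
                     output="sos")
    phases = np.empty((n, n_bands, t_total))
    carriers = np.empty((n, n_bands))
    for b, band in enumerate(config.bands):
        center = config.band_carriers[band.name]
        bw = band.high - band.low
        half_span = config.carrier_spread * bw
        lo = max(band.low + 0.05 * bw, center - half_span)
        hi = min(band.high - 0.05 * bw, center + half_span)
        grid = np.linspace(lo, hi, n) if n > 1 else np.array([center])
        f_roi = grid[rng.permutation(n)][:, None]
        carriers[:, b] = f_roi[:, 0]
        wobble = sosfiltfilt(sos_mod,
                             rng.normal(0.0, 1.0, size=(n, t_total)),
                             axis=-1)
        wobble /= np.maximum(wobble.std(axis=-1, keepdims=True), 1e-12)
        f_inst = f_roi + config.freq_dev_hz * wobble
        theta0 = rng.uniform(-np.pi, np.pi, size=(n, 1))
        phases[:, b, :] = (2 * np.pi * np.cumsum(f_inst, axis=-1) / fs
                           + theta0)

    band_signals = np.cos(phases)  # modified segment by segment below
    seg = config.segment_samples
    pac_norm = lambda s: np.sqrt(1 + s ** 2 / 2)
    for w, state_id in enumerate(schedule):
        spec = states[int(state_id)]
        sl = slice(w * seg, (w + 1) * seg)
        intra_by_band: dict[int, list[Coupling]] = {}
        cross: list[Coupling] = []
        for c in spec.couplings:
            if mode_is_cross(c.mode):
                cross.append(c)
            else:
                intra_by_band.setdefault(mode_bands(c.mode)[0], []).append(c)
        # Effective phase per (roi, band): shared root phase for coupled
        # members, latent otherwise; PAC modulators read from this map.
        eff_offset: dict[tuple[int, int], tuple[int, float]] = {}
        for band, couplings in intra_by_band.items():
            resolved = _intra_forest(couplings, n)
            for target, (root, offset, s) in resolved.items():
                shared = np.cos(phases[root, band, sl] - offset)
                own = np.cos(phases[target, band, sl])
                band_signals[target, band, sl] = (
                    np.sqrt(1 - s ** 2) * own + s * shared)
                eff_offset[(target, band)] = (root, offset)
        for c in cross:
            lo, hi = mode_bands(c.mode)
            root, offset = eff_offset.get((c.roi_i, lo), (c.roi_i, 0.0))
            phi_low = phases[root, lo, sl] - offset
            mod = (1 + c.strength * np.cos(phi_low - c.lag)) \
                / pac_norm(c.strength)
            band_signals[c.roi_j, hi, sl] = \
                band_signals[c.roi_j, hi, sl] * mod
    # Oscillators are expressed where the state repertoire engages them
    # ("auto"): a rhythm a region never couples through is not simulated as
    # a sustained narrowband tone but left to the broadband background,
    # mirroring region-specific spectral peaks in real recordings.
    if config.active_bands == "auto":
        active = np.zeros((n, n_bands), dtype=bool)
        for spec in states.values():
            for c in spec.couplings:
                lo, hi = mode_bands(c.mode)
                active[c.roi_i, lo] = True
                active[c.roi_j, hi] = True
    else:
        active = np.ones((n, n_bands), dtype=bool)
    band_signals *= active[:, :, None]
    signals = band_signals.sum(axis=1)
    # Broadband background activity (always present): keeps every band's
    # analytic phase defined and carries no pairwise coupling.
    bg_sd = np.sqrt(0.5 * 10 ** (config.background_db / 10))
    signals = signals + rng.normal(0.0, bg_sd, signals.shape)
    if config.snr_db is not None and np.isfinite(config.snr_db):
        noise_sd = np.sqrt(signals.var(axis=1, keepdims=True)
                           / 10 ** (config.snr_db / 10))
        signals = signals + rng.normal(0.0, 1.0, signals.shape) * noise_sd
    truth = GroundTruth(schedule=schedule.copy(),
                        segment_samples=config.segment_samples,
                        states=states, config=config, carriers=carriers)
    return signals, truth


@dataclass(frozen=True)
class GroupSpec:
    """A group's state repertoire and Markov schedule dynamics."""

    name: str
    states: tuple[StateSpec, ...]
    schedule_tp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "schedule_tp",
                           _validate_transition_matrix(self.schedule_tp))
        if len(self.states) != self.schedule_tp.shape[0]:
            raise ValueError("one transition-matrix row per state required")


@dataclass
class Subject:
    """One simulated recording with its label and ground truth."""

    subject_id: str
    label: str
    signals: np.ndarray
    fs: float
    ground_truth: GroundTruth
    seed: int


def _repertoire_key(spec: GroupSpec) -> tuple:
    return tuple(sorted((s.state_id, s.couplings) for s in spec.states))


def generate_group_dataset(group_a_spec: GroupSpec, group_b_spec: GroupSpec,
                           n_subjects_each: int, seed: int = 0,
                           config: SimulationConfig | None = None
                           ) -> list[Subject]:
    """Simulate two labeled groups of subjects, reproducibly.

    Per-subject seeds derive from the master seed; identical arguments give
    bit-identical datasets.  The two groups must have distinguishable state
    repertoires.
    """
    if n_subjects_each < 1:
        raise ValueError("n_subjects_each must be >= 1")
    if _repertoire_key(group_a_spec) == _repertoire_key(group_b_spec):
        raise ValueError("group state repertoires are indistinguishable")
    if config is None:
        config = SimulationConfig()
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2 ** 31, size=2 * n_subjects_each)
    subjects: list[Subject] = []
    idx = 0
    for spec in (group_a_spec, group_b_spec):
        k = len(spec.states)
        # schedule positions 1..k are mapped to the group's declared state
        # ids, so repertoires need not use ids 1..k
        id_by_pos = {pos + 1: s.state_id for pos, s in enumerate(spec.states)}
        for s in range(n_subjects_each):
            sub_seed = int(subject_seeds[idx])
            idx += 1
            rng = np.random.default_rng(sub_seed)
            start = int(rng.integers(1, k + 1))
            positions = generate_state_schedule(
                spec.schedule_tp, config.n_segments, start, rng=rng)
            schedule = np.array([id_by_pos[p] for p in positions])
            signals, truth = generate_roi_signals(config, spec.states,
                                                  schedule, rng=rng)
            subjects.append(Subject(
                subject_id=f"{spec.name}{s + 1:02d}", label=spec.name,
                signals=signals, fs=config.fs, ground_truth=truth,
                seed=sub_seed))
    return subjects
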