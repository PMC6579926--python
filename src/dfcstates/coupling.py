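"""Time-resolved coupling estimation and dominant-mode selection.

Every ROI pair is probed, window by window, for 36 potential intrinsic
coupling modes: 8 intra-frequency phase-to-phase couplings (one per band) and
28 phase-to-amplitude cross-frequency couplings (one per unordered band
pair, lower band as phase modulator).  The estimator throughout is the
imaginary part of the phase-locking value,

    iPLV = | Im( (1/T) sum_t exp(i (phi_a(t) - phi_b(t))) ) |,

which is blind to zero-lag coupling by construction and therefore robust to
instantaneous field-spread effects.  A circular-shift surrogate null with
max-statistic correction across the 36 modes yields, per pair and window, a
single Dominant Intrinsic Coupling Mode (DICM) or the no-coupling label 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert, sosfiltfilt

from .spectral import (BandDefinition, BandSignals, WindowGrid, _design_sos)

__all__ = [
    "N_MODES",
    "N_INTRA_MODES",
    "N_CROSS_MODES",
    "mode_index",
    "mode_bands",
    "mode_is_cross",
    "CouplingSnapshot",
    "SurrogateNull",
    "CouplingContext",
    "iplv",
    "pac_iplv",
    "mode_iplv_vector",
    "surrogate_null_for_pair",
    "dominant_mode",
    "build_dfcg",
    "comodulogram",
]

N_BANDS = 8
N_INTRA_MODES = N_BANDS
_CROSS_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(N_BANDS) for j in range(i + 1, N_BANDS))
N_CROSS_MODES = len(_CROSS_PAIRS)
N_MODES = N_INTRA_MODES + N_CROSS_MODES  # 8 + 28 = 36

# mode index -> (low band, high band), 0-based band indices; entry 0 unused.
_MODE_BANDS: tuple[tuple[int, int], ...] = (
    (-1, -1),
    *((b, b) for b in range(N_BANDS)),
    *_CROSS_PAIRS,
)
_CROSS_OFFSET = N_INTRA_MODES + 1  # first cross mode index


def mode_index(low_band: int, high_band: int) -> int:
    """Mode index (1-36) of a band pair; equal bands give intra modes 1-8."""
    if not (0 <= low_band < N_BANDS and 0 <= high_band < N_BANDS):
        raise ValueError("band indices must be in 0..7")
    if low_band == high_band:
        return low_band + 1
    lo, hi = sorted((low_band, high_band))
    return _CROSS_OFFSET + _CROSS_PAIRS.index((lo, hi))


def mode_bands(index: int) -> tuple[int, int]:
    """(low band, high band) 0-based indices of mode `index` (1-36)."""
    if not 1 <= index <= N_MODES:
        raise ValueError(f"mode index {index} outside 1..{N_MODES}")
    return _MODE_BANDS[index]


def mode_is_cross(index: int) -> bool:
    lo, hi = mode_bands(index)
    return lo != hi


def iplv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Imaginary phase-locking value of two equal-length phase windows."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase windows must have identical shape")
    if phase_a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b))).imag))


def pac_iplv(phase_low_a: np.ndarray, amplitude_high_b: np.ndarray,
             low_band: BandDefinition, fs: float, order: int = 4) -> float:
    """Phase-to-amplitude coupling strength between two series.

    The high-band amplitude envelope of the second series is band-passed
    within `low_band`, its analytic phase extracted, and the iPLV against the
    first series' low-band phase returned.  A modulation envelope with no
    variance inside `low_band` carries no phase: the function warns and
    returns 0.
    """
    amplitude_high_b = np.asarray(amplitude_high_b, dtype=float)
    sos = _design_sos(low_band, fs, order)
    env = sosfiltfilt(sos, amplitude_high_b)
    if np.max(np.abs(env)) < 1e-12 * max(np.max(np.abs(amplitude_high_b)),
                                         1e-300):
        warnings.warn("amplitude envelope has no variance inside the "
                      "modulating band; PAC undefined, returning 0")
        return 0.0
    env_phase = np.angle(hilbert(env))
    return iplv(np.asarray(phase_low_a, dtype=float), env_phase)


@dataclass
class CouplingSnapshot:
    """One window of the integrated dynamic functional connectivity graph.

    `strength` holds the dominant-mode iPLV per ROI pair (symmetric, zero
    diagonal); `mode` the corresponding mode index, with 0 marking pairs
    without a surrogate-significant coupling (strength 0 there).
    """

    window_id: int
    strength: np.ndarray
    mode: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.mode == 0) & (self.strength != 0)):
            raise ValueError("strength must be 0 wherever mode is 0")


@dataclass
class SurrogateNull:
    """Circular-shift surrogate null for one ROI pair and window.

    `null` has one row per surrogate and one column per mode; `null_max` is
    the per-surrogate maximum across modes (the max-statistic controlling
    the family-wise error over the 36 modes) and `p_values[m] =
    (r_m + 1)/(n_surrogates + 1)` where r_m counts surrogates whose
    max-statistic is >= the observed value of mode m.
    """

    n_surrogates: int
    null: np.ndarray
    p_values: np.ndarray
    seed: int

    @property
    def null_max(self) -> np.ndarray:
        return self.null.max(axis=1)


class CouplingContext:
    """Precomputed unit phasors for all 36 mode ingredients of a recording.

    For every ROI: 8 band-phase phasors exp(i*phi_b) plus, for each of the 28
    band pairs, the phasor of the analytic phase of the high band's amplitude
    envelope band-passed inside the low band.  Computing these once per
    recording (rather than per window) keeps filter transients confined to
    the recording edges, which the edge margin already excludes.
    """

    def __init__(self, band_signals: BandSignals, order: int = 4):
        self.band_signals = band_signals
        n_rois, _, n = band_signals.phase.shape
        self.n_rois = n_rois
        self.n_samples = n
        self.margin = int(band_signals.edge_margin)
        # unit phasors stored as float32 cos/sin planes: the pairwise
        # statistic Im(e^{i phi_a} e^{-i phi_b}) = sin(phi_a - phi_b)
        # then needs only two multiplies per sample
        self.phase_cos = np.cos(band_signals.phase).astype(np.float32)
        self.phase_sin = np.sin(band_signals.phase).astype(np.float32)
        self.env_cos = np.empty((n_rois, N_CROSS_MODES, n), dtype=np.float32)
        self.env_sin = np.empty((n_rois, N_CROSS_MODES, n), dtype=np.float32)
        fs = band_signals.fs
        for c, (lo, hi) in enumerate(_CROSS_PAIRS):
            sos = _design_sos(band_signals.bands[lo], fs, order)
            env = sosfiltfilt(sos, band_signals.amplitude[:, hi, :], axis=-1)
            ph = np.angle(hilbert(env, axis=-1))
            self.env_cos[:, c, :] = np.cos(ph)
            self.env_sin[:, c, :] = np.sin(ph)


def _disjoint_sums(z_im: np.ndarray, starts: np.ndarray, width: int
                   ) -> np.ndarray:
    """Window sums for a non-overlapping, sorted window set (reduceat)."""
    bounds = np.column_stack([starts, starts + width]).ravel()
    trailing = bounds[-1] >= z_im.shape[-1]
    if trailing:  # reduceat forbids an index at the end of the axis;
        bounds = bounds[:-1]  # its tail sum is exactly the last window
    sums = np.add.reduceat(z_im, bounds, axis=-1, dtype=np.float64)
    if trailing:
        return np.concatenate([sums[..., :-1:2], sums[..., -1:]], axis=-1)
    return sums[..., ::2]


def _windowed_iplv(z_im: np.ndarray, starts: np.ndarray, width: int
                   ) -> np.ndarray:
    """|window mean| of the phasor imaginary part for every window.

    `z_im` holds sin(phi_a - phi_b) per shift row; accumulation runs in
    float64 so single-precision inputs lose no window-sum accuracy.
    Overlapping grids are partitioned into disjoint interleaved groups and
    every window is summed independently from zero, so the value of a
    window never depends on which other windows are evaluated with it
    (bit-for-bit streaming equivalence).
    """
    if starts.size == 0:
        return np.zeros(z_im.shape[:-1] + (0,))
    out = np.empty(z_im.shape[:-1] + (starts.size,))
    remaining = np.arange(starts.size)
    while remaining.size:
        prev_end = -1
        take, rest = [], []
        for idx in remaining:
            if starts[idx] >= prev_end:
                take.append(idx)
                prev_end = starts[idx] + width
            else:
                rest.append(idx)
        idxs = np.asarray(take)
        out[..., idxs] = _disjoint_sums(z_im, starts[idxs], width)
        remaining = np.asarray(rest, dtype=int)
    return np.abs(out) / width


def _pair_mode_values(ctx: CouplingContext, i: int, j: int,
                      starts: np.ndarray, width: int,
                      offsets: np.ndarray) -> np.ndarray:
    """iPLV of every mode for pair (i, j), all windows and circular shifts.

    Returns an array of shape (n_shifts, N_MODES, n_windows); row s uses ROI
    j's series circularly shifted by offsets[s] (offset 0 = observed).  Cross
    modes take the maximum over the two phase/amplitude direction
    assignments so a coupling planted in either direction is seen.
    """
    n = ctx.n_samples
    m = ctx.margin
    interior = n - 2 * m
    # The circular shift is confined to the margin-trimmed interior, so
    # surrogate windows never read filter-edge-contaminated samples; shifted
    # rows are strided views into a doubled interior (no index gather).
    rel = np.asarray(starts, dtype=int) - m
    if rel.size and (rel.min() < 0 or rel.max() + width > interior):
        raise ValueError("windows must lie inside the margin-trimmed region")
    rows = (interior - offsets) % interior
    out = np.empty((offsets.size, N_MODES, rel.size))

    def core(x):
        return x[m:n - m]

    def shifted(x):
        doubled = np.concatenate([core(x), core(x)])
        return np.lib.stride_tricks.sliding_window_view(doubled,
                                                        interior)[rows]

    def sin_diff(a_cos, a_sin, b_cos, b_sin):
        # sin(phi_a - phi_b), ROI j's series circularly shifted per row
        z = core(a_sin)[None, :] * shifted(b_cos)
        z -= core(a_cos)[None, :] * shifted(b_sin)
        return z

    for b in range(N_BANDS):
        z = sin_diff(ctx.phase_cos[i, b], ctx.phase_sin[i, b],
                     ctx.phase_cos[j, b], ctx.phase_sin[j, b])
        out[:, b, :] = _windowed_iplv(z, rel, width)
    for c, (lo, hi) in enumerate(_CROSS_PAIRS):
        z1 = sin_diff(ctx.phase_cos[i, lo], ctx.phase_sin[i, lo],
                      ctx.env_cos[j, c], ctx.env_sin[j, c])
        v1 = _windowed_iplv(z1, rel, width)
        # opposite direction: ROI j's low phase (shifted) against ROI i's
        # envelope phase; sin swaps sign, the magnitude is all that matters
        z2 = sin_diff(ctx.env_cos[i, c], ctx.env_sin[i, c],
                      ctx.phase_cos[j, lo], ctx.phase_sin[j, lo])
        v2 = _windowed_iplv(z2, rel, width)
        out[:, N_INTRA_MODES + c, :] = np.maximum(v1, v2)
    return out


def _pair_offsets(seed: int, i: int, j: int, n_surrogates: int,
                  interior_samples: int, width: int) -> np.ndarray:
    """Deterministic surrogate shift offsets for pair (i, j).

    Offsets apply circularly within the margin-trimmed interior; they are at
    least one window width and at most interior - width, so no surrogate
    realigns the pair; entry 0 is the unshifted observation.
    """
    lo, hi = width, interior_samples - width
    if hi < lo:
        raise ValueError("series too short for a valid circular shift")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, j]))
    offs = rng.integers(lo, hi + 1, size=n_surrogates)
    return np.concatenate([[0], offs])


def _mode_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Max-statistic p-values controlling the family-wise error over modes.

    Each surrogate contributes its maximum iPLV across the 36 modes;
    `observed` is (n_modes, ...) and `null` (n_surrogates, n_modes, ...);
    returns p of shape like `observed` with
    p_m = (r_m + 1)/(n_surrogates + 1), r_m counting surrogates whose
    max-statistic is >= mode m's observed value (equality counts toward r).
    """
    null_max = null.max(axis=1)
    r = (null_max[:, None] >= observed[None]).sum(axis=0)
    return (r + 1) / (null.shape[0] + 1)


def _seam_in_window(seams: np.ndarray, starts: np.ndarray, width: int
                    ) -> np.ndarray:
    """Mask of (shift, window) pairs whose window spans the circular seam.

    A circularly shifted series is discontinuous where the interior wraps;
    a surrogate value read from a window containing that seam mixes two
    unrelated stretches and is excluded from the null.
    """
    return (starts[None, :] < seams[:, None]) \
        & (seams[:, None] < starts[None, :] + width)


def mode_iplv_vector(band_signals: BandSignals, roi_i: int, roi_j: int,
                     window: tuple[int, int],
                     ctx: CouplingContext | None = None) -> np.ndarray:
    """Observed iPLV of all 36 modes for one ROI pair and window.

    `window` is (start_sample, width_samples).  Entries 0..7 are the intra
    band couplings delta..gamma2, entries 8..35 the cross-frequency pairs in
    fixed lexicographic order (index m corresponds to mode m+1).
    """
    if ctx is None:
        ctx = CouplingContext(band_signals)
    start, width = window
    if not (0 <= start and start + width <= ctx.n_samples):
        raise ValueError("window outside the series")
    vals = _pair_mode_values(ctx, roi_i, roi_j, np.array([start]), width,
                             np.array([0]))
    return vals[0, :, 0]


def surrogate_null_for_pair(band_signals: BandSignals, roi_i: int,
                            roi_j: int, window: tuple[int, int],
                            n_surrogates: int = 99, seed: int = 0,
                            ctx: CouplingContext | None = None
                            ) -> SurrogateNull:
    """Circular-shift surrogate null of all 36 modes for one pair/window."""
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    if ctx is None:
        ctx = CouplingContext(band_signals)
    start, width = window
    offsets = _pair_offsets(seed, roi_i, roi_j, n_surrogates,
                            ctx.n_samples - 2 * ctx.margin, width)
    vals = _pair_mode_values(ctx, roi_i, roi_j, np.array([start]), width,
                             offsets)[:, :, 0]
    observed, null = vals[0], vals[1:]
    valid = ~_seam_in_window(ctx.margin + offsets[1:], np.array([start]),
                             width)[:, 0]
    null = null[valid]
    p = _mode_pvalues(observed, null)
    return SurrogateNull(n_surrogates=int(valid.sum()), null=null,
                         p_values=p, seed=seed)


def dominant_mode(iplv_vector: np.ndarray, surrogate_null: SurrogateNull,
                  alpha: float = 0.05) -> tuple[int, float]:
    """Strongest surrogate-significant mode of a 36-vector, or (0, 0).

    Significance is `p <= alpha` after max-statistic control across modes;
    among significant modes the largest iPLV wins, exact ties going to the
    lower mode index.
    """
    v = np.asarray(iplv_vector, dtype=float)
    if v.shape != (N_MODES,):
        raise ValueError(f"expected a {N_MODES}-vector")
    sig = surrogate_null.p_values <= alpha
    if not sig.any():
        return 0, 0.0
    masked = np.where(sig, v, -np.inf)
    m = int(np.argmax(masked))  # argmax returns the first (lowest) index
    return m + 1, float(v[m])


def build_dfcg(band_signals: BandSignals, window_grid: WindowGrid,
               n_surrogates: int = 99, alpha: float = 0.05, seed: int = 0,
               ctx: CouplingContext | None = None
               ) -> list[CouplingSnapshot]:
    """Integrated dynamic functional connectivity graph, one snapshot/window.

    For every ROI pair the 36 mode strengths and their circular-shift
    surrogate null are evaluated on every window of `window_grid`; the
    dominant significant mode (max-statistic corrected, `p <= alpha`) fills
    the snapshot's strength/mode matrices, pairs without a significant mode
    getting mode 0 and strength 0.

    Computation streams pair by pair; every window is summed independently
    of the rest of the grid, so the result for any subset of the windows is
    bit-identical to the batch run, and the full 4-D
    [mode x window x ROI x ROI] tensor is never materialized.
    """
    if ctx is None:
        ctx = CouplingContext(band_signals)
    n_rois = ctx.n_rois
    starts = np.asarray(window_grid.starts, dtype=int)
    width = window_grid.width_samples
    if starts.size and (starts.min() < 0
                        or starts.max() + width > ctx.n_samples):
        raise ValueError("window grid extends outside the series")
    n_w = starts.size
    strength = np.zeros((n_w, n_rois, n_rois))
    mode = np.zeros((n_w, n_rois, n_rois), dtype=int)
    for i in range(n_rois):
        for j in range(i + 1, n_rois):
            offsets = _pair_offsets(seed, i, j, n_surrogates,
                                    ctx.n_samples - 2 * ctx.margin, width)
            vals = _pair_mode_values(ctx, i, j, starts, width, offsets)
            observed, null = vals[0], vals[1:]
            valid = ~_seam_in_window(ctx.margin + offsets[1:], starts,
                                     width)  # (n_surr, n_w)
            null_max = null.max(axis=1)
            r = ((null_max[:, None, :] >= observed[None, :, :])
                 & valid[:, None, :]).sum(axis=0)
            n_valid = valid.sum(axis=0)
            p = (r + 1) / (n_valid[None, :] + 1)
            masked = np.where(p <= alpha, observed, -np.inf)
            dom = masked.argmax(axis=0)
            dom_val = observed[dom, np.arange(n_w)]
            has_sig = np.isfinite(masked.max(axis=0))
            m_ij = np.where(has_sig, dom + 1, 0)
            s_ij = np.where(has_sig, dom_val, 0.0)
            strength[:, i, j] = strength[:, j, i] = s_ij
            mode[:, i, j] = mode[:, j, i] = m_ij
    return [CouplingSnapshot(window_id=w, strength=strength[w],
                             mode=mode[w]) for w in range(n_w)]


def comodulogram(snapshots: list[CouplingSnapshot]) -> np.ndarray:
    """Empirical 8x8 probability distribution of dominant coupling modes.

    Counts every (pair, window) with mode != 0 over the upper-triangle ROI
    pairs of all snapshots.  Intra-frequency modes fill the diagonal; cross
    modes (low, high) the lower triangle at [high, low] (phase-modulating
    band on the column axis).  Entries sum to 1.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    counts = np.zeros((N_BANDS, N_BANDS))
    n = snapshots[0].mode.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    for snap in snapshots:
        modes = snap.mode[iu, ju]
        for m in modes[modes > 0]:
            lo, hi = mode_bands(int(m))
            counts[hi, lo] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("all dominant modes are 0: distribution undefined")
    return counts / total
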