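"""Narrowband decomposition, analytic phase/amplitude and sliding-window grids.

Broadband ROI time series are split into eight canonical electrophysiological
rhythms (delta through high gamma) with zero-phase IIR band-pass filters, and
the analytic signal of every narrowband series provides the instantaneous
phase and amplitude that all coupling estimators downstream consume.  Phase
fidelity is the overriding concern here: forward-backward filtering removes
group delay, and a per-recording edge margin (one full cycle of the slowest
band) flags the stretch of samples at either end where Hilbert-transform edge
artifacts make the phase unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BandSignals",
    "WindowGrid",
    "bandpass_bank",
    "analytic_phase_amplitude",
    "sliding_windows",
    "edge_margin_samples",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges for {self.name!r}: "
                             f"({self.low}, {self.high})")


#: Canonical eight-band partition of 1-90 Hz used throughout the package.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta1", 13.0, 20.0),
    BandDefinition("beta2", 20.0, 30.0),
    BandDefinition("gamma1", 30.0, 49.0),
    BandDefinition("gamma2", 51.0, 90.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def _validate_bands(bands: Sequence[BandDefinition], fs: float) -> None:
    for b in bands:
        if b.high >= fs / 2:
            raise ValueError(
                f"band {b.name!r} upper edge {b.high} Hz is at or above the "
                f"Nyquist frequency {fs / 2} Hz")


def edge_margin_samples(bands: Sequence[BandDefinition], fs: float) -> int:
    """One full cycle of the slowest band's low edge, in samples.

    Samples inside this margin at either end of a recording carry filter and
    Hilbert edge artifacts; window grids are laid out on the trimmed interior.
    """
    low_min = min(b.low for b in bands)
    return int(np.ceil(fs / low_min))


def _design_sos(band: BandDefinition, fs: float, order: int) -> np.ndarray:
    return butter(order, [band.low, band.high], btype="bandpass",
                  fs=fs, output="sos")


def bandpass_bank(signal: np.ndarray, fs: float,
                  bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                  order: int = 4) -> np.ndarray:
    """Zero-phase band-pass filter `signal` into every band.

    Parameters
    ----------
    signal : array, shape (..., n_samples)
        Broadband series; the filter runs along the last axis.
    fs : float
        Sampling rate in Hz.
    bands : sequence of BandDefinition
    order : int
        Butterworth order of the one-directional filter; the effective order
        doubles because filtering runs forward and backward (no group delay).

    Returns
    -------
    array, shape (..., n_bands, n_samples)
    """
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    _validate_bands(bands, fs)
    out = np.empty(signal.shape[:-1] + (len(bands), signal.shape[-1]))
    for k, band in enumerate(bands):
        sos = _design_sos(band, fs, order)
        out[..., k, :] = sosfiltfilt(sos, signal, axis=-1)
    return out


def analytic_phase_amplitude(narrowband: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and amplitude via the analytic signal.

    Returns `(phase, amplitude)` with phase wrapped to (-pi, pi] and
    amplitude >= 0.  Raises on constant input, whose phase is undefined.
    """
    x = np.asarray(narrowband, dtype=float)
    if np.ptp(x, axis=-1).min() == 0:
        raise ValueError("constant input: instantaneous phase is undefined")
    z = hilbert(x, axis=-1)
    return np.angle(z), np.abs(z)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout over a sampled series.

    `starts` are window start indices in samples; every window spans
    `[start, start + width_samples)` and lies fully inside the series.
    """

    fs: float
    width: float
    step: float
    starts: np.ndarray
    width_samples: int

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def step_samples(self) -> int:
        return int(self.starts[1] - self.starts[0]) if len(self) > 1 \
            else int(np.floor(self.step * self.fs))

    def subset(self, index) -> "WindowGrid":
        """Grid restricted to a subset of windows (same geometry)."""
        return WindowGrid(self.fs, self.width, self.step,
                          np.atleast_1d(self.starts[index]).copy(),
                          self.width_samples)


def sliding_windows(n_samples: int, fs: float, width: float = 1.0,
                    step: float = 0.05, start: int = 0) -> WindowGrid:
    """Build the sliding-window grid: `width` s windows every `step` s.

    The number of windows is ``floor((n - start - width*fs)/(step*fs)) + 1``.
    Window widths use floor on ``width*fs``; start positions are
    ``floor(i * step * fs)`` so that a step that is not a whole number of
    samples (e.g. 50 ms at 250 Hz) still advances at the nominal rate on
    average and the closed-form count holds at any sampling rate.
    """
    if not (width >= step > 0):
        raise ValueError("require width >= step > 0")
    width_samples = int(np.floor(width * fs))
    step_fs = step * fs
    if step_fs < 1:
        raise ValueError("step shorter than one sample")
    usable = n_samples - start
    if width_samples > usable:
        raise ValueError(
            f"window of {width_samples} samples does not fit in "
            f"{usable} usable samples")
    count = int(np.floor((usable - width_samples) / step_fs + 1e-9)) + 1
    starts = start + np.floor(np.arange(count) * step_fs
                              + 1e-9).astype(int)
    return WindowGrid(fs, width, step, starts, width_samples)


@dataclass
class BandSignals:
    """Per-ROI, per-band narrowband series with analytic phase and amplitude.

    Arrays are shaped (n_rois, n_bands, n_samples).  `edge_margin` samples at
    either end are unreliable (filter/Hilbert edge artifacts); use
    :meth:`window_grid` for a grid confined to the trimmed interior.
    """

    narrowband: np.ndarray
    phase: np.ndarray
    amplitude: np.ndarray
    fs: float
    bands: tuple[BandDefinition, ...] = field(default=DEFAULT_BANDS)
    edge_margin: int = 0

    @property
    def n_rois(self) -> int:
        return self.narrowband.shape[0]

    @property
    def n_samples(self) -> int:
        return self.narrowband.shape[-1]

    @classmethod
    def from_broadband(cls, data: np.ndarray, fs: float,
                       bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                       order: int = 4) -> "BandSignals":
        """Decompose broadband ROI series (rows = ROIs) into band signals."""
        data = np.atleast_2d(np.asarray(data, dtype=float))
        nb = bandpass_bank(data, fs, bands, order=order)
        phase, amp = analytic_phase_amplitude(nb)
        return cls(narrowband=nb, phase=phase, amplitude=amp, fs=fs,
                   bands=tuple(bands),
                   edge_margin=edge_margin_samples(bands, fs))

    def window_grid(self, width: float = 1.0, step: float = 0.05
                    ) -> WindowGrid:
        """Sliding-window grid on the margin-trimmed interior of the series."""
        usable_end = self.n_samples - self.edge_margin
        grid = sliding_windows(usable_end, self.fs, width=width, step=step,
                               start=self.edge_margin)
        return grid
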