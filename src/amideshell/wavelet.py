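"""Continuous wavelet transform (Morlet-Gabor), spectrograms and
instantaneous-frequency extraction.

The mother wavelet is psi(t) = pi^(-1/4) exp(i w0 t) exp(-t^2 / (2 sigma^2)).
A dilated copy at scale s (time units) has effective frequency
nu = (w0 + sqrt(2 + w0^2)) / (4 pi s); at w0 = 2 pi the factor nu*s is 1.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from amideshell.spectra import C_CM_PER_FS

__all__ = [
    "WaveletParams",
    "Spectrogram",
    "InstFreqSeries",
    "morlet_gabor",
    "effective_frequency_factor",
    "scale_to_frequency",
    "frequency_to_scale",
    "planewave_frequency",
    "planewave_scale",
    "scales_for_band",
    "cwt",
    "cwt_direct",
    "instantaneous_frequency",
    "ridge_frequencies",
    "filter_jumps",
]


@dataclass
class WaveletParams:
    """Mother-wavelet parameters: plane-wave frequency w0 (rad per unit
    time) and Gaussian width sigma (unit time)."""

    omega0: float = 2.0 * np.pi
    sigma: float = 8.0

    def __post_init__(self) -> None:
        if self.omega0 <= 0 or self.sigma <= 0:
            raise ValueError("omega0 and sigma must be positive")


def morlet_gabor(t: np.ndarray | float, params: WaveletParams | None = None) -> np.ndarray:
    """Evaluate the mother wavelet at (dimensionless) time ``t``."""
    p = params or WaveletParams()
    t = np.asarray(t, dtype=float)
    return np.pi ** -0.25 * np.exp(1j * p.omega0 * t) * np.exp(-(t**2) / (2 * p.sigma**2))


def effective_frequency_factor(omega0: float = 2.0 * np.pi) -> float:
    """nu * s for the scaled wavelet: (w0 + sqrt(2 + w0^2)) / (4 pi)."""
    return (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi)


def scale_to_frequency(s: float | np.ndarray, params: WaveletParams | None = None,
                       time_unit_fs: float = 1.0) -> np.ndarray:
    """Convert scale(s) (in units of ``time_unit_fs`` fs) to cm^-1."""
    p = params or WaveletParams()
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scales must be positive")
    nu_per_fs = effective_frequency_factor(p.omega0) / (s * time_unit_fs)
    return nu_per_fs / C_CM_PER_FS


def frequency_to_scale(freq_cm: float | np.ndarray, params: WaveletParams | None = None,
                       time_unit_fs: float = 1.0) -> np.ndarray:
    """Inverse of :func:`scale_to_frequency`."""
    p = params or WaveletParams()
    freq_cm = np.asarray(freq_cm, dtype=float)
    if np.any(freq_cm <= 0):
        raise ValueError("frequencies must be positive")
    return effective_frequency_factor(p.omega0) / (freq_cm * C_CM_PER_FS * time_unit_fs)


def planewave_frequency(s: float | np.ndarray, params: WaveletParams | None = None) -> np.ndarray:
    """Ridge-scale to frequency (cm^-1) via the plane-wave relation
    nu = omega0 / (2 pi s); at omega0 = 2 pi this is exactly 1/s.

    The modulus-maximizing scale for a pure tone of frequency nu is
    s = omega0 / (2 pi nu), so this (not the wavelength relation of
    :func:`scale_to_frequency`, which differs by ~1.25% at omega0 = 2 pi)
    is the conversion used for instantaneous frequencies."""
    p = params or WaveletParams()
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scales must be positive")
    return p.omega0 / (2.0 * np.pi * s * C_CM_PER_FS)


def planewave_scale(freq_cm: float | np.ndarray, params: WaveletParams | None = None) -> np.ndarray:
    """Inverse of :func:`planewave_frequency` (scale in fs)."""
    p = params or WaveletParams()
    freq_cm = np.asarray(freq_cm, dtype=float)
    if np.any(freq_cm <= 0):
        raise ValueError("frequencies must be positive")
    return p.omega0 / (2.0 * np.pi * freq_cm * C_CM_PER_FS)


def scales_for_band(lo_cm: float, hi_cm: float, n: int = 512,
                    params: WaveletParams | None = None,
                    time_unit_fs: float = 1.0) -> np.ndarray:
    """Logarithmically spaced scales (ascending) covering [lo_cm, hi_cm]."""
    if not (0 < lo_cm < hi_cm):
        raise ValueError("need 0 < lo_cm < hi_cm")
    s_hi = planewave_scale(lo_cm, params) / time_unit_fs
    s_lo = planewave_scale(hi_cm, params) / time_unit_fs
    return np.geomspace(s_lo, s_hi, n)


@dataclass
class Spectrogram:
    """Time-frequency grid: W[i, j] is the transform at scale ``scales[i]``
    and time step j * dt_fs."""

    scales: np.ndarray
    W: np.ndarray
    dt: float
    params: WaveletParams

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.W.shape[0] != len(self.scales):
            raise ValueError("W row count must match number of scales")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.W) ** 2

    @property
    def frequencies(self) -> np.ndarray:
        """Ridge-convention frequencies (plane-wave relation) per scale."""
        return planewave_frequency(self.scales, self.params)

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.W.shape[1])


@dataclass
class InstFreqSeries:
    """Per-frame instantaneous frequency (cm^-1) with a validity flag."""

    frequency: np.ndarray
    valid: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.frequency.shape != self.valid.shape:
            raise ValueError("frequency and valid must share shape")

    def window_mean(self, start_fs: float, end_fs: float) -> float:
        t = self.dt * np.arange(len(self.frequency))
        m = (t >= start_fs - 1e-9) & (t < end_fs - 1e-9) & self.valid
        if not m.any():
            raise ValueError("no valid samples in window")
        return float(self.frequency[m].mean())


def _kernel(scale_samples: float, params: WaveletParams, truncate: float = 8.0) -> np.ndarray:
    """Sampled conjugate wavelet at one scale; support +-truncate*sigma*s."""
    half = int(np.ceil(truncate * params.sigma * scale_samples))
    k = np.arange(-half, half + 1)
    return np.conj(morlet_gabor(k / scale_samples, params))


def cwt(signal: np.ndarray, dt: float, scales: np.ndarray,
        params: WaveletParams | None = None, truncate: float = 8.0) -> Spectrogram:
    """Discrete CWT: W(n, s) = |s|^(-1/2) sum_n' f(n' dt) psi*((n'-n) dt / s).

    ``scales`` are in fs.  Scales below 2*dt (beyond Nyquist) are rejected.
    Evaluated by FFT convolution per scale; the Gaussian envelope is
    truncated at ``truncate`` * sigma * s, which is exact to double
    precision for the default 8 sigma.
    """
    p = params or WaveletParams()
    f = np.asarray(signal, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if np.any(scales < 2.0 * dt):
        raise ValueError(f"scales below Nyquist limit 2*dt = {2 * dt} fs")
    n = len(f)
    W = np.empty((len(scales), n), dtype=complex)
    for i, s in enumerate(scales):
        ker = _kernel(s / dt, p, truncate)
        # correlation with psi*((n'-n) dt/s): convolve with reversed kernel
        W[i] = fftconvolve(f, ker[::-1], mode="same") / np.sqrt(s)
    return Spectrogram(scales=scales, W=W, dt=dt, params=p)


def cwt_direct(signal: np.ndarray, dt: float, scales: np.ndarray,
               params: WaveletParams | None = None) -> Spectrogram:
    """O(n^2) literal evaluation of the discretized transform (oracle path)."""
    p = params or WaveletParams()
    f = np.asarray(signal, dtype=float)
    scales = np.asarray(scales, dtype=float)
    n = len(f)
    idx = np.arange(n)
    W = np.empty((len(scales), n), dtype=complex)
    for i, s in enumerate(scales):
        for j in range(n):
            t = (idx - j) * dt / s
            W[i, j] = np.sum(f * np.conj(morlet_gabor(t, p))) / np.sqrt(s)
    return Spectrogram(scales=scales, W=W, dt=dt, params=p)


def instantaneous_frequency(spec: Spectrogram) -> InstFreqSeries:
    """Per time step, the frequency whose scale maximizes |W|^2.

    Frames within one envelope half-width (sigma * s_max) of either edge
    are flagged lower-confidence (cone of influence)."""
    power = spec.power
    best = np.argmax(power, axis=0)
    freqs = spec.frequencies[best]
    n = power.shape[1]
    edge = int(np.ceil(spec.params.sigma * spec.scales[-1] / spec.dt))
    valid = np.ones(n, dtype=bool)
    valid[:edge] = False
    if edge > 0:
        valid[-edge:] = False
    return InstFreqSeries(frequency=freqs, valid=valid, dt=spec.dt,
                          meta={"edge_frames": edge})


def ridge_frequencies(signal: np.ndarray, dt: float, scales: np.ndarray,
                      params: WaveletParams | None = None,
                      truncate: float = 8.0) -> InstFreqSeries:
    """Memory-light ridge extraction: same result as
    ``instantaneous_frequency(cwt(...))`` without storing the full grid."""
    p = params or WaveletParams()
    f = np.asarray(signal, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if np.any(scales < 2.0 * dt):
        raise ValueError(f"scales below Nyquist limit 2*dt = {2 * dt} fs")
    n = len(f)
    best_power = np.full(n, -np.inf)
    best_scale = np.zeros(n, dtype=int)
    for i, s in enumerate(scales):
        ker = _kernel(s / dt, p, truncate)
        w = fftconvolve(f, ker[::-1], mode="same") / np.sqrt(s)
        pw = np.abs(w) ** 2
        upd = pw > best_power
        best_power[upd] = pw[upd]
        best_scale[upd] = i
    freqs = planewave_frequency(scales[best_scale], p)
    edge = int(np.ceil(p.sigma * scales[-1] / dt))
    valid = np.ones(n, dtype=bool)
    valid[:edge] = False
    if edge > 0:
        valid[-edge:] = False
    return InstFreqSeries(frequency=freqs, valid=valid, dt=dt,
                          meta={"edge_frames": edge})


def filter_jumps(series: InstFreqSeries, floor: float = 1500.0,
                 smooth_window: int = 25) -> InstFreqSeries:
    """Remove sub-``floor`` artifacts and smooth.

    Entries below ``floor`` are invalidated, gaps are linearly interpolated
    from the surviving samples, and a rolling median of ``smooth_window``
    frames is applied (window 1 = interpolation only)."""
    freq = series.frequency.copy()
    ok = freq >= floor
    if not ok.any():
        raise ValueError(f"all entries below the {floor} cm^-1 floor")
    idx = np.arange(len(freq))
    freq[~ok] = np.interp(idx[~ok], idx[ok], freq[ok])
    if smooth_window > 1:
        from scipy.ndimage import median_filter

        freq = median_filter(freq, size=smooth_window, mode="nearest")
    return InstFreqSeries(frequency=freq, valid=series.valid.copy(), dt=series.dt,
                          meta={**series.meta, "floor": floor, "smooth_window": smooth_window})
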