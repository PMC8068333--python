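"""Power and IR spectra from autocorrelation + Fourier transform.

The frequency axis is in cm^-1 with spacing 1/(c * pad_factor * depth * dt);
c = 2.99792458e10 cm/s exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "C_CM_PER_S",
    "C_CM_PER_FS",
    "Spectrum",
    "autocorrelation",
    "frequency_resolution",
    "power_spectrum",
    "ir_spectrum",
    "velocity_series",
    "peak_position",
]

C_CM_PER_S = 2.99792458e10
C_CM_PER_FS = C_CM_PER_S * 1e-15


@dataclass
class Spectrum:
    """Frequency-domain representation on a uniform cm^-1 axis."""

    frequency: np.ndarray
    intensity: np.ndarray
    dt: float
    depth: int
    pad_factor: int
    window: str | None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.frequency.shape != self.intensity.shape:
            raise ValueError("frequency and intensity must have the same shape")

    @property
    def resolution(self) -> float:
        """Axis spacing in cm^-1."""
        return frequency_resolution(self.dt, self.depth, self.pad_factor)


def autocorrelation(series: np.ndarray, depth: int, normalize: bool = True) -> np.ndarray:
    """Autocorrelation of a scalar (n,) or vector (n, d) series up to ``depth`` lags.

    Vector series use the per-lag mean of the dot product.  The biased
    estimator c(k) = (1/n) sum_t x(t).x(t+k) is used; with ``normalize``
    the lag-0 value is scaled to 1 (all-zero input yields zeros).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if depth > n:
        raise ValueError(f"depth {depth} exceeds series length {n}")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acf = np.zeros(depth)
    for c in range(x.shape[1]):
        f = np.fft.rfft(x[:, c], nfft)
        acf += np.fft.irfft(f * np.conj(f), nfft)[:depth]
    acf /= n
    if normalize:
        if acf[0] == 0.0:
            return np.zeros(depth)
        acf = acf / acf[0]
    return acf


def frequency_resolution(dt: float, depth: int, pad_factor: int = 8) -> float:
    """Frequency-axis spacing in cm^-1: 1 / (c * pad_factor * depth * dt)."""
    if dt <= 0 or depth <= 0 or pad_factor <= 0:
        raise ValueError("dt, depth and pad_factor must be positive")
    return 1.0 / (C_CM_PER_S * pad_factor * depth * dt * 1e-15)


def _window_values(name: str | None, m: int) -> np.ndarray:
    if name is None or name == "none":
        return np.ones(m)
    if name == "hann":
        # one-sided half of a Hann window over the correlation lags
        return np.cos(np.pi * np.arange(m) / (2 * (m - 1))) ** 2 if m > 1 else np.ones(1)
    raise ValueError(f"unknown window {name!r}")


def _acf_to_spectrum(
    acf: np.ndarray, dt: float, pad_factor: int, window: str | None, flags: dict | None = None
) -> Spectrum:
    depth = len(acf)
    wk = _window_values(window, depth)
    n = pad_factor * depth
    padded = np.zeros(n)
    padded[:depth] = acf * wk
    # two-sided spectrum of the even extension of the one-sided ACF
    spec = np.fft.rfft(padded).real
    spec = 2.0 * spec - padded[0]
    intensity = np.clip(spec[: n // 2 + 1], 0.0, None)
    dnu = frequency_resolution(dt, depth, pad_factor)
    freq = dnu * np.arange(len(intensity))
    return Spectrum(freq, intensity, dt=dt, depth=depth, pad_factor=pad_factor,
                    window=window, flags=flags or {})


def power_spectrum(
    series: np.ndarray,
    dt: float,
    depth: int,
    pad_factor: int = 8,
    window: str | None = "hann",
) -> Spectrum:
    """Power spectrum of a scalar series: FT of its (mean-removed) ACF.

    The series is mean-centered; the unnormalized ACF (lag-0 = variance) is
    windowed, zero-padded to ``pad_factor * depth`` and Fourier transformed.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("power_spectrum expects a scalar series")
    if depth > len(x):
        raise ValueError(f"depth {depth} exceeds series length {len(x)}")
    x = x - x.mean()
    acf = autocorrelation(x, depth, normalize=False)
    return _acf_to_spectrum(acf, dt, pad_factor, window)


def velocity_series(positions: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference velocities (one-sided at the endpoints), per fs."""
    p = np.asarray(positions, dtype=float)
    v = np.gradient(p, dt, axis=0)
    return v


def mass_weighted_power_spectrum(
    traj_positions: np.ndarray,
    masses: np.ndarray,
    dt: float,
    depth: int,
    pad_factor: int = 8,
    window: str | None = "hann",
) -> Spectrum:
    """Power spectrum from the mass-weighted velocity ACF of a group of atoms."""
    v = velocity_series(traj_positions, dt)  # (F, N, 3)
    n_frames = v.shape[0]
    if depth > n_frames:
        raise ValueError(f"depth {depth} exceeds series length {n_frames}")
    flat = v.reshape(n_frames, -1)
    w = np.repeat(np.asarray(masses, dtype=float), 3)
    flat = flat * np.sqrt(w)
    acf = autocorrelation(flat, depth, normalize=False)
    return _acf_to_spectrum(acf, dt, pad_factor, window)


def ir_spectrum(
    dipole: np.ndarray,
    dt: float,
    depth: int,
    pad_factor: int = 8,
    window: str | None = "hann",
) -> Spectrum:
    """IR-like spectrum: FT of the dipole time-derivative autocorrelation.

    The three Cartesian components are differentiated and their ACFs summed.
    A constant dipole produces a zero spectrum flagged ``constant_input``.
    """
    mu = np.asarray(dipole, dtype=float)
    if mu.ndim != 2 or mu.shape[1] != 3:
        raise ValueError("dipole series must have shape (n, 3)")
    if depth > mu.shape[0]:
        raise ValueError(f"depth {depth} exceeds series length {mu.shape[0]}")
    dmu = velocity_series(mu, dt)
    flags = {}
    if np.allclose(dmu, 0.0):
        flags["constant_input"] = True
    acf = autocorrelation(dmu, depth, normalize=False)
    return _acf_to_spectrum(acf, dt, pad_factor, window, flags)


def peak_position(spectrum: Spectrum, frange: tuple[float, float]) -> float:
    """Frequency (cm^-1) of the maximum intensity inside ``frange``,
    refined by 3-point parabolic interpolation.  Ties take the leftmost
    maximum and set the ``tie`` flag on the spectrum."""
    lo, hi = frange
    mask = (spectrum.frequency >= lo) & (spectrum.frequency <= hi)
    if not mask.any():
        raise ValueError(f"range {frange} does not overlap the frequency axis")
    idx = np.nonzero(mask)[0]
    local = spectrum.intensity[idx]
    imax = idx[int(np.argmax(local))]
    if np.count_nonzero(local == local.max()) > 1:
        spectrum.flags["tie"] = True
    # parabolic refinement needs interior neighbours
    if 0 < imax < len(spectrum.intensity) - 1:
        y0, y1, y2 = spectrum.intensity[imax - 1 : imax + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            return float(spectrum.frequency[imax] + shift * spectrum.resolution)
    return float(spectrum.frequency[imax])
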