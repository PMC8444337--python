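"""Excess-charge IR spectrum from the CEC velocity autocorrelation function.

The power spectrum of the CEC velocity is the excess-charge contribution to
the IR spectrum: collective motions encoded in the CEC (the proton-transfer
mode near 1200 cm^-1, flanking water bending near 1750 cm^-1) appear as
bands, while bulk-like motions the CEC excludes contribute nothing.
Intensities are in arbitrary units; frequencies in cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Spectrum",
    "estimate_velocity",
    "vacf",
    "ir_spectrum",
    "smooth_spectrum",
    "CM_PER_INVERSE_FS",
]

# 1 fs^-1 expressed in wavenumbers: 1e15 Hz / c
CM_PER_INVERSE_FS = 1e15 / 2.99792458e10  # = 33356.40951981521 cm^-1


@dataclass
class Spectrum:
    frequencies: np.ndarray  # cm^-1, strictly increasing
    intensities: np.ndarray  # arbitrary units, >= 0
    resolution: float  # grid spacing, cm^-1

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def peak_frequency(self, fmin: float = 0.0) -> float:
        """Frequency of the spectral maximum at or above ``fmin``."""
        sel = self.frequencies >= fmin
        return float(self.frequencies[sel][np.argmax(self.intensities[sel])])


def estimate_velocity(track: np.ndarray, dt: float) -> np.ndarray:
    """Finite-difference velocities (A/fs): central interior, one-sided ends."""
    track = np.atleast_2d(np.asarray(track, dtype=float))
    if track.shape[0] == 1:
        track = track.T
    if len(track) < 3:
        raise ConfigurationError("need at least 3 positions to estimate velocities")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(track, dt, axis=0, edge_order=1)


def vacf(velocities: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Velocity autocorrelation C(tau) = <v(0).v(tau)>, averaged over origins."""
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    if v.shape[0] == 1:
        v = v.T
    n = len(v)
    if max_lag is None:
        max_lag = n // 2
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    # FFT-based cross-correlation summed over Cartesian components
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(v, n=nfft, axis=0)
    acf = np.fft.irfft((F * np.conj(F)).sum(axis=1), n=nfft)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return acf.real / counts


def ir_spectrum(
    velocities: np.ndarray,
    dt: float,
    window: str = "hann",
    max_lag: int | None = None,
    zero_pad: int = 4,
    omega2_weight: bool = False,
) -> Spectrum:
    """One-sided power spectrum of the (tapered) VACF on a cm^-1 grid.

    The transform uses the biased autocorrelation estimator, whose
    symmetric extension is the non-negative periodogram; total spectral
    power then equals VACF(0) exactly for the untapered transform. A Hann
    taper on the lag axis suppresses leakage by default (``window="none"``
    disables it). ``zero_pad`` refines the frequency grid by the given
    factor. The optional omega^2 weighting is off by default; spectra are
    in arbitrary units either way.
    """
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    if v.shape[0] == 1:
        v = v.T
    n = len(v)
    if n < 64:
        raise ConfigurationError("need at least 64 velocity samples")
    # biased linear autocorrelation (divides by n, not n - tau): its even
    # extension transforms to the periodogram, which is non-negative exactly
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(v, n=nfft, axis=0)
    c = np.fft.irfft((F * np.conj(F)).sum(axis=1), n=nfft)[:n].real / n
    L = n - 1 if max_lag is None else int(max_lag)
    if not 0 < L < n:
        raise ValueError("max_lag must lie in (0, len(velocities))")
    c = c[: L + 1]
    if window == "hann":
        taper = 0.5 * (1 + np.cos(np.pi * np.arange(L + 1) / L))
    elif window == "none":
        taper = np.ones(L + 1)
    else:
        raise ValueError(f"unknown window {window!r}")
    ct = c * taper
    if zero_pad > 1:
        ct = np.concatenate([ct, np.zeros((zero_pad - 1) * (L + 1))])
    # symmetric extension with a zero at the fold point -> real transform
    full = np.concatenate([ct, [0.0], ct[:0:-1]])
    S = np.fft.rfft(full).real
    freqs_fs = np.fft.rfftfreq(len(full), d=dt)
    freqs_cm = freqs_fs * CM_PER_INVERSE_FS
    if omega2_weight:
        S = S * freqs_cm**2
    S = np.clip(S, 0.0, None)
    res = float(freqs_cm[1] - freqs_cm[0])
    return Spectrum(frequencies=freqs_cm, intensities=S, resolution=res)


def smooth_spectrum(spec: Spectrum, window_cm: float = 33.0) -> Spectrum:
    """Boxcar running average of the stated width (edges use the available span)."""
    if window_cm < spec.resolution:
        raise ConfigurationError(
            f"window ({window_cm} cm^-1) is smaller than the grid spacing "
            f"({spec.resolution} cm^-1)"
        )
    w = max(1, int(round(window_cm / spec.resolution)))
    kernel = np.ones(w)
    num = np.convolve(spec.intensities, kernel, mode="same")
    den = np.convolve(np.ones_like(spec.intensities), kernel, mode="same")
    return Spectrum(
        frequencies=spec.frequencies.copy(),
        intensities=num / den,
        resolution=spec.resolution,
    )
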