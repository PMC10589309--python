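"""Pulsatile synthetic flow and the spectral SNR metric of LSCI precision.

In vivo, LSCI precision is scored by how well the cardiac modulation of the
blood flow index stands out of the noise floor: the per-pixel SNR is the
spectral amplitude at the cardiac peak divided by the surrounding noise
plateau.  The synthetic stand-in modulates the ordered-motion speed
sinusoidally, v(t) = v0*(1 + m*sin(2*pi*f_c*t)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import DomainError, ParameterError
from .field_synthesis import MotionModel

__all__ = [
    "PulsatileFlow",
    "SNRMap",
    "pulsatile_motion",
    "snr_spectral",
    "median_snr",
    "variation_ratio",
]


@dataclass(frozen=True)
class PulsatileFlow:
    """Sinusoidally modulated flow speed.

    base_speed : um/us; time-average speed (maps to a base tau_c by the
        velocity calibration).
    modulation_depth : fractional amplitude in [0, 1).
    cardiac_freq : Hz-like frequency in 1/us (e.g. 1e-5 for a 100 ms period).
    """

    base_speed: float
    modulation_depth: float = 0.2
    cardiac_freq: float = 1e-5

    def __post_init__(self):
        if self.base_speed < 0:
            raise ParameterError("base_speed must be >= 0")
        if not (0 <= self.modulation_depth < 1):
            raise ParameterError("modulation_depth must be in [0, 1)")
        if self.cardiac_freq <= 0:
            raise ParameterError("cardiac_freq must be positive")


def pulsatile_motion(
    flow: PulsatileFlow, direction=(1.0, 0.0, 0.0)
) -> MotionModel:
    """Ordered MotionModel with v(t) = base_speed*(1 + m*sin(2*pi*f*t)).

    The time-average speed over an integer number of periods equals
    ``base_speed``.
    """
    d = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ParameterError("direction must be non-zero")
    vel = d / norm * flow.base_speed
    m, f = flow.modulation_depth, flow.cardiac_freq

    def modulation(t: float) -> float:
        return 1.0 + m * math.sin(2.0 * math.pi * f * t)

    return MotionModel(
        kind="ordered",
        velocity=vel,
        speed_modulation=modulation if m > 0 else None,
    )


@dataclass
class SNRMap:
    """Per-pixel spectral SNR of the cardiac peak over the noise plateau."""

    values: np.ndarray
    cardiac_band: Tuple[float, float]
    plateau_band: Tuple[float, float]
    capped: bool = False


def snr_spectral(
    bfi_series: np.ndarray,
    sampling_rate: float,
    cardiac_band: Tuple[float, float],
    plateau_band: Tuple[float, float],
    ceiling: float = 1e6,
) -> SNRMap:
    """Per-pixel SNR = peak |FFT| in the cardiac band / median in the plateau.

    ``bfi_series`` is (time, ...) — per-pixel BFI (or K) time series sampled
    at ``sampling_rate`` (same time unit as the band frequencies).  The DC
    bin is excluded.  A zero plateau (noise-free input) caps the SNR at
    ``ceiling`` and flags the map.  Invariant to global scaling of the
    series.
    """
    series = np.asarray(bfi_series, dtype=np.float64)
    n = series.shape[0]
    lo_c, hi_c = cardiac_band
    lo_p, hi_p = plateau_band
    if not (lo_c < hi_c and lo_p < hi_p):
        raise ParameterError("bands must be (low, high) with low < high")
    if max(lo_c, lo_p) < min(hi_c, hi_p):
        raise ParameterError("cardiac and plateau bands must be disjoint")
    f_centre = 0.5 * (lo_c + hi_c)
    if n < 8.0 * sampling_rate / max(f_centre, 1e-300):
        # fewer than ~8 cardiac periods: the peak bin is not resolved
        raise ParameterError("series shorter than 8 cardiac periods")
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    spec = np.abs(np.fft.rfft(series, axis=0))
    nondc = freqs > 0
    in_c = nondc & (freqs >= lo_c) & (freqs <= hi_c)
    in_p = nondc & (freqs >= lo_p) & (freqs <= hi_p)
    if not in_c.any() or not in_p.any():
        raise ParameterError("a band contains no Fourier bins")
    peak = spec[in_c].max(axis=0)
    plateau = np.median(spec[in_p], axis=0)
    # a plateau at the round-off floor of the peak is effectively noise-free
    zero_plateau = plateau <= peak * 1e-9
    capped = bool(np.any(zero_plateau))
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(~zero_plateau, peak / np.maximum(plateau, 1e-300), ceiling)
    snr = np.where(zero_plateau & (peak == 0), 0.0, snr)
    snr = np.minimum(snr, ceiling)
    return SNRMap(
        values=snr, cardiac_band=cardiac_band, plateau_band=plateau_band,
        capped=capped,
    )


def median_snr(snr_map: SNRMap, mask: Optional[np.ndarray] = None) -> float:
    """Median SNR over (optionally masked) pixels — the robust summary used
    to compare conditions; artefact pixels are excluded via ``mask``
    (True = keep)."""
    vals = snr_map.values
    if mask is not None:
        vals = vals[mask]
    if np.size(vals) == 0:
        raise ParameterError("no pixels to summarise")
    return float(np.median(vals))


def variation_ratio(
    k_series: np.ndarray,
    sampling_rate: float,
    cardiac_band: Tuple[float, float],
) -> np.ndarray:
    """Cardiac contrast variation sigma(K)_cardiac / <K> per pixel.

    The K series is band-passed by spectral masking (out-of-band rfft bins
    zeroed — exactly invertible, no filter transients) and the standard
    deviation of the band-limited series is divided by the series mean.
    For K(t) = K0*(1 + m*sin) with the sinusoid in band the ratio is
    m/sqrt(2) (the RMS of the sinusoid).
    """
    series = np.asarray(k_series, dtype=np.float64)
    n = series.shape[0]
    mean = series.mean(axis=0)
    if np.any(mean == 0):
        raise DomainError("zero-mean K series")
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    spec = np.fft.rfft(series, axis=0)
    lo, hi = cardiac_band
    keep = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    shape = [1] * series.ndim
    shape[0] = len(freqs)
    spec = spec * keep.reshape(shape)
    banded = np.fft.irfft(spec, n=n, axis=0)
    return banded.std(axis=0) / mean
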