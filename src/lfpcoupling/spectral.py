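"""Welch power spectral density and band-power extraction.

PSDs are estimated per epoch with Welch's method (Hamming window, 50%
overlap, one-sided density scaling) and then averaged across epochs, so
the epoch remains the unit of analysis.  Band powers integrate the
density over half-open frequency intervals [low, high) with exact edge
interpolation, which makes adjacent bands exactly additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ParameterError
from .preprocess import EpochSet

#: default Welch segment length in samples (~0.98 Hz resolution at 1 kHz)
DEFAULT_SEGMENT_LENGTH = 1024


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with half-open interval convention [low, high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ParameterError(
                f"band {self.name}: need 0 < low < high, got [{self.low}, {self.high})"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: canonical rodent hippocampal bands
THETA = BandSpec("theta", 4.0, 12.0)
LOW_GAMMA = BandSpec("low_gamma", 30.0, 60.0)
HIGH_GAMMA = BandSpec("high_gamma", 60.0, 100.0)
GAMMA = BandSpec("gamma", 30.0, 100.0)

CANONICAL_BANDS = (THETA, LOW_GAMMA, HIGH_GAMMA)


@dataclass
class PSDEstimate:
    """One-sided Welch PSD per channel.

    ``power`` has shape ``(n_channels, n_freqs)`` in signal-units^2/Hz.
    """

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    n_epochs_averaged: int
    window_params: dict = field(default_factory=dict)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(self.power < 0):
            raise ParameterError("PSD values must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("frequency grid must be strictly increasing")


def welch_psd(
    epochs: EpochSet,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    overlap_fraction: float = 0.5,
) -> PSDEstimate:
    """Welch PSD averaged over segments within each epoch and over epochs.

    Hamming window, mean removal per segment, one-sided density scaling.
    """
    if epochs.n_epochs == 0:
        raise ParameterError("cannot estimate a PSD from an empty EpochSet")
    if segment_length > epochs.samples_per_epoch:
        raise ParameterError(
            f"segment_length {segment_length} exceeds samples_per_epoch "
            f"{epochs.samples_per_epoch}"
        )
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must be in [0, 1)")
    noverlap = int(segment_length * overlap_fraction)
    freqs, pxx = signal.welch(
        epochs.epochs,
        fs=epochs.fs,
        window="hamming",
        nperseg=segment_length,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    power = pxx.mean(axis=0)  # average over epochs -> (channels, freqs)
    return PSDEstimate(
        freqs=freqs,
        power=power,
        fs=epochs.fs,
        n_epochs_averaged=epochs.n_epochs,
        window_params={
            "window": "hamming",
            "nperseg": segment_length,
            "noverlap": noverlap,
            "detrend": "constant",
        },
        channel_labels=list(epochs.channel_labels),
    )


def band_power(psd: PSDEstimate, band: BandSpec) -> np.ndarray:
    """Integrated power over ``band`` per channel (signal-units^2).

    Trapezoidal integration of the density over [band.low, band.high] with
    the density linearly interpolated at the exact band edges; this makes
    band_power additive across adjacent bands to machine precision.
    """
    if band.low < psd.freqs[0] or band.high > psd.freqs[-1]:
        raise ParameterError(
            f"band [{band.low}, {band.high}) outside PSD grid "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}]"
        )
    inner = psd.freqs[(psd.freqs > band.low) & (psd.freqs < band.high)]
    grid = np.concatenate([[band.low], inner, [band.high]])
    out = np.empty(psd.power.shape[0])
    for ch in range(psd.power.shape[0]):
        vals = np.interp(grid, psd.freqs, psd.power[ch])
        out[ch] = np.trapezoid(vals, grid)
    return out


def total_power(psd: PSDEstimate) -> np.ndarray:
    """Integral of the density over the full frequency grid, per channel."""
    return np.trapezoid(psd.power, psd.freqs, axis=-1)


def group_mean_psd(psds: list[PSDEstimate]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise group mean and variance of subject-level PSD curves.

    Each subject contributes the mean over its channels; returns
    ``(freqs, mean_curve, variance_curve)``.
    """
    if not psds:
        raise ParameterError("need at least one PSDEstimate")
    freqs = psds[0].freqs
    for p in psds[1:]:
        if p.freqs.shape != freqs.shape or not np.allclose(p.freqs, freqs):
            raise ParameterError("all PSDs must share one frequency grid")
    curves = np.stack([p.power.mean(axis=0) for p in psds])
    return freqs, curves.mean(axis=0), curves.var(axis=0, ddof=0)
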