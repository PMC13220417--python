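"""Inter-channel phase synchrony via the phase-locking value (PLV).

For a pair of instantaneous-phase series the PLV is the magnitude of the
circular mean of the unit phasors of their pointwise phase differences,

    PLV = | (1/T) * sum_t exp(i (phi1(t) - phi2(t))) |,

0 for no locking and 1 for perfect locking.  Channel-pair matrices are
computed per epoch (band-limited with the same zero-phase FIR contract
as the coupling module, phases via the Hilbert transform) and averaged
across epochs; phase-difference distributions are reported in degrees
over [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DataError, ParameterError
from .pac import bandpass_fir_zero_phase, filter_edge_samples
from .preprocess import EpochSet
from .spectral import BandSpec
from scipy import signal as _signal


@dataclass
class PLVMatrix:
    """Symmetric channel x channel phase-locking values for one band."""

    values: np.ndarray
    band: BandSpec
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("PLV matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("PLV matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise DataError("PLV values must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_channels * (self.n_channels - 1) // 2

    @property
    def mean_plv(self) -> float:
        """Mean over the off-diagonal upper triangle."""
        iu = np.triu_indices(self.n_channels, k=1)
        return float(self.values[iu].mean())


@dataclass
class PhaseDiffDistribution:
    """Normalized histogram of wrapped phase differences in degrees."""

    bin_edges: np.ndarray  # degrees over [0, 360], length n_bins+1
    probabilities: np.ndarray
    pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        s = self.probabilities.sum()
        if abs(s - 1.0) > 1e-12:
            raise DataError(f"probabilities sum to {s}, expected 1")


def plv_pair(phase1: np.ndarray, phase2: np.ndarray) -> float:
    """PLV between two instantaneous-phase series (radians)."""
    phase1 = np.asarray(phase1, dtype=float)
    phase2 = np.asarray(phase2, dtype=float)
    if phase1.shape != phase2.shape:
        raise DataError(
            f"phase series lengths differ: {phase1.shape} vs {phase2.shape}")
    if phase1.size == 0:
        raise DataError("phase series must contain at least one sample")
    return float(np.abs(np.mean(np.exp(1j * (phase1 - phase2)))))


def plv_matrix(epochs: EpochSet, band: BandSpec) -> PLVMatrix:
    """Pairwise PLV matrix for one band, averaged over epochs.

    Each epoch of each channel is band-filtered (zero-phase FIR), phases
    are taken from the Hilbert transform, filter-transient edge samples
    are excluded, and the per-epoch pairwise PLVs are averaged.
    """
    if epochs.n_channels < 2:
        raise ParameterError("need >= 2 channels for a PLV matrix")
    if epochs.n_epochs == 0:
        raise DataError("empty EpochSet")
    if band.high >= epochs.fs / 2:
        raise ParameterError(
            f"band [{band.low}, {band.high}) exceeds Nyquist {epochs.fs / 2}")
    n_edge = filter_edge_samples(band, epochs.fs)
    filtered = bandpass_fir_zero_phase(epochs.epochs, band, epochs.fs)
    phases = np.angle(_signal.hilbert(filtered, axis=-1))
    if 2 * n_edge >= epochs.samples_per_epoch:
        raise DataError("epochs too short for the band's filter transient")
    phases = phases[..., n_edge:-n_edge]
    n_ch = epochs.n_channels
    acc = np.zeros((n_ch, n_ch))
    for e in range(epochs.n_epochs):
        for i, j in combinations(range(n_ch), 2):
            v = plv_pair(phases[e, i], phases[e, j])
            acc[i, j] += v
            acc[j, i] += v
    acc /= epochs.n_epochs
    np.fill_diagonal(acc, 1.0)
    return PLVMatrix(values=acc, band=band,
                     channel_labels=list(epochs.channel_labels))


def phase_difference_distribution(
    phase1: np.ndarray, phase2: np.ndarray, n_bins: int = 12,
    pair: tuple[str, str] = ("", ""),
) -> PhaseDiffDistribution:
    """Histogram of phase differences wrapped to [0, 360) degrees.

    The default 30-degree bins place differences near zero in the first
    bin and near 360 in the last, so a concentration "between 330 and 30
    degrees" spans the last + first bins.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    phase1 = np.asarray(phase1, dtype=float)
    phase2 = np.asarray(phase2, dtype=float)
    if phase1.shape != phase2.shape:
        raise DataError("phase series lengths differ")
    diff_deg = np.mod(np.degrees(phase1 - phase2), 360.0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(diff_deg, bins=edges)
    return PhaseDiffDistribution(
        bin_edges=edges,
        probabilities=counts / counts.sum(),
        pair=pair,
    )
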