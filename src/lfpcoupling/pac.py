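"""Theta-gamma phase-amplitude coupling via the modulation index.

The estimator follows the Tort mutual-information construction: the slow
band's instantaneous phase (zero-phase FIR bandpass + Hilbert transform)
is divided into N equal bins (default 16, i.e. 22.5 deg per bin), the
fast band's amplitude envelope is averaged within each bin and normalized
to a probability distribution p_j, and

    MI = (ln N - H(p)) / ln N,        H(p) = -sum_j p_j ln p_j,

so MI = 0 for a perfectly uniform amplitude-by-phase distribution and
MI = 1 when all amplitude mass falls in one bin.  Spurious coupling is
excluded with a circular time-shift surrogate null: the amplitude series
is rotated relative to the phase series by random offsets, the MI is
recomputed per surrogate, and the observed MI is kept only if it exceeds
the surrogate mean + 2 SD (otherwise it is reported as 0).

Comodulograms scan MI over a grid of narrow phase bands (1 Hz wide, 1 Hz
step across theta) and wider amplitude bands (20 Hz wide, 2 Hz step
across gamma).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError
from .spectral import BandSpec

logger = logging.getLogger(__name__)

#: number of phase bins for the modulation index
DEFAULT_N_BINS = 16

#: number of surrogate rotations for the significance threshold
DEFAULT_N_SURROGATES = 10

#: comodulogram grids: phase centers 4..12 Hz step 1, amplitude centers
#: 30..100 Hz step 2; bandwidths are full widths (center +/- half-width)
DEFAULT_PHASE_CENTERS = np.arange(4.0, 12.0 + 0.5, 1.0)
DEFAULT_AMP_CENTERS = np.arange(30.0, 100.0 + 1.0, 2.0)
DEFAULT_PHASE_BANDWIDTH = 1.0
DEFAULT_AMP_BANDWIDTH = 20.0

_CYCLES_AT_LOW_EDGE = 3.0
_HAMMING_TB_FACTOR = 3.3   # Hamming transition width ~ 3.3 * fs / n_taps
_TRANSITION_CAP_HZ = 5.0   # keep skirts sharp enough to pass theta sidebands


# ---------------------------------------------------------------------------
# filtering and analytic decomposition


def design_bandpass_fir(band: BandSpec, fs: float) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) bandpass taps for ``band``.

    The tap count is the larger of (a) three cycles of the band's low
    edge and (b) enough taps that the Hamming transition width stays
    below min(bandwidth, 5 Hz); rounded up to an odd count (type-I
    symmetric FIR).  The bandwidth bound keeps narrow 1-Hz bands at
    unity center gain; the 5 Hz cap keeps the skirts of wide amplitude
    bands sharp enough that modulation sidebands a few Hz inside the
    band edges are passed at full gain (otherwise comodulogram peaks
    get displaced onto single-sideband cells).
    """
    if not 0 < band.low < band.high < fs / 2:
        raise ParameterError(
            f"band [{band.low}, {band.high}) must lie inside (0, Nyquist={fs / 2})"
        )
    transition = min(band.width, _TRANSITION_CAP_HZ)
    n = int(np.ceil(max(_CYCLES_AT_LOW_EDGE * fs / band.low,
                        _HAMMING_TB_FACTOR * fs / transition)))
    if n % 2 == 0:
        n += 1
    return signal.firwin(n, [band.low, band.high], pass_zero=False,
                         window="hamming", fs=fs)


def bandpass_fir_zero_phase(x: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Apply the band's FIR forward-backward (zero net phase shift).

    Implemented as a single FFT convolution with the filter's
    autocorrelation (equivalent to forward-backward application of a
    symmetric FIR), with odd reflection padding at the edges.
    """
    x = np.asarray(x, dtype=float)
    taps = design_bandpass_fir(band, fs)
    n = len(taps)
    if x.shape[-1] <= 3 * n:
        raise DataError(
            f"signal of {x.shape[-1]} samples too short for a {n}-tap filter "
            f"on band [{band.low}, {band.high}); need more than {3 * n} samples"
        )
    h2 = np.convolve(taps, taps)  # double-pass response, still symmetric
    pad = n
    first = x[..., pad:0:-1]
    last = x[..., -2:-pad - 2:-1]
    xp = np.concatenate(
        [2 * x[..., :1] - first, x, 2 * x[..., -1:] - last], axis=-1
    )
    y = signal.fftconvolve(xp, np.broadcast_to(h2, xp.shape[:-1] + (len(h2),)),
                           mode="same", axes=-1)
    return y[..., pad:pad + x.shape[-1]]


def filter_edge_samples(band: BandSpec, fs: float) -> int:
    """Samples at each record boundary contaminated by filter transients."""
    return len(design_bandpass_fir(band, fs))


@dataclass
class AnalyticSignal:
    """Instantaneous phase and amplitude of a band-limited signal.

    ``phase`` is in radians in (-pi, pi]; ``amplitude`` is the Hilbert
    envelope (>= 0).  ``n_edge`` samples at each end are contaminated by
    the bandpass transient and should be excluded from binning.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    band: BandSpec
    fs: float
    n_edge: int = 0

    def interior(self) -> tuple[np.ndarray, np.ndarray]:
        """Phase and amplitude with edge samples stripped."""
        if self.n_edge == 0:
            return self.phase, self.amplitude
        sl = slice(self.n_edge, -self.n_edge)
        return self.phase[sl], self.amplitude[sl]


def analytic_decompose(
    filtered: np.ndarray, band: BandSpec, fs: float, n_edge: int | None = None
) -> AnalyticSignal:
    """Hilbert-transform phase and amplitude of an already band-limited signal."""
    filtered = np.asarray(filtered, dtype=float)
    if not np.all(np.isfinite(filtered)):
        raise DataError("non-finite values in band-limited signal")
    analytic = signal.hilbert(filtered)
    if n_edge is None:
        n_edge = (filter_edge_samples(band, fs) + 1) // 2
    return AnalyticSignal(
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
        band=band,
        fs=fs,
        n_edge=int(n_edge),
    )


def extract_band(x: np.ndarray, band: BandSpec, fs: float) -> AnalyticSignal:
    """Bandpass + Hilbert in one step (edge count from the filter length)."""
    filtered = bandpass_fir_zero_phase(x, band, fs)
    return analytic_decompose(filtered, band, fs,
                              n_edge=filter_edge_samples(band, fs))


# ---------------------------------------------------------------------------
# modulation index


@dataclass
class PhaseBinDistribution:
    """Normalized mean-amplitude-by-phase-bin distribution."""

    n_bins: int
    bin_edges: np.ndarray  # radians, length n_bins+1, from -pi to pi
    mean_amplitude: np.ndarray
    probabilities: np.ndarray

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / self.n_bins

    def __post_init__(self) -> None:
        s = self.probabilities.sum()
        if abs(s - 1.0) > 1e-12:
            raise DataError(f"bin probabilities sum to {s}, expected 1")


@dataclass
class ModulationIndexResult:
    """Modulation index with optional surrogate statistics."""

    mi: float
    entropy: float
    distribution: PhaseBinDistribution
    phase_band: BandSpec | None = None
    amp_band: BandSpec | None = None
    surrogate_mis: np.ndarray | None = None
    significant: bool | None = None

    @property
    def mi_corrected(self) -> float:
        """Observed MI if it beats the surrogate threshold, else 0."""
        if self.significant is None:
            raise ParameterError("no surrogate test was run for this result")
        return self.mi if self.significant else 0.0


def phase_bin_edges(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal phase-bin edges over (-pi, pi], first bin starting at -pi."""
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def bin_phases(phase: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Half-open [edge, next_edge) bin index per sample; +pi joins the last bin."""
    edges = phase_bin_edges(n_bins)
    idx = np.digitize(phase, edges) - 1
    return np.clip(idx, 0, n_bins - 1)


def _mi_from_binned(idx: np.ndarray, amplitude: np.ndarray, counts: np.ndarray,
                    n_bins: int) -> tuple[float, float, np.ndarray, np.ndarray]:
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    mean_amp = sums / counts
    total = mean_amp.sum()
    if total <= 0:
        # all-zero amplitude: maximally uniform by convention
        p = np.full(n_bins, 1.0 / n_bins)
        mean_amp = np.zeros(n_bins)
    else:
        p = mean_amp / total
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))
    mi = (np.log(n_bins) - entropy) / np.log(n_bins)
    return float(mi), entropy, mean_amp, p


def phase_bin_distribution(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> PhaseBinDistribution:
    """Mean amplitude per phase bin, normalized to probabilities."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise DataError("phase and amplitude must have equal length")
    idx = bin_phases(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0]
        raise DataError(
            f"phase bins {empty.tolist()} received no samples; "
            "provide a longer record so every bin is occupied"
        )
    _, _, mean_amp, p = _mi_from_binned(idx, amplitude, counts, n_bins)
    return PhaseBinDistribution(
        n_bins=n_bins,
        bin_edges=phase_bin_edges(n_bins),
        mean_amplitude=mean_amp,
        probabilities=p,
    )


def modulation_index(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    phase_band: BandSpec | None = None,
    amp_band: BandSpec | None = None,
) -> ModulationIndexResult:
    """Tort modulation index of ``amplitude`` on ``phase``.

    Natural logarithms are used in both the entropy and the ln N
    normalization (the base cancels in the ratio).
    """
    dist = phase_bin_distribution(phase, amplitude, n_bins)
    p = dist.probabilities
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))
    mi = float((np.log(n_bins) - entropy) / np.log(n_bins))
    return ModulationIndexResult(
        mi=mi,
        entropy=entropy,
        distribution=dist,
        phase_band=phase_band,
        amp_band=amp_band,
    )


def surrogate_shifts(
    n_samples: int,
    fs: float,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random circular offsets, uniform in [fs, n_samples - fs) samples."""
    if n_surrogates < 2:
        raise ParameterError("n_surrogates must be >= 2 (SD undefined otherwise)")
    min_shift = int(fs)
    if n_samples < 2 * min_shift:
        raise DataError(
            f"record of {n_samples} samples too short for circular-shift "
            f"surrogates; need at least {2 * min_shift}"
        )
    rng = rng if rng is not None else np.random.default_rng()
    return rng.integers(min_shift, n_samples - min_shift, size=n_surrogates)


def surrogate_threshold(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.Generator | None = None,
    fs: float = 1000.0,
    n_bins: int = DEFAULT_N_BINS,
    shifts: np.ndarray | None = None,
    phase_band: BandSpec | None = None,
    amp_band: BandSpec | None = None,
) -> ModulationIndexResult:
    """Observed MI against a circular time-shift surrogate null.

    Each surrogate rotates the amplitude series relative to the phase
    series by a random offset uniform in [fs, T - fs] samples (at least
    one second away from true alignment in either direction) and
    recomputes the MI.  The observed MI is flagged significant iff it
    exceeds mean + 2 SD (ddof=1) of the surrogate MIs; non-significant
    results report ``mi_corrected`` = 0.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    result = modulation_index(phase, amplitude, n_bins,
                              phase_band=phase_band, amp_band=amp_band)
    if shifts is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        shifts = surrogate_shifts(len(phase), fs, n_surrogates, rng)
    elif len(shifts) < 2:
        raise ParameterError("need at least 2 surrogate shifts")
    idx = bin_phases(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        raise DataError("empty phase bin; provide a longer record")
    sur = np.empty(len(shifts))
    for k, off in enumerate(shifts):
        sur[k], _, _, _ = _mi_from_binned(idx, np.roll(amplitude, int(off)),
                                          counts, n_bins)
    threshold = sur.mean() + 2.0 * sur.std(ddof=1)
    result.surrogate_mis = sur
    result.significant = bool(result.mi > threshold)
    return result


# ---------------------------------------------------------------------------
# comodulogram


@dataclass
class Comodulogram:
    """Surrogate-corrected MI over a (phase frequency x amplitude frequency) grid.

    ``mi_grid[i, j]`` is the corrected MI for phase center i and amplitude
    center j; cells whose amplitude band would exceed Nyquist are NaN.
    """

    phase_freq_centers: np.ndarray
    amp_freq_centers: np.ndarray
    mi_grid: np.ndarray
    raw_mi_grid: np.ndarray
    phase_bandwidth: float = DEFAULT_PHASE_BANDWIDTH
    amp_bandwidth: float = DEFAULT_AMP_BANDWIDTH
    n_bins: int = DEFAULT_N_BINS
    n_surrogates: int = DEFAULT_N_SURROGATES
    meta: dict = field(default_factory=dict)

    def band_mi(self, phase_band: BandSpec, amp_band: BandSpec,
                reduce: str = "mean", corrected: bool = True) -> float:
        """Summary MI over the cells whose centers fall in a band rectangle.

        ``reduce`` is "mean" (default) or "max".
        """
        pm = (self.phase_freq_centers >= phase_band.low) & (
            self.phase_freq_centers < phase_band.high)
        am = (self.amp_freq_centers >= amp_band.low) & (
            self.amp_freq_centers < amp_band.high)
        if not pm.any() or not am.any():
            raise ParameterError("band rectangle contains no grid centers")
        cells = (self.mi_grid if corrected else self.raw_mi_grid)[np.ix_(pm, am)]
        if reduce == "mean":
            return float(np.nanmean(cells))
        if reduce == "max":
            return float(np.nanmax(cells))
        raise ParameterError(f"unknown reduce {reduce!r}")

    def argmax_cell(self, corrected: bool = False) -> tuple[float, float]:
        """(phase center, amplitude center) of the largest MI cell."""
        grid = self.mi_grid if corrected else self.raw_mi_grid
        i, j = np.unravel_index(np.nanargmax(grid), grid.shape)
        return float(self.phase_freq_centers[i]), float(self.amp_freq_centers[j])


def comodulogram(
    x: np.ndarray,
    fs: float,
    phase_centers: np.ndarray | None = None,
    amp_centers: np.ndarray | None = None,
    phase_bandwidth: float = DEFAULT_PHASE_BANDWIDTH,
    amp_bandwidth: float = DEFAULT_AMP_BANDWIDTH,
    n_bins: int = DEFAULT_N_BINS,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.Generator | None = None,
) -> Comodulogram:
    """Surrogate-corrected comodulogram of a single-channel signal.

    One set of circular surrogate shifts is drawn from ``seed`` and shared
    across all grid cells, so the null comparison is consistent over the
    (heavily overlapping) amplitude bands.  Bandwidths are full widths:
    each center c scans the band [c - bw/2, c + bw/2).
    """
    x = np.asarray(x, dtype=float)
    if phase_centers is None:
        phase_centers = DEFAULT_PHASE_CENTERS
    if amp_centers is None:
        amp_centers = DEFAULT_AMP_CENTERS
    phase_centers = np.asarray(phase_centers, dtype=float)
    amp_centers = np.asarray(amp_centers, dtype=float)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shifts = surrogate_shifts(len(x), fs, n_surrogates, rng)

    # decompose once per phase band: binned indices + edge size
    phase_info = []
    for pc in phase_centers:
        band = BandSpec(f"phase_{pc:g}", pc - phase_bandwidth / 2,
                        pc + phase_bandwidth / 2)
        sig = extract_band(x, band, fs)
        phase_info.append((bin_phases(sig.phase, n_bins), sig.n_edge))

    amp_info = []
    for ac in amp_centers:
        lo, hi = ac - amp_bandwidth / 2, ac + amp_bandwidth / 2
        if hi >= fs / 2:
            warnings.warn(
                f"amplitude band [{lo}, {hi}) exceeds Nyquist; cells at "
                f"{ac} Hz recorded as missing", stacklevel=2)
            amp_info.append(None)
            continue
        band = BandSpec(f"amp_{ac:g}", lo, hi)
        sig = extract_band(x, band, fs)
        amp_info.append((sig.amplitude, sig.n_edge))

    raw = np.full((len(phase_centers), len(amp_centers)), np.nan)
    corrected = np.full_like(raw, np.nan)
    for i, (idx_full, p_edge) in enumerate(phase_info):
        for j, info in enumerate(amp_info):
            if info is None:
                continue
            amp_full, a_edge = info
            edge = max(p_edge, a_edge)
            sl = slice(edge, len(x) - edge)
            idx = idx_full[sl]
            counts = np.bincount(idx, minlength=n_bins)
            if np.any(counts == 0):
                raise DataError(
                    "empty phase bin in comodulogram cell; record too short")
            mi, _, _, _ = _mi_from_binned(idx, amp_full[sl], counts, n_bins)
            sur = np.empty(len(shifts))
            for k, off in enumerate(shifts):
                rolled = np.roll(amp_full, int(off))[sl]
                sur[k], _, _, _ = _mi_from_binned(idx, rolled, counts, n_bins)
            raw[i, j] = mi
            corrected[i, j] = mi if mi > sur.mean() + 2.0 * sur.std(ddof=1) else 0.0
    return Comodulogram(
        phase_freq_centers=phase_centers,
        amp_freq_centers=amp_centers,
        mi_grid=corrected,
        raw_mi_grid=raw,
        phase_bandwidth=phase_bandwidth,
        amp_bandwidth=amp_bandwidth,
        n_bins=n_bins,
        n_surrogates=n_surrogates,
        meta={"shifts": shifts.tolist()},
    )
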