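"""Synthetic multichannel LFP generation with known ground truth.

Real hippocampal recordings used for theta-gamma coupling analyses are
rarely deposited, so every downstream stage here is validated against
signals whose coupling and synchrony are known by construction:

* ``generate_coupled_lfp`` builds a theta oscillation whose phase
  modulates a gamma carrier's envelope with a controllable depth kappa
  (sinusoidal phase-to-amplitude transfer), on top of a 1/f^alpha noise
  floor, optional 50 Hz powerline contamination, and slow baseline drift.
* ``generate_multichannel_synchrony`` builds channels that share a common
  oscillatory phase mixed with independent random-walk phase jitter, so
  expected pairwise phase locking rises monotonically from ~0 to 1 as the
  synchrony knob goes from 0 to 1.
* ``generate_stim_waveform`` renders the rectangular 40 Hz pulse train of
  a low-field magnetic stimulator (duty cycle within each period, burst
  gating over a repeating burst cycle).

All randomness flows from a single seed; identical configs produce
bit-identical output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import DataError, ParameterError
from .preprocess import Recording

#: random-walk phase-jitter step (rad per sample) used by the synchrony knob
PHASE_JITTER_STEP = 0.1

#: acquisition-style band limit applied to the 1/f noise floor (Hz)
NOISE_BAND = (0.3, 300.0)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for the synthetic LFP generator.

    ``coupling_strength`` (kappa) sets the depth of theta-phase modulation
    of the gamma envelope: at sample t the true envelope is
    ``gamma_amp * (1 - kappa + kappa * (1 + cos(theta_phase(t))) / 2)``,
    so kappa=0 gives a constant envelope and kappa=1 full modulation.
    ``synchrony`` in [0, 1] controls inter-channel phase locking.

    ``theta_phase_jitter`` / ``gamma_phase_jitter`` are random-walk phase
    steps (rad/sample SD) giving both rhythms the slow frequency wander
    of biological oscillations; without it the rhythms are strictly
    periodic and circular time-shift surrogates cannot destroy coupling
    (a shift then only rotates the preferred phase bin, which the
    modulation index is invariant to).
    """

    duration_s: float
    fs: float = 1000.0
    n_channels: int = 6
    theta_freq: float = 8.0
    gamma_freq: float = 75.0
    coupling_strength: float = 0.5
    synchrony: float = 0.5
    theta_amp: float = 1.0
    gamma_amp: float = 0.5
    theta_phase_jitter: float = 0.03
    gamma_phase_jitter: float = 0.05
    noise_exponent: float = 1.0
    noise_scale: float = 0.2
    powerline_amp: float = 0.0
    drift_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1")
        if not 0 <= self.coupling_strength <= 1:
            raise ParameterError("coupling_strength must be in [0, 1]")
        if not 0 <= self.synchrony <= 1:
            raise ParameterError("synchrony must be in [0, 1]")
        if self.fs <= 2 * self.gamma_freq:
            raise ParameterError("fs must exceed 2*gamma_freq")
        for name in ("theta_amp", "gamma_amp", "noise_scale",
                     "powerline_amp", "drift_amp",
                     "theta_phase_jitter", "gamma_phase_jitter"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StimParams:
    """Rectangular burst-mode stimulation waveform parameters.

    Defaults describe a 40 Hz train at 10 mT-equivalent amplitude with a
    24% duty cycle, gated so bursts occupy 33% of each 1 s burst cycle.
    """

    frequency: float = 40.0
    amplitude: float = 10.0
    duty_cycle: float = 0.24
    burst_fraction: float = 0.33
    burst_cycle_s: float = 1.0
    fs: float = 10000.0

    def __post_init__(self) -> None:
        if not 0 < self.duty_cycle <= 1:
            raise ParameterError("duty_cycle must be in (0, 1]")
        if not 0 < self.burst_fraction <= 1:
            raise ParameterError("burst_fraction must be in (0, 1]")
        if self.frequency <= 0 or self.burst_cycle_s <= 0:
            raise ParameterError("frequency and burst_cycle_s must be positive")
        if self.fs <= 2 * self.frequency:
            raise ParameterError("fs must exceed 2*frequency")


@dataclass
class Waveform:
    """A single-channel stimulation waveform."""

    samples: np.ndarray
    fs: float


def _channel_rngs(seed: int, n_channels: int) -> list[np.random.Generator]:
    """Deterministic per-channel substreams from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_channels)]


def _powerlaw_noise(n: int, fs: float, alpha: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^alpha spectrum, band-limited
    to the acquisition band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    inside = (freqs >= NOISE_BAND[0]) & (freqs <= NOISE_BAND[1])
    shape[inside] = freqs[inside] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _drift(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Slow baseline wander: three random-phase sinusoids below 0.5 Hz,
    scaled to RMS ``amp``."""
    if amp == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    freqs = rng.uniform(0.03, 0.45, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    d = np.sum([np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)],
               axis=0)
    return amp * d / np.sqrt(np.mean(d**2))


def coupled_envelope(theta_phase: np.ndarray, kappa: float,
                     baseline: float) -> np.ndarray:
    """Ground-truth gamma envelope given the theta phase.

    ``baseline * (1 - kappa + kappa * (1 + cos(theta_phase)) / 2)``:
    constant at kappa=0, fully modulated (touching 0) at kappa=1.
    """
    return baseline * (1.0 - kappa + kappa * (1.0 + np.cos(theta_phase)) / 2.0)


def generate_coupled_lfp(config: SimConfig) -> Recording:
    """Multichannel LFP-like signal with theta-phase-modulated gamma.

    Each channel carries a theta oscillation at ``theta_freq`` (random
    initial phase per channel), a gamma carrier at ``gamma_freq`` whose
    envelope follows :func:`coupled_envelope`, a 1/f^alpha noise floor,
    and optional powerline and drift components.
    """
    n = config.n_samples
    t = np.arange(n) / config.fs
    rngs = _channel_rngs(config.seed, config.n_channels)
    data = np.empty((config.n_channels, n))
    for ch, rng in enumerate(rngs):
        theta_phase = 2 * np.pi * config.theta_freq * t + rng.uniform(0, 2 * np.pi)
        gamma_phase = 2 * np.pi * config.gamma_freq * t + rng.uniform(0, 2 * np.pi)
        if config.theta_phase_jitter > 0:
            theta_phase = theta_phase + np.cumsum(
                rng.normal(0.0, config.theta_phase_jitter, size=n))
        if config.gamma_phase_jitter > 0:
            gamma_phase = gamma_phase + np.cumsum(
                rng.normal(0.0, config.gamma_phase_jitter, size=n))
        env = coupled_envelope(theta_phase, config.coupling_strength,
                               config.gamma_amp)
        x = config.theta_amp * np.cos(theta_phase) + env * np.cos(gamma_phase)
        if config.noise_scale > 0:
            x = x + config.noise_scale * _powerlaw_noise(
                n, config.fs, config.noise_exponent, rng)
        if config.powerline_amp > 0:
            x = x + config.powerline_amp * np.sin(
                2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        if config.drift_amp > 0:
            x = x + _drift(n, config.fs, config.drift_amp, rng)
        data[ch] = x
    return Recording(
        data=data,
        fs=config.fs,
        metadata={"generator": "generate_coupled_lfp", "config": config.to_dict()},
    )


def generate_multichannel_synchrony(config: SimConfig) -> Recording:
    """Channels sharing a common oscillatory phase with controllable locking.

    Per-channel phase = common phase + (1 - synchrony) * independent
    random-walk jitter (step SD ``PHASE_JITTER_STEP`` rad/sample), so
    synchrony=1 duplicates the oscillatory phase across channels and the
    expected pairwise PLV rises monotonically with the knob.  The carrier
    frequency is ``gamma_freq``; noise and artifacts follow the config.
    """
    if config.n_channels < 2:
        raise ParameterError("n_channels must be >= 2 for synchrony generation")
    n = config.n_samples
    t = np.arange(n) / config.fs
    common_phase = 2 * np.pi * config.gamma_freq * t
    rngs = _channel_rngs(config.seed, config.n_channels)
    data = np.empty((config.n_channels, n))
    for ch, rng in enumerate(rngs):
        jitter = np.cumsum(rng.normal(0.0, PHASE_JITTER_STEP, size=n))
        phase = common_phase + (1.0 - config.synchrony) * jitter
        x = config.gamma_amp * np.cos(phase)
        if config.noise_scale > 0:
            x = x + config.noise_scale * _powerlaw_noise(
                n, config.fs, config.noise_exponent, rng)
        if config.powerline_amp > 0:
            x = x + config.powerline_amp * np.sin(
                2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        if config.drift_amp > 0:
            x = x + _drift(n, config.fs, config.drift_amp, rng)
        data[ch] = x
    return Recording(
        data=data,
        fs=config.fs,
        metadata={"generator": "generate_multichannel_synchrony",
                  "config": config.to_dict()},
    )


def generate_stim_waveform(params: StimParams, duration_s: float) -> Waveform:
    """Rectangular burst-gated pulse train.

    Within a burst, each 1/frequency period holds ``amplitude`` for
    ``duty_cycle`` of the period and 0 otherwise; bursts occupy the first
    ``burst_fraction`` of each ``burst_cycle_s``.  Output values are
    exactly {0, amplitude}.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    n = int(round(duration_s * params.fs))
    i = np.arange(n)
    period = params.fs / params.frequency            # samples per period
    cycle = params.burst_cycle_s * params.fs         # samples per burst cycle
    in_pulse = np.mod(i, period) < params.duty_cycle * period
    in_burst = np.mod(i, cycle) < params.burst_fraction * cycle
    samples = np.where(in_pulse & in_burst, params.amplitude, 0.0)
    return Waveform(samples=samples, fs=params.fs)


def inject_artifacts(recording: Recording, powerline_amp: float,
                     drift_amp: float, seed: int = 0) -> Recording:
    """Add 50 Hz powerline and sub-0.5 Hz drift components to a recording.

    Pure function: the input recording is left unchanged.  With both
    amplitudes zero the output data equal the input exactly.
    """
    if recording.n_samples == 0:
        raise DataError("recording is empty")
    if powerline_amp < 0 or drift_amp < 0:
        raise ParameterError("artifact amplitudes must be non-negative")
    t = np.arange(recording.n_samples) / recording.fs
    rngs = _channel_rngs(seed, recording.n_channels)
    data = recording.data.copy()
    for ch, rng in enumerate(rngs):
        if powerline_amp > 0:
            data[ch] += powerline_amp * np.sin(
                2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        if drift_amp > 0:
            data[ch] += _drift(recording.n_samples, recording.fs, drift_amp, rng)
    return recording.copy_with(
        data, injected_artifacts={"powerline_amp": powerline_amp,
                                  "drift_amp": drift_amp, "seed": seed})
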