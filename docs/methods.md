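# Methods

This note documents the models, parameter choices, and numerical
decisions behind `lfpcoupling`, and what the synthetic validation does
and does not establish about real recordings.

## Signal model of the synthetic generator

Each channel of `generate_coupled_lfp` is

    x(t) = A_θ cos φ_θ(t) + A_env(t) cos φ_γ(t) + σ n_α(t)
           + powerline + drift,

with

* φ_θ(t) = 2π f_θ t + φ_0 + W_θ(t): theta phase (default f_θ = 8 Hz)
  with a random initial phase per channel and a random-walk wander W_θ
  (step SD `theta_phase_jitter` = 0.03 rad/sample at 1 kHz, i.e. a
  Lorentzian linewidth of ~0.14 Hz). γ analogous with f_γ = 75 Hz and
  step SD 0.05 (~0.4 Hz linewidth).
* A_env(t) = A_γ (1 − κ + κ (1 + cos φ_θ(t)) / 2): sinusoidal
  phase-to-amplitude transfer with coupling depth κ ∈ [0, 1]. κ = 0
  gives a constant envelope (coefficient of variation 0 before noise);
  κ = 1 modulates fully, the envelope touching 0 at the theta trough.
  This transfer matches the binned-amplitude assumption of the MI
  estimator and makes MI analytically monotone in κ.
* n_α: unit-variance Gaussian noise with a 1/f^α spectrum (α = 1
  default), band-limited to 0.3–300 Hz to mirror typical acquisition
  filtering; σ = `noise_scale` (default 0.2 of the unit theta
  amplitude).
* Optional artifacts: a 50 Hz sinusoid of amplitude `powerline_amp`
  (random phase per channel) and a baseline drift built from three
  random-phase sinusoids below 0.5 Hz scaled to RMS `drift_amp`.

Defaults (6 channels, 1 kHz, A_θ = 1, A_γ = 0.5, noise 0.2, artifacts
off) are the package's standing study conditions for validation runs;
they were chosen once as a plausible resting-state regime (prominent
theta, weaker gamma, visible 1/f floor) and are not tuned per test.

**Why the phase wander is essential.** With strictly periodic rhythms a
circular time shift of the amplitude series only rotates which phase
bin is preferred, and the modulation index is invariant under bin
relabeling — the surrogate null would inherit the full coupling and
the corrected MI would be 0 even at κ = 1. Finite-linewidth rhythms are
both the biologically realistic case and the regime in which time-shift
surrogates are meaningful.

`generate_multichannel_synchrony` drives all channels from one common
oscillatory phase at f_γ plus per-channel random-walk jitter scaled by
(1 − synchrony) (step SD 0.1 rad/sample). At synchrony = 1 the phases
are identical (pairwise PLV = 1); at 0 the channels decorrelate with a
phase-diffusion time constant of ~0.1 s. Expected PLV is monotone in
the knob because the pairwise phase-difference variance scales as
(1 − synchrony)².

The stimulation waveform generator renders a 40 Hz rectangular train
(amplitude 10 field units) holding peak for `duty_cycle` = 24% of each
period, gated into bursts occupying `burst_fraction` = 33% of each
`burst_cycle_s`. The burst repetition period is not fixed by the
hardware description the defaults emulate; it defaults to 1 s and is an
explicit parameter. How the 24% duty composes with burst gating is
likewise a convention: duty applies within bursts, the waveform is 0
between bursts.

## Preprocessing

* **Baseline drift removal**: per-channel multilevel DWT with the
  fifth-order Coiflet (`coif5`), symmetric extension; the approximation
  coefficients at the deepest level are zeroed and the signal
  reconstructed. The depth is the smallest L with fs/2^(L+1) < 0.5 Hz
  (L = 10 at 1 kHz), so the discarded band cannot touch theta. A
  recording must support that depth (≥ ~29.7 k samples at 1 kHz) or a
  length error is raised. Double application changes the output by
  < 1% RMS on drift-free inputs; with strong drift (RMS ≥ 2× signal)
  the residual boundary interaction can reach a few percent.
* **Notch**: second-order IIR notch at 50 Hz, quality factor 30,
  applied forward–backward (zero phase). Measured: ≥ 30 dB attenuation
  at 50 Hz, < 1% amplitude change at 10 Hz.
* **Epoching**: non-overlapping 4 s epochs; the trailing remainder is
  discarded and logged; a recording shorter than one epoch yields an
  empty epoch set with a warning. The acquisition-side hardware chain
  (0.3–300 Hz, gain 5000) is emulated in the generator's noise
  band-limiting, not re-applied in preprocessing.
* Order of operations: drift removal → notch → epoching.

## Spectral estimation

Welch PSD per epoch (Hamming window, 1024-sample segments ≈ 0.98 Hz
resolution at 1 kHz, 50% overlap, per-segment mean removal, one-sided
density), then averaged across epochs; epochs are the analysis unit
throughout. The segment length resolves theta while still averaging ≥ 7
segments per 4 s epoch. Band power integrates the density over
[low, high) with the density interpolated at the exact band edges,
which makes adjacent bands additive to machine precision. Canonical
bands: theta [4, 12), low gamma [30, 60), high gamma [60, 100). Group
PSD curves average channels within subject, then subjects.

## Phase–amplitude coupling

* **FIR design**: windowed-sinc (Hamming), linear phase, odd tap count
  = max(3 cycles of the band's low edge, 3.3·fs / min(bandwidth, 5 Hz)).
  The bandwidth term keeps 1 Hz phase bands at unity center gain; the
  5 Hz transition cap keeps wide amplitude bands' skirts sharp enough
  to pass modulation sidebands sitting a few Hz inside the band edges —
  with bandwidth-proportional transitions the comodulogram peak
  migrates onto single-sideband cells. Applied forward–backward (zero
  net phase), implemented as one FFT convolution with the filter's
  autocorrelation and odd reflection padding; a signal must be longer
  than 3 filter lengths. One filter length at each record edge is
  excluded from binning.
* **Bandwidth conventions**: "1 Hz" phase bands and "20 Hz" amplitude
  bands are full widths (center ± half-width).
* **MI**: 16 half-open phase bins starting at −π (+π joins the last
  bin); natural logarithms (the base cancels in the normalization).
  An empty phase bin raises an error asking for a longer record —
  occupied-bins-only renormalization is never silently substituted.
* **Surrogates**: 10 circular shifts of the amplitude series, offsets
  uniform in [fs, T − fs] samples; significant iff observed MI >
  surrogate mean + 2·SD (SD with ddof = 1); non-significant cells
  report 0. One set of offsets is shared across all comodulogram cells.
  With 10 surrogates this rule has a measured per-cell type-I error of
  ~5–15% (right-skewed null), so scattered false-positive cells in a
  corrected null comodulogram are expected; the 324-cell grid is
  essentially never entirely zero. Single-cell conclusions should rely
  on the band-summary MI, not on individual cells.
* **Comodulogram**: phase centers 4–12 Hz step 1, amplitude centers
  30–100 Hz step 2 (9 × 36 grid); cells whose amplitude band would
  cross Nyquist are recorded as missing with a warning. Band-summary
  MI over a (phase band × amplitude band) rectangle is the mean of the
  cells whose centers fall inside it (a max reduction is available via
  a flag; which of the two a given published figure used is generally
  not recoverable). PAC defaults to the concatenated continuous record
  per subject; per-epoch averaging is possible by epoching first.

## Synchrony

PLV per channel pair, computed per 4 s epoch on the band-filtered,
Hilbert-phased signal (same FIR contract as PAC, filter-length edge
exclusion per epoch) and averaged across epochs; per-epoch averaging
reduces slow-drift bias. The matrix diagonal is 1; the band mean is the
off-diagonal upper-triangle mean. Full-gamma matrices can be computed
either over [30, 100) as one band or per sub-band; both are provided. No small-sample PLV bias correction is applied: at ~4000
samples per epoch the positive bias for independent narrowband phases
is ≈ √(π/4·T·BW)⁻¹ ≈ 0.05–0.09, visible as the null floor in reported
means but negligible relative to locking of interest.

## Statistics

One-way ANOVA (scipy) with Tukey HSD pairwise adjustment
(statsmodels); repeated-measures / mixed ANOVA (pingouin) for
day-indexed designs, requiring a complete subject × timepoint grid, no
sphericity correction by default (Greenhouse–Geisser behind a flag);
t/F reconstruction from printed mean ± SD and n summaries (pooled t by
default, Welch reported alongside; for ≥ 3 groups the one-way F implied
by the summaries); box summaries with linear-interpolation quartiles
and 1.5×IQR whiskers. Stars: p < 0.05 *, < 0.01 **, < 0.001 ***. The
all-flat repeated-measures case (0/0) is reported as F = 0, p = 1.
Day-indexed tables map to repeated-measures, single-timepoint tables
to one-way; both overridable.

## Validation scale and limitations

Monte-Carlo validation uses 60 s, 6-channel, 1 kHz records and 5–10
seeds per condition — sizes at which every recovery property (MI
strictly increasing in κ, PLV strictly increasing in synchrony,
null MI non-significant, comodulogram peak within ±1/±6 Hz of ground
truth) is stable.

The generator emulates stationary resting-state signals with a single
theta and a single gamma oscillator per channel. It does not model
non-stationary bouts, asymmetric (non-sinusoidal) theta waveforms —
which are known to produce spurious PAC in real hippocampal data —
multiple simultaneous gamma generators, volume conduction, or spike
leakage. Passing the synthetic recovery tests therefore demonstrates
estimator correctness, not robustness to those real-data confounds.
Group-level inferences on real data additionally depend on electrode
placement and referencing, which are out of scope here.
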