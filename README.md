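# lfpcoupling

Theta–gamma cross-frequency coupling and synchrony analysis for
multichannel local field potential (LFP) recordings, with a synthetic
generator whose coupling and synchrony are known by construction.

Resting-state hippocampal LFP studies routinely quantify three things
from the same preprocessed signal: band power, theta–gamma
phase–amplitude coupling (PAC), and inter-channel phase synchrony.
`lfpcoupling` packages that pipeline — wavelet baseline detrending, 50 Hz
notch filtering, 4 s epoching, Welch band power, the Tort modulation
index with a circular-shift surrogate null, and phase-locking-value
(PLV) matrices — as a tested, reusable library and CLI for
electrophysiologists who want the whole chain reproducible from one
seeded configuration. Because raw animal recordings of this kind are
rarely deposited, the package ships a first-class synthetic LFP
generator so every stage can be validated against ground truth at desk
scale.

## The estimators

**Modulation index (MI).** The slow band's instantaneous phase φ(t)
(zero-phase FIR bandpass + Hilbert transform) is divided into N = 16
equal bins of 22.5°; the fast band's Hilbert envelope A(t) is averaged
within each bin and normalized to a distribution p_j. Then

    MI = (ln N − H(p)) / ln N,    H(p) = −Σ_j p_j ln p_j,

so MI = 0 for amplitude uniform over phase and MI = 1 for amplitude
concentrated in a single bin. Spurious coupling is excluded by
circularly time-shifting A(t) against φ(t) (10 surrogates, offsets
uniform in [1 s, T−1 s]); the observed MI is kept only if it exceeds the
surrogate mean + 2 SD, otherwise it is reported as 0. Comodulograms
scan MI over phase centers 4–12 Hz (1 Hz wide, 1 Hz step) × amplitude
centers 30–100 Hz (20 Hz wide, 2 Hz step).

**Phase-locking value.** For channels k, l with phases φ_k, φ_l,

    PLV = | ⟨ exp(i(φ_k(t) − φ_l(t))) ⟩_t |  ∈ [0, 1],

computed per 4 s epoch after band filtering and averaged across epochs;
matrices, band means, and phase-difference histograms (30° bins over
0–360°) are reported.

**Synthetic ground truth.** Each channel carries a theta rhythm whose
phase modulates a gamma carrier's envelope with depth κ ∈ [0, 1]
(envelope ∝ 1 − κ + κ(1+cos φ_θ)/2), a 1/f noise floor, optional 50 Hz
and drift artifacts, and an inter-channel synchrony knob ∈ [0, 1]
implemented as a shared phase plus per-channel random-walk jitter. Both
rhythms get realistic slow phase wander — without it, circular-shift
surrogates cannot destroy coupling at all (a shift would only rotate
the preferred phase bin, which MI is invariant to).

## Worked example

```python
from pathlib import Path
from lfpcoupling import RunConfig, SimConfig, run_pipeline

summary = run_pipeline(RunConfig(
    output_dir=Path("demo"),
    sim=SimConfig(duration_s=60.0, coupling_strength=0.8,
                  synchrony=0.7, seed=7),
    seed=7,
))
```

prints nothing, but the returned summary (and the CSV bundle in
`demo/`) contains:

```
epochs analysed:        15
theta x low-gamma MI:   0.000012
theta x high-gamma MI:  0.000924
mean PLV (low gamma):   0.093
mean PLV (high gamma):  0.456
band power  theta       0.4976
            low_gamma   0.0043
            high_gamma  0.0575
```

Read: with the gamma carrier at 75 Hz and κ = 0.8, the
surrogate-corrected theta×high-gamma MI is two orders of magnitude
above theta×low-gamma (which is null-level); the synchrony knob at 0.7
locks the 75 Hz carrier across channels (high-gamma PLV 0.46) while
low-gamma PLV stays at its independent-noise floor (~0.09); and band
power concentrates in theta with the smaller gamma carrier split
between sub-bands. `demo/` also holds the comodulogram CSV + heatmap,
PLV matrices per band, the preprocessed recording (HDF5), and a
provenance sidecar (config hash, seed, package version).

The same chain is available from the shell:

```sh
lfpcoupling simulate --duration 60 --coupling 0.8 --seed 7 -o rec.h5
lfpcoupling pac rec.h5 --phase-band 4 12 --amp-band 60 100 --seed 7 -o pac/
lfpcoupling plv rec.h5 --band 30 60 -o plv/
lfpcoupling stats groups.csv --design oneway -o stats/
lfpcoupling run --config run.toml
```

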