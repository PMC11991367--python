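# Methods

## Synthetic ECG generator

One beat is modelled as six localized wave components — P, Q, R, S, T, U — on
a flat isoelectric baseline, each a Gaussian bump
`a · exp(−(t − c)² / (2w²))` with amplitude `a` (mV), center `c` and width `w`
as fractions of the beat. The default template is

| wave | amplitude (mV) | center | width |
|------|---------------|--------|-------|
| P | 0.10 | 0.20 | 0.025 |
| Q | −0.12 | 0.36 | 0.010 |
| R | 1.00 | 0.40 | 0.012 |
| S | −0.20 | 0.44 | 0.010 |
| T | 0.25 | 0.62 | 0.040 |
| U | 0.04 | 0.78 | 0.030 |

chosen so that the R wave dominates, centers strictly increase and the U wave
stays below 0.05 mV — the qualitative morphology of a normal sinus beat. The
beat is periodic by construction (bump distances wrap around the beat
boundary; samples sit at phases `(i + ½)/n`), so the same waveform can be
reconstructed from its Fourier harmonics; `synthesize_beat(fourier_terms=K)`
exposes that truncated-series view (`K ≥ n/2` reproduces the bump sum
exactly, the default `n = 90` at 250 Hz giving a 0.36 s beat). Defaults: 90
samples per beat and a 250 Hz sampling rate, inside the usual 200–500 Hz
range for diagnostic ECG.

Datasets are independent Gaussian-noise realizations of the one clean beat:
`noisy = clean + noise_factor · ε`, `ε ~ N(0, I)`, with `noise_factor` the
noise standard deviation in normalized amplitude units. Normalization
(default: batch min/max to [−1, 1]; z-scoring and none also available)
records its affine parameters so inversion is exact to 1e-12. Splitting is
80/10/10 by default, with val/test rounded to nearest and train absorbing the
remainder. A master seed fans out one `SeedSequence` child per signal, so a
dataset is reproducible and each signal independent of how many are drawn.

What the generator does **not** emulate: multi-beat rhythms and heart-rate
variability, baseline wander, electrode motion artifacts, powerline
interference, or pathological morphologies. Passing tests therefore
demonstrate the watermarking pipeline's behaviour under controlled Gaussian
perturbations of a stereotyped beat, not performance on clinical recordings.

## VAE

Encoder 90 → 128 → 64 → 2×20 (mean and log-variance), decoder 20 → 64 → 128 →
90, ReLU after hidden affine layers, identity outputs (signals live near
[−1, 1] but may exceed it slightly; no output squashing). The loss is
`MSE(x, x̂) + β · KL(q(z|x) ‖ N(0, I))` with the reconstruction averaged over
samples and batch and the KL summed over latent dimensions, averaged over the
batch — this keeps β = 1 meaningful at latent dimension 20. The network is
implemented directly in numpy with hand-derived gradients, verified against
central finite differences in the test suite; the model is small enough that
this outperforms any framework overhead and guarantees bit-level determinism
under a fixed seed (initialization, shuffling and reparameterization draws
all derive from one `SeedSequence`).

Training defaults: Adam (β₁ = 0.9, β₂ = 0.999) at learning rate 0.001, batch
32, 400 epochs, β = 1. Adam is the package's optimizer choice for stable
convergence within the epoch budget; plain SGD is available via
`VAEConfig(optimizer="sgd")`. Optional early stopping (patience 50 on
validation loss) is off by default so the fixed-epoch runs are exactly
reproducible. Weight init is He (fan-in) for the ReLU stacks, zero biases.

**Training-set size.** Epochs and batch size fix only the number of optimizer
steps per epoch times the dataset size. The experiment sweeps train on 1000
signals (800 train → 25 batches/epoch → 10 000 updates over 400 epochs),
which reliably reaches reconstruction MSE below 1e-6 on noiseless data;
much smaller datasets leave the optimizer short of convergence at the same
epoch count.

**Posterior collapse is a feature here.** On this data family (noise
realizations of one beat) the VAE needs almost no latent code: the posterior
collapses toward the prior and the decoder learns to ignore most latent
coordinates. That is precisely why the latent-mean strategy barely perturbs
the output (its MSE is insensitive to α and to the latent dimension) — and,
conversely, why re-encoding a watermarked signal cannot recover the latent
shift (see limitations).

## Watermarking

All strategies are non-blind: the `EmbedRecord` stores the original reference
(μ, z, or spectral magnitudes) and, for the latent strategies, the
watermarked carrier. Bits occupy latent coordinates 0..L−1 (configurable);
extraction computes `(carrier − reference)/α` and thresholds at ½ (midpoint
rule for 0/1 payloads). Stored-reference extraction is the exact algebraic
inverse of embedding — BER is 0 for any payload and any α > 0, which the
property tests assert. A `reencode` extraction mode re-encodes the suspect
signal instead, mirroring a verification workflow without stored carriers;
it is approximate (see limitations) and its BER is reported, never assumed.

Frequency-domain embedding operates on the DFT of the reconstruction. A bit
shifts the total spectral magnitude of its conjugate bin pair by α — each of
the two bins moves by α/2, up for bit 1, down for bit 0 (floored at 1e-9 so
magnitudes stay positive) — with phase preserved and conjugate symmetry
maintained, so the inverse transform is real to numerical precision. This
convention equals modifying the single positive-frequency coefficient by α
and keeping the real part, and by Parseval adds exactly
`L·α²/(2n²)` to the time-domain MSE when no bin floors — about 6.2e-4·α² at
L = 10, n = 90, which is what keeps the frequency strategy's α-influence on
MSE below 1e-3 across α ∈ {0.1, 0.5, 0.9}. Default bins are half-spectrum
indices 2..L+1 (skipping DC and the fundamental); the DC and Nyquist bins are
rejected. Extraction compares the suspect's magnitudes against the stored
reference: above → bit 1, otherwise bit 0.

## Metrics

MSE is the plain mean of squared differences. DTW uses the classic
unconstrained dynamic program with absolute-difference local cost and
anchored endpoints; an optional Sakoe–Chiba window is exposed but off by
default. DTW is not a metric (the triangle inequality fails), so experiment
tables only rely on its nonnegativity and monotone response to noise. The
implementation is validated against exhaustive alignment-path enumeration on
short integer signals. SNR is `−10·log10(Σ(ŝ−s)²/Σs²)` dB, returning +∞ for
a perfect reconstruction rather than erroring; BER operates on hard bits
(continuous extractions are thresholded upstream).

## Sensor filter chain

Stages are order-2 Butterworth filters designed by bilinear transform at the
dataset sample rate: high-pass 1 Hz, band-pass 5–20 Hz, low-pass 10 Hz.
Butterworth order 2 is the conventional choice for ECG front-end modelling
(maximally flat passband, smooth Bode magnitude). Application is causal
(`lfilter`) by default, as in a physical analog chain; zero-phase
(`filtfilt`) is available behind a flag. The Bode response evaluates each
stage on a 256-point log-spaced grid over [0.1, 100] Hz and multiplies
complex responses, reporting magnitude in dB and unwrapped phase in degrees.
The chain's absolute gain is reproduced in shape only; no attenuator stage is
modelled.

Watermark survival through the chain is a reported quantity, not a
guarantee: frequency-domain extraction compares attenuated magnitudes against
unattenuated references, so a passband gain g defeats a bit-1 whenever
`g < |X|/(|X| + α/2)`. The survival test constructs the configuration where
passband transparency is sufficient (carrier magnitudes at or below α/2).

## Experiments

Sweeps cover α ∈ {0.1, 0.5, 0.9}, latent dimensions {10, 20, 30} and noise
factors {0.1, 0.3, 0.5}, with 5 seeds by default and per-cell seeds derived
order-independently from the master seed. Noise-sweep rows compare (a) the
first training signal, (b) the mean of all training signals and (c) the
watermarked reconstruction, reporting pairwise MSE and DTW. The z strategy
embeds with a fresh seeded reparameterization draw (its variability under
sampling is the point of that comparison); the μ strategy uses the
deterministic ε = 0 draw; the frequency strategy perturbs the ε = 0
reconstruction. Aggregates report median and inter-seed range.

## Known limitations

* **Re-encode extraction does not work in this regime.** Because the decoder
  prunes the latent coordinates that carry the watermark, encode(decode(·))
  erases the latent shift: the re-encoded mean difference is numerically zero
  and re-encode BER is at chance or worse. This is structural — the very
  collapse that makes the μ strategy imperceptible removes the information a
  blind-ish re-encoding would need. The mode is kept for completeness and its
  BER is always reported alongside the stored-reference result.
* Degenerate noiseless datasets make all signals identical; the VAE then
  memorizes one waveform, which is the intended stress case for
  watermark-fidelity measurements but says nothing about generative variety.
* SNR magnitudes in the BER table depend on the synthetic signals and the
  per-row reparameterization draws; they characterize this pipeline, not any
  external recording.
* The DTW implementation is O(n·m) Python/numpy; fine at n = 90, not intended
  for long multi-beat records.
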