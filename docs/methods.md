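# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the VMD–SSA–SVD denoising pipeline, in the order the
method runs.

## Variational mode decomposition

The decomposition solves the standard penalised variational problem in the
frequency domain by ADMM. Each iteration updates mode k's half-band spectrum
with a Wiener filter centred on its current centre frequency,

    u_k(ω) ← (f(ω) − Σ_{i≠k} u_i(ω) − λ(ω)/2) / (1 + α (ω − ω_k)²),

then moves ω_k to the power-weighted centroid of |u_k|², and finally (when
the fidelity step τ ≠ 0) performs dual ascent on λ. The denominator uses
α(ω−ω_k)², the convention of the reference implementation that the
literature's customary α ranges (hundreds to thousands) assume.

Choices:

- **τ = 0, tol = 1e-7, max_iter = 500.** With τ = 0 the reconstruction
  constraint is soft, which is what makes VMD noise-robust (the residual is
  mostly noise). These are the conventional defaults.
- **Boundary handling.** The signal is mirror-extended by half its length on
  each side and cropped after decomposition; this suppresses the edge
  artefacts of circular convolution. Internal FFTs use the mirrored length
  as-is (no power-of-two padding): correctness over speed; the hot loop is
  compiled with numba anyway.
- **Mode order.** Modes are re-sorted by ascending centre frequency after
  convergence, so mode 0 is always the lowest-frequency (baseline-carrying)
  component. The extraction order of the ADMM has no meaning of its own.
- **Initialisation.** Centre frequencies start uniformly spaced over the
  half-band (deterministic); zero and seeded-random initialisation are
  available. `dc_mode` pins ω_0 = 0 but is off by default — the drift is
  captured by a low-but-nonzero-frequency mode and handled by the mean
  criterion instead.
- **Centroid bias.** Spectral-centroid frequency estimates of very low
  tones (≲ 5 Hz on short records) carry a small negative bias from leakage
  and mirroring, about 1–2%; irrelevant for mode partitioning, visible in
  tone-recovery tests.

## Sparrow search and the envelope-entropy fitness

K and α are integers searched over [2, 15] × [500, 5000] with the canonical
three-role sparrow search (producers with exponential-decay moves under a
random alarm value, scroungers following the best producer or fleeing the
worst position, and a 10% scout fraction relocated each iteration);
producer fraction 0.2, safety threshold 0.8, population 30, 15 iterations.
Positions are clamped to bounds and integer dimensions rounded after every
move, so the fitness is only ever evaluated at feasible integer pairs, and
those evaluations are memoised — the search typically touches 100–300
distinct grid points out of ~500 evaluations. Ties on fitness keep the
earlier position; the recorded convergence curve tracks the global best and
is non-increasing by construction.

The fitness of a candidate (K, α) is the minimum across modes of the
envelope entropy: with a_i = |hilbert(u)_i| and p_i = a_i/Σa,
H = −Σ p_i ln p_i. A mode that isolates sparse, coherent structure (QRS
spikes) has a concentrated envelope and low entropy; flat-envelope tones
score the maximum ln N and noise-like modes score high. The mean across
modes is available as an alternative aggregate. Note that because the
envelope is the analytic-signal magnitude, a single impulse does not reach
entropy zero — the discrete Hilbert kernel spreads it — it is merely far
below the flat-envelope maximum.

On realistic ECG fixtures this fitness landscape is nearly flat (a range of
~0.3 nats across the whole box) and its minimum tends to sit at small K and
small α, because a broad low-α mode containing the full QRS train has the
sparsest envelope. This matters for end-to-end quality; see Limitations.

## Baseline rejection and effective-mode selection

A mode whose absolute mean exceeds a threshold carries the drifted isoline.
The default threshold is scale-aware: 3 × |mean of the linearly detrended
record|, floored at 0.02 mV. The flagged modes' sum is the drift estimate
and is also subtracted from the original signal before the correlation
step — computing ρ against the raw drift-dominated input would compress all
correlations into the range where the threshold formula rejects everything.

The interrelation number is the product-moment correlation; the threshold
μ = max(ρ)/(10·max(ρ) − 3) is defined for max(ρ) > 0.3 and satisfies
μ ≤ max(ρ) exactly when max(ρ) ≥ 0.4, so the top mode always survives in
that regime. Below max(ρ) = 0.3 the formula is singular; the library raises
a diagnosable error and the pipeline falls back to a fixed μ = 0.1
(configurable). ρ is compared signed, as the formula is written; an
absolute-value comparison is available behind a flag. Ties (ρ = μ) count as
effective so floating-point equality never drops a mode.

## Hankel/SVD denoising

Each effective mode is embedded in a near-square Hankel matrix
(p = n//2 + 1 rows — near-square maximises subspace separability), its SVD
taken, and singular values beyond a cut-off zeroed; the rank-reduced matrix
is projected back to a sequence by anti-diagonal averaging, the standard
inverse of the embedding.

- **Order selection.** The difference spectrum d_i = σ_i − σ_{i+1} peaks
  wherever a group of strong components ends. For a lone oscillation there
  is a single dominant peak and the cut-off is its position (rank 2 for one
  real sinusoid, 4 for two, and so on). A quasi-periodic mode, however,
  contains one singular-value *pair per beat harmonic* with unequal
  strengths, so the largest single gap usually falls inside the signal
  group and truncating there amputates half the mode's energy. The cut-off
  is therefore the **last** peak within 0.1 of the maximum peak — the
  demarcation between the whole signal group and the noise floor — which
  reduces to the plain argmax whenever one gap dominates.
- **Guard.** If the selected order is the last possible one, no noise floor
  was found and the block is returned unmodified (with a warning) rather
  than truncated arbitrarily.
- **Windowing.** Sequences longer than 5 000 samples are processed in
  50%-overlapping windows of 2 048 samples, crossfaded with a linear ramp,
  bounding the cubic SVD cost; the result stays deterministic.
- **Energy.** Truncation always lowers the Frobenius norm, which makes the
  averaging non-expansive in the anti-diagonal-count-weighted norm. In the
  plain sequence norm an adversarial (pure white noise) input can gain a
  fraction of a percent of energy through the single-element edge
  diagonals; on oscillatory inputs the plain-norm energy decreases in every
  seeded trial we run.

## Synthetic data

The generators define the study conditions and are pure functions of
(parameters, seed):

- **Three-tone test signal**: sin(2π·6t) + 1.2·cos(2π·55t) +
  1.4·sin(2π·180t) + Gaussian noise. The noise level of the classical
  version of this fixture is not standardised; it is exposed as `noise_sd`
  (default 0.1 mV).
- **Synthetic ECG**: a Gaussian-bump P–QRS–T template repeated at the beat
  period with 1% beat-to-beat timing and amplitude jitter, mean-centred.
  Defaults: 72 bpm; P (0.15 mV, −0.20 s, σ 25 ms), Q (−0.10, −0.035, 10),
  R (1.00, 0, 12), S (−0.25, 0.035, 10), T (0.30, 0.30, 60) — textbook
  lead-II proportions. This is a morphological stand-in, not a dynamical
  heart model: no arrhythmia, no respiratory modulation, no waveform
  variability beyond the jitter. Passing tests therefore demonstrate the
  mechanics of mode partitioning and denoising, not clinical performance.
- **Baseline wander**: amplitude·sin(2πft) + offset, default 0.4 mV at
  0.5 Hz. The benchmark adds a 0.3 mV DC offset, emulating the electrode
  half-cell isoline of raw recordings; a pure zero-mean sinusoid over an
  integer number of periods would be invisible to any mean-value criterion,
  which in real recordings engages precisely because the isoline is offset.
- **Calibrated noise**: white Gaussian noise normalised by its realised
  sample power, so the measured SNR equals the request to machine
  precision.
- **Benchmark protocol** (`make_noisy_ecg_benchmark`): clean 360 Hz / 10 s
  ECG + drift (with offset) + white noise at 10 dB relative to the clean
  ECG. The resulting corrupted record sits near −7.6 dB overall because the
  drift dominates the error power.

## Problem sizes

The test suite and the acceptance script run the full sparrow-optimised
pipeline on ten seeds of the 3 600-sample benchmark, 20-seed sphere-function
batteries, and 20-seed SVD gain measurements; unit tests use 300–2 000
sample fixtures and reduced search budgets (population 6–10, 3–5
iterations) where the full budget adds nothing to the property under test.

## Limitations

- **Drift-band overlap bounds the achievable SNR.** About 8% of the
  synthetic ECG's power lies below 2.5 Hz (T/P waves and the 1.2 Hz beat
  fundamental). The lowest VMD mode inevitably captures part of that band
  together with the drift, and discarding it discards that signal content:
  with the *best* fixed (K, α) on the benchmark the output SNR is capped
  near 12 dB, independent of later stages. This is the classical spectral
  overlap between baseline wander and the ST/T band, and it is the
  dominant error term of the method on this benchmark — the removed
  content still correlates with the injected drift at r > 0.9, i.e. the
  drift itself is recovered well.
- **The envelope-entropy fitness does not optimise SNR.** Its minimum on
  the benchmark sits at K ≈ 5, α ≈ 500–700 (verified by exhaustive grid
  search), which costs several dB against the best fixed parameters. The
  fitness is kept as specified; fixing (K, α) by hand is supported.
- **SVD stage is neutral-at-best on already-clean modes.** After VMD and
  correlation selection the in-mode SNR is high (~23 dB on the benchmark),
  so rank truncation can only remove signal; the demarcation-seeking order
  selection keeps the loss small but not zero (a clean-input pipeline run
  retains correlation ≈ 0.98 with its input).
- **WFDB support is the MIT-BIH dialect only**: format 212, one or two
  channels, gain/baseline applied; no multi-segment records, no
  annotations.
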