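# ecgdenoise

Removal of baseline wander and broadband noise from single-channel ECG
recordings by **sparrow-search-optimised variational mode decomposition with
per-mode Hankel/SVD noise reduction** (VMD–SSA–SVD).

ECG signals are weak, low-frequency and easily corrupted: respiration and
electrode motion add a slow baseline drift that overlaps the ST segment in
frequency, and equipment/muscle activity adds broadband noise. Plain
filtering distorts the waves; this package instead decomposes the recording
into narrow-band intrinsic mode functions, identifies which modes carry the
drifted isoline, which carry cardiac structure, and which carry noise, and
cleans the retained modes individually before reconstruction. It is intended
for biomedical-signal researchers who want a tested, reproducible reference
implementation with synthetic fixtures, not a clinical device.

## Method

1. **VMD.** The signal f is split into K band-limited modes u_k with centre
   frequencies ω_k by minimising Σ_k ‖∂_t[(δ(t) + j/πt) ∗ u_k] e^{−jω_k t}‖²
   subject to Σ u_k ≈ f, solved by frequency-domain ADMM (Wiener-filter mode
   updates, centroid frequency updates, dual ascent). The penalty α sets
   mode bandwidth; larger α gives narrower modes.
2. **Parameter selection.** K ∈ [2, 15] and α ∈ [500, 5000] (integers) are
   chosen by the sparrow search algorithm (population 30, 15 iterations),
   minimising the **envelope entropy** fitness: the Shannon entropy of the
   normalised analytic-signal envelope, minimised over the K modes. Sparse,
   structured components score low; noise-like components score high.
3. **Baseline rejection.** Modes whose absolute mean exceeds a threshold
   carry the drifted isoline and are discarded; their sum is the drift
   estimate.
4. **Effective-mode selection.** Each remaining mode's interrelation number
   (product-moment correlation) ρ with the drift-removed signal is compared
   with the threshold μ = max(ρ) / (10·max(ρ) − 3); modes with ρ ≥ μ are
   retained, the rest rejected as noise.
5. **SVD denoising.** Each retained mode is embedded in a near-square Hankel
   matrix H = UΣVᵀ; the retained order is read off the singular value
   difference spectrum d_i = σ_i − σ_{i+1}, the remaining singular values
   are zeroed and the sequence is rebuilt by anti-diagonal averaging.
6. **Evaluation.** Against a clean reference x and estimate x̃:
   SNR = 10·log₁₀(Σx²/Σ(x−x̃)²) dB, MSE = (1/N)Σ(x−x̃)².

Everything needed to exercise the pipeline is generated on the fly: a
three-tone validation signal, a parametric Gaussian-bump P–QRS–T ECG,
sinusoidal baseline wander (0.4 mV at 0.5 Hz by default) and SNR-calibrated
white noise. Real recordings are read from CSV or WFDB (MIT-BIH dialect,
format 212) files.

## Worked example

```python
from ecgdenoise import make_noisy_ecg_benchmark, denoise, PipelineConfig, snr_db

clean, noisy, drift = make_noisy_ecg_benchmark(seed=1)   # 360 Hz, 10 s
print(f"input SNR: {snr_db(clean, noisy):.2f} dB")
report = denoise(noisy, PipelineConfig(seed=1), clean_reference=clean)
print(f"selected K={report.params_used[0]}, alpha={report.params_used[1]}")
print(f"baseline modes: {sorted(report.selection.baseline_idx)}, "
      f"effective: {sorted(report.selection.effective_idx)}")
print(f"output SNR: {report.snr_db:.2f} dB, output MSE: {report.mse:.4f}")
```

prints

```
input SNR: -7.57 dB
selected K=5, alpha=702
baseline modes: [0], effective: [1, 2, 3, 4]
output SNR: 3.82 dB, output MSE: 0.0125
```

The corrupted record starts at −7.6 dB because the 0.4 mV drift (riding on a
0.3 mV electrode offset) dominates the error power. The sparrow search picks
(K, α) by envelope entropy, the lowest mode (centre frequency ≈ 0.2 Hz,
nonzero mean) is identified as baseline drift and dropped, and the retained
modes are SVD-cleaned and summed — an 11.4 dB improvement, with the removed
content correlating with the injected drift at r ≈ 0.92. See
`docs/methods.md` for why the absolute output SNR is bounded by the spectral
overlap between drift and the ECG's own sub-2.5 Hz content.

The same pipeline is available from the shell:

```sh
ecgdenoise simulate --record synthetic --snr-db 10 --seed 1 --out sim/
ecgdenoise denoise --input sim/noisy.csv --reference sim/clean.csv \
    --seed 1 --out results/
ecgdenoise optimize --input sim/noisy.csv --pop 30 --iters 15 \
    --seed 1 --out convergence.csv
```

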