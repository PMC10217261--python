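"""Synthetic signal generators: test tones, parametric ECG, baseline wander
and SNR-calibrated white noise.

Every generator is a pure function of its parameters and seed, so the whole
pipeline can be exercised without downloading any recordings. The ECG
generator builds a quasi-periodic P-QRS-T beat from Gaussian bumps; it is a
morphological stand-in for a real recording, not a dynamical heart model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Signal

__all__ = [
    "EcgMorphology",
    "gen_test_signal",
    "gen_synthetic_ecg",
    "gen_baseline_wander",
    "add_noise_at_snr",
    "make_noisy_ecg_benchmark",
]

#: frequencies (Hz) and amplitudes (mV) of the three-tone validation signal
TEST_TONES = ((6.0, 1.0, np.sin), (55.0, 1.2, np.cos), (180.0, 1.4, np.sin))


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump of the beat template."""

    amplitude: float  # mV, signed
    offset: float     # s, centre relative to the R peak
    width: float      # s, Gaussian sigma


@dataclass(frozen=True)
class EcgMorphology:
    """Parametric description of one heartbeat.

    Amplitudes in mV, offsets/widths in seconds relative to the R peak.
    Defaults approximate a lead-II adult beat at rest.
    """

    heart_rate: float = 72.0  # beats per minute
    p: Wave = field(default_factory=lambda: Wave(0.15, -0.20, 0.025))
    q: Wave = field(default_factory=lambda: Wave(-0.10, -0.035, 0.010))
    r: Wave = field(default_factory=lambda: Wave(1.00, 0.0, 0.012))
    s: Wave = field(default_factory=lambda: Wave(-0.25, 0.035, 0.010))
    t: Wave = field(default_factory=lambda: Wave(0.30, 0.30, 0.060))

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def waves(self) -> tuple[Wave, ...]:
        return (self.p, self.q, self.r, self.s, self.t)

    def validate(self) -> None:
        if not self.heart_rate > 0:
            raise ValueError(f"heart_rate must be > 0, got {self.heart_rate}")
        for name, w in zip("pqrst", self.waves):
            if not w.width > 0:
                raise ValueError(f"{name}-wave width must be > 0, got {w.width}")
        # the 3-sigma support of the whole template must fit in one beat,
        # otherwise consecutive beats overlap
        lo = min(w.offset - 3.0 * w.width for w in self.waves)
        hi = max(w.offset + 3.0 * w.width for w in self.waves)
        if hi - lo > self.beat_period:
            raise ValueError(
                f"beat template spans {hi - lo:.3f}s, overlapping beyond one "
                f"beat period of {self.beat_period:.3f}s"
            )


def gen_test_signal(fs: float, duration: float, noise_sd: float = 0.1,
                    seed: int = 0) -> Signal:
    """Three-tone validation signal: sin(2*pi*6t) + 1.2 cos(2*pi*55t)
    + 1.4 sin(2*pi*180t) + Gaussian noise of standard deviation ``noise_sd``.

    ``fs`` must satisfy Nyquist for the 180 Hz tone (fs >= 360 Hz).
    """
    if fs < 2 * 180.0:
        raise ValueError(
            f"fs={fs} Hz is below the Nyquist rate of 360 Hz required by the 180 Hz tone"
        )
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for freq, amp, fn in TEST_TONES:
        x += amp * fn(2.0 * np.pi * freq * t)
    if noise_sd:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n)
    return Signal(x, fs, label="three-tone test signal")


def gen_synthetic_ecg(fs: float, duration: float,
                      morphology: EcgMorphology | None = None,
                      seed: int = 0, rr_jitter: float = 0.01,
                      amp_jitter: float = 0.01) -> Signal:
    """Quasi-periodic synthetic ECG built from a Gaussian-bump beat template.

    The template (P, Q, R, S, T bumps) repeats at the beat period with small
    seeded beat-to-beat timing and amplitude jitter (fractional standard
    deviations ``rr_jitter`` and ``amp_jitter``). The record is mean-centred
    so the isoline is at zero; the R amplitude is preserved relative to that
    isoline.
    """
    morph = morphology or EcgMorphology()
    morph.validate()
    period = morph.beat_period
    if duration < 2 * period:
        raise ValueError(
            f"duration {duration}s covers fewer than 2 beats at {morph.heart_rate} bpm"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    rng = np.random.default_rng(seed)
    n_beats = int(np.ceil(duration / period)) + 1
    r_time = period / 2.0  # first R peak half a period in
    for _ in range(n_beats):
        gain = 1.0 + amp_jitter * rng.standard_normal()
        for w in morph.waves:
            if w.amplitude == 0.0:
                continue
            c = r_time + w.offset
            x += gain * w.amplitude * np.exp(-0.5 * ((t - c) / w.width) ** 2)
        r_time += period * (1.0 + rr_jitter * rng.standard_normal())
    if np.any(x):
        x = x - np.mean(x)
    return Signal(x, fs, label=f"synthetic ECG {morph.heart_rate:g} bpm")


def gen_baseline_wander(fs: float, duration: float, amplitude: float = 0.4,
                        freq: float = 0.5, offset: float = 0.0) -> Signal:
    """Sinusoidal baseline drift: amplitude*sin(2*pi*freq*t) + offset.

    Defaults follow the standard ECG corruption protocol (0.4 mV at 0.5 Hz).
    ``offset`` models the DC isoline shift of raw recordings; it is what makes
    the drift component detectable by a mean-value criterion.
    """
    if freq >= fs / 2:
        raise ValueError(f"drift frequency {freq} Hz violates Nyquist at fs={fs} Hz")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return Signal(amplitude * np.sin(2.0 * np.pi * freq * t) + offset, fs,
                  label=f"baseline wander {amplitude:g} mV @ {freq:g} Hz")


def add_noise_at_snr(clean: Signal, snr_db: float, seed: int = 0) -> Signal:
    """Add white Gaussian noise so the measured SNR of (clean, clean+noise)
    equals ``snr_db`` exactly.

    The noise realisation is normalised by its own sample power, so
    10*log10(sum x^2 / sum n^2) hits the request to machine precision.
    """
    p_clean = clean.power()
    if p_clean == 0.0:
        raise ValueError("SNR is undefined for an all-zero clean signal")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(len(clean))
    p_target = p_clean * 10.0 ** (-snr_db / 10.0)
    w *= np.sqrt(p_target / np.mean(w ** 2))
    return clean.with_samples(clean.samples + w,
                              label=f"{clean.label} + noise @ {snr_db:g} dB")


def make_noisy_ecg_benchmark(fs: float = 360.0, duration: float = 10.0,
                             snr_db: float = 10.0, drift_amplitude: float = 0.4,
                             drift_freq: float = 0.5, drift_offset: float = 0.3,
                             heart_rate: float = 72.0, seed: int = 0):
    """Standard corruption protocol used throughout the tests.

    Returns ``(clean, noisy, drift)`` where ``noisy = clean + drift + noise``:
    a synthetic ECG, a 0.4 mV / 0.5 Hz sinusoidal baseline wander riding on a
    DC isoline offset, and white noise calibrated to ``snr_db`` against the
    clean ECG.
    """
    morph = EcgMorphology(heart_rate=heart_rate)
    clean = gen_synthetic_ecg(fs, duration, morph, seed=seed)
    drift = gen_baseline_wander(fs, duration, drift_amplitude, drift_freq,
                                offset=drift_offset)
    noisy_part = add_noise_at_snr(clean, snr_db, seed=seed + 1)
    noise = noisy_part.samples - clean.samples
    noisy = clean.with_samples(clean.samples + drift.samples + noise,
                               label="corrupted synthetic ECG")
    return clean, noisy, drift
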