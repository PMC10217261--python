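import numpy as np
import pytest

from ecgdenoise import (Signal, gen_test_signal, make_noisy_ecg_benchmark,
                        vmd_decompose, VMDParams)


@pytest.fixture(scope="session")
def eq1_clean():
    """Noise-free three-tone test signal at 1 kHz for one second."""
    return gen_test_signal(fs=1000, duration=1.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def eq1_noisy():
    return gen_test_signal(fs=1000, duration=1.0, noise_sd=0.1, seed=7)


@pytest.fixture(scope="session")
def eq1_small():
    """Short, low-rate three-tone signal for expensive parameter sweeps."""
    return gen_test_signal(fs=500, duration=0.6, noise_sd=0.1, seed=7)


@pytest.fixture(scope="session")
def ecg_benchmark():
    """(clean, noisy, drift) triple of the standard corruption protocol."""
    return make_noisy_ecg_benchmark(seed=1)


@pytest.fixture(scope="session")
def benchmark_modes(ecg_benchmark):
    """Fixed-parameter decomposition (K=11, alpha=3194) of the noisy benchmark."""
    _, noisy, _ = ecg_benchmark
    return vmd_decompose(noisy, VMDParams(K=11, alpha=3194))


def tone(freq, fs, duration, amp=1.0, phase=0.0):
    t = np.arange(int(round(fs * duration))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)
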