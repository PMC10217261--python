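"""Mode selection: partition VMD modes into baseline-drift, effective and
noise groups.

Baseline-carrying modes are flagged first by the mean-value criterion (a
mode whose absolute mean exceeds a threshold carries the drifted isoline).
Among the remaining modes, the interrelation number rho of each mode with
the original signal (the product-moment correlation) is compared with the
data-driven threshold

    mu = max(rho) / (10 * max(rho) - 3),

valid for max(rho) > 0.3: modes with rho >= mu are kept as effective, the
rest are rejected as noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import detrend

from .core import Signal
from .vmd import ModeSet

__all__ = ["SelectionResult", "ThresholdError", "interrelation_number",
           "selection_threshold", "flag_baseline_modes",
           "select_effective_modes", "default_mean_threshold"]


class ThresholdError(ValueError):
    """The correlation threshold formula is undefined (max rho <= 0.3)."""


@dataclass(frozen=True)
class SelectionResult:
    """Partition of mode indices with the statistics that produced it.

    ``rho`` is NaN for baseline-flagged modes (they are excluded from the
    correlation pool before the threshold is computed).
    """

    baseline_idx: frozenset[int]
    effective_idx: frozenset[int]
    noise_idx: frozenset[int]
    rho: np.ndarray            # per-mode interrelation number (NaN if baseline)
    mu: float                  # threshold applied to rho
    mean_values: np.ndarray    # per-mode means (mV)
    mean_threshold: float      # mV

    @property
    def K(self) -> int:
        return self.mean_values.size

    def to_dict(self) -> dict:
        return {
            "baseline_idx": sorted(self.baseline_idx),
            "effective_idx": sorted(self.effective_idx),
            "noise_idx": sorted(self.noise_idx),
            "rho": [None if np.isnan(r) else float(r) for r in self.rho],
            "mu": float(self.mu),
            "mean_values": [float(m) for m in self.mean_values],
            "mean_threshold": float(self.mean_threshold),
        }


def interrelation_number(x: Sequence[float], y: Sequence[float]) -> float:
    """Normalised cross-moment of two equal-length series (Pearson form):

        rho = sum (x - xbar)(y - ybar) / sqrt(sum (x-xbar)^2 sum (y-ybar)^2)

    Lies in [-1, 1]; undefined (rejected) if either series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"inputs must be equal-length 1-D, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("interrelation number is undefined for zero-variance input")
    r = float(dx @ dy) / np.sqrt(sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def selection_threshold(rho: Sequence[float]) -> float:
    """Threshold mu = max(rho) / (10*max(rho) - 3).

    Defined only for max(rho) > 0.3 (the denominator must be positive);
    below that, raise :class:`ThresholdError` advising a fixed fallback.
    """
    r = np.asarray(rho, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one interrelation number")
    rmax = float(np.nanmax(r))
    if rmax <= 0.3:
        raise ThresholdError(
            f"threshold formula max(rho)/(10*max(rho)-3) is undefined for "
            f"max(rho)={rmax:.4f} <= 0.3; use a fixed fallback threshold "
            f"(e.g. mu=0.1) instead"
        )
    return rmax / (10.0 * rmax - 3.0)


def default_mean_threshold(original: Signal, floor: float = 0.02) -> float:
    """Scale-aware default for the baseline mean criterion (mV).

    Three times the absolute mean of the linearly detrended record, floored
    at ``floor`` mV; conservative for any zero-ish-mean recording.
    """
    resid = detrend(original.samples, type="linear")
    return max(3.0 * abs(float(np.mean(resid))), floor)


def flag_baseline_modes(modeset: ModeSet, mean_threshold: float) -> frozenset[int]:
    """Indices of modes whose absolute mean exceeds ``mean_threshold`` —
    the components carrying the drifted isoline."""
    means = modeset.modes.mean(axis=1)
    return frozenset(int(i) for i in np.flatnonzero(np.abs(means) > mean_threshold))


def select_effective_modes(modeset: ModeSet, original: Signal,
                           mean_threshold: float | None = None,
                           rho_mode: str = "signed",
                           mu_fallback: float | None = None) -> SelectionResult:
    """Full three-way partition of a mode set.

    1. flag baseline modes by the mean criterion and subtract their sum
       from ``original`` (the drift estimate is removed first, so the
       correlations are not dominated by the drift);
    2. correlate every remaining mode with the drift-removed original
       (interrelation number);
    3. derive the threshold mu from the maximum correlation;
    4. keep modes with rho >= mu as effective, reject the rest as noise.

    ``rho_mode="absolute"`` compares |rho| instead of signed rho.
    ``mu_fallback`` (if given) replaces mu when the threshold formula is
    undefined; otherwise the :class:`ThresholdError` propagates.
    """
    if len(modeset.modes[0]) != len(original):
        raise ValueError("mode set was not derived from this signal (length mismatch)")
    if rho_mode not in ("signed", "absolute"):
        raise ValueError(f"unknown rho_mode {rho_mode!r}")
    K = modeset.K
    if mean_threshold is None:
        mean_threshold = default_mean_threshold(original)

    means = modeset.modes.mean(axis=1)
    baseline = flag_baseline_modes(modeset, mean_threshold)
    remaining = [i for i in range(K) if i not in baseline]
    if not remaining:
        raise ValueError(
            f"all {K} modes were flagged as baseline drift "
            f"(mean threshold {mean_threshold:g} mV); nothing left to denoise"
        )

    reference = original.samples
    if baseline:
        reference = reference - modeset.modes[sorted(baseline)].sum(axis=0)

    rho = np.full(K, np.nan)
    for i in remaining:
        mode = modeset.modes[i]
        if np.ptp(mode) == 0.0:  # constant mode cannot correlate; treat as noise
            rho[i] = 0.0
        else:
            rho[i] = interrelation_number(mode, reference)
    scores = np.abs(rho) if rho_mode == "absolute" else rho

    try:
        mu = selection_threshold(scores[remaining])
    except ThresholdError:
        if mu_fallback is None:
            raise
        mu = float(mu_fallback)

    effective = frozenset(i for i in remaining if scores[i] >= mu)
    noise = frozenset(i for i in remaining if scores[i] < mu)
    return SelectionResult(baseline_idx=baseline, effective_idx=effective,
                           noise_idx=noise, rho=rho, mu=mu,
                           mean_values=means, mean_threshold=float(mean_threshold))
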