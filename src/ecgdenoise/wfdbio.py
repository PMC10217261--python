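"""Minimal WFDB (MIT-BIH dialect) record I/O.

Reads the subset of the WFDB format the MIT-BIH Arrhythmia and Noise Stress
Test databases use: a ``.hea`` text header plus a single ``.dat`` file in
format 212 (two 12-bit two's-complement samples packed into 3 bytes), with
ADC gain and baseline applied to convert to physical units (mV). A writer
for the same subset exists so tests can generate round-trip fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .core import Signal

__all__ = ["read_wfdb", "write_wfdb"]


@dataclass(frozen=True)
class _SignalSpec:
    filename: str
    fmt: str
    gain: float      # ADC units per mV
    baseline: int    # ADC value of 0 mV
    units: str


def _parse_header(hea_path: str):
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    name, n_sig = rec[0], int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samp = int(rec[3]) if len(rec) > 3 else 0
    specs = []
    for ln in lines[1: 1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1]
        gain, baseline, units = 200.0, 0, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if float(g) != 0 else 200.0
            # ADC zero (field 5) is the baseline fallback when no "(...)"
            if "(" not in tok[2] and len(tok) > 4:
                baseline = int(tok[4])
        specs.append(_SignalSpec(fname, fmt, gain, baseline, units))
    return name, fs, n_samp, specs


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = b.size // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_values]


def read_wfdb(path: str, channel: int = 0) -> Signal:
    """Read one channel of a WFDB record in physical units (mV).

    ``path`` is the record path without extension (or the ``.hea`` file).
    """
    if path.endswith(".hea"):
        path = path[:-4]
    hea = path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    name, fs, n_samp, specs = _parse_header(hea)
    if not 0 <= channel < len(specs):
        raise ValueError(
            f"record {name!r} has {len(specs)} channel(s); channel {channel} "
            f"does not exist"
        )
    spec = specs[channel]
    if spec.fmt != "212":
        raise ValueError(f"unsupported WFDB format {spec.fmt!r}; only 212 is handled")
    dat = os.path.join(os.path.dirname(path) or ".", spec.filename)
    with open(dat, "rb") as fh:
        raw = fh.read()
    n_sig = len(specs)
    values = _unpack_212(raw, n_samp * n_sig if n_samp else None)
    if n_samp == 0:
        n_samp = values.size // n_sig
    adc = values[: n_samp * n_sig].reshape(-1, n_sig)[:, channel]
    physical = (adc.astype(float) - spec.baseline) / spec.gain
    return Signal(physical, fs, label=f"{name} ch{channel}")


def write_wfdb(path: str, signals: Signal | list[Signal], gain: float = 200.0,
               baseline: int = 0) -> None:
    """Write one or two channels as a format-212 WFDB record (fixture/export
    helper; quantises to 12-bit ADC units with the given gain)."""
    if isinstance(signals, Signal):
        signals = [signals]
    if not 1 <= len(signals) <= 2:
        raise ValueError("only 1- or 2-channel records are supported")
    fs = signals[0].fs
    n = len(signals[0])
    if any(len(s) != n or s.fs != fs for s in signals):
        raise ValueError("all channels must share length and sampling rate")
    name = os.path.basename(path)
    adc = np.stack([np.clip(np.round(s.samples * gain + baseline), -2048, 2047)
                    for s in signals], axis=1).astype(np.int32).ravel()
    if adc.size % 2:
        adc = np.concatenate([adc, [0]])
    u = np.where(adc < 0, adc + 4096, adc).astype(np.uint32)
    s0, s1 = u[0::2], u[1::2]
    packed = np.empty((s0.size, 3), dtype=np.uint8)
    packed[:, 0] = s0 & 0xFF
    packed[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    packed[:, 2] = s1 & 0xFF
    with open(path + ".dat", "wb") as fh:
        fh.write(packed.tobytes())
    with open(path + ".hea", "w") as fh:
        fh.write(f"{name} {len(signals)} {fs:g} {n}\n")
        for _ in signals:
            fh.write(f"{name}.dat 212 {gain:g}({baseline})/mV 12 0 0 0 0\n")
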