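"""Acquisition-chain filtering.

Whole-cell currents in the emulated rig pass through a four-pole Bessel
low-pass with a −3 dB cutoff of 2 kHz before being digitized at 10 kHz.
The digital implementation here is magnitude-normalized so the −3 dB point
lands on the requested cutoff, and is applied causally (single pass), like
the analog hardware it mimics.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["bessel_lowpass", "bessel_sos"]


def bessel_sos(fc: float, sampling_rate: float, poles: int = 4) -> np.ndarray:
    """Second-order sections of the digital Bessel low-pass."""
    nyq = sampling_rate / 2.0
    if not 0 < fc < nyq:
        raise ValueError(f"cutoff {fc} Hz must lie in (0, Nyquist={nyq} Hz)")
    if poles < 1:
        raise ValueError("filter needs at least one pole")
    return signal.bessel(poles, fc, btype="low", norm="mag", output="sos",
                         fs=sampling_rate)


def bessel_lowpass(trace: np.ndarray, fc: float, sampling_rate: float,
                   poles: int = 4, axis: int = -1) -> np.ndarray:
    """Causal Bessel low-pass of ``trace`` (DC gain 1, −3 dB at ``fc``).

    The filter state is initialized to the first sample's steady state so a
    constant trace passes through unchanged (no start-up transient).
    """
    trace = np.asarray(trace, dtype=float)
    sos = bessel_sos(fc, sampling_rate, poles)
    zi = signal.sosfilt_zi(sos)  # steady-state for unit input
    if trace.ndim == 1:
        filt, _ = signal.sosfilt(sos, trace, zi=zi * trace[0])
        return filt
    if axis not in (-1, trace.ndim - 1):
        raise ValueError("multi-dimensional input must be filtered along the last axis")
    out = np.empty_like(trace)
    for i in range(trace.shape[0]):
        out[i], _ = signal.sosfilt(sos, trace[i], zi=zi * trace[i, 0])
    return out
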