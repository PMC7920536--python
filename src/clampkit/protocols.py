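"""Voltage-clamp stimulus protocols.

A :class:`StimProtocol` describes the command-voltage structure of a sweep
bundle: a holding potential, optional families of voltage steps, an optional
agonist puff window, and an optional paired-pulse (recovery-from-inactivation)
structure.  All voltages are *command* potentials in mV; the amplifier's
liquid junction potential (default −10 mV) is stored alongside so that
effective membrane potentials can be derived exactly once downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = ["StimProtocol", "PairedPulseSpec", "ProtocolError", "make_protocol"]

DEFAULT_JUNCTION_POTENTIAL_MV = -10.0


class ProtocolError(ValueError):
    """Raised when a stimulus protocol is structurally invalid."""


@dataclass(frozen=True)
class PairedPulseSpec:
    """Prepulse/test-pulse structure for recovery-from-inactivation runs.

    The canonical protocol depolarizes from a hyperpolarized holding level
    with a 500-ms prepulse, returns to the holding level for a variable
    interval, then applies a 100-ms test pulse to the same level.
    """

    prepulse_mV: float
    prepulse_ms: float
    test_mV: float
    test_ms: float
    intervals_ms: tuple[float, ...]
    pre_hold_ms: float = 50.0   # settle at holding before the prepulse

    def __post_init__(self) -> None:
        iv = tuple(float(x) for x in self.intervals_ms)
        if len(iv) == 0:
            raise ProtocolError("paired_pulse requires at least one interval")
        if any(b <= a for a, b in zip(iv, iv[1:])):
            raise ProtocolError("paired-pulse intervals must be strictly increasing")
        if any(x <= 0 for x in iv):
            raise ProtocolError("paired-pulse intervals must be positive")
        object.__setattr__(self, "intervals_ms", iv)


@dataclass(frozen=True)
class StimProtocol:
    """Command-voltage protocol shared by all sweeps of a bundle.

    Parameters
    ----------
    holding_potential : float
        Command holding potential, mV.
    step_levels : tuple of float
        Command potential of the step in each sweep, mV.  Empty for
        fixed-hold protocols.
    step_onset, step_duration : float
        Step timing in ms.  Ignored when ``step_levels`` is empty.
    sweep_duration : float
        Length of every sweep, ms.
    n_sweeps : int
        Number of sweeps; equals ``len(step_levels)`` for step families,
        ``len(paired_pulse.intervals_ms)`` for paired-pulse protocols.
    puff_window : (start_ms, duration_ms), optional
        Window during which a puff-applied drug acts.
    paired_pulse : PairedPulseSpec, optional
    junction_potential : float
        Liquid junction potential in mV; effective membrane potential is
        ``command + junction_potential``.
    """

    holding_potential: float
    step_levels: tuple[float, ...] = ()
    step_onset: float = 0.0
    step_duration: float = 0.0
    sweep_duration: float = 1000.0
    n_sweeps: int = 1
    puff_window: Optional[tuple[float, float]] = None
    paired_pulse: Optional[PairedPulseSpec] = None
    junction_potential: float = DEFAULT_JUNCTION_POTENTIAL_MV

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_levels", tuple(float(v) for v in self.step_levels))
        volts = [self.holding_potential, *self.step_levels]
        if self.paired_pulse is not None:
            volts += [self.paired_pulse.prepulse_mV, self.paired_pulse.test_mV]
        if not all(math.isfinite(v) for v in volts):
            raise ProtocolError("all command voltages must be finite")
        if self.sweep_duration <= 0:
            raise ProtocolError("sweep_duration must be positive")
        if self.step_levels:
            if self.step_onset < 0 or self.step_duration <= 0:
                raise ProtocolError("step window must have positive duration and non-negative onset")
            if self.step_onset + self.step_duration > self.sweep_duration:
                raise ProtocolError("step window extends beyond sweep")
        if self.puff_window is not None:
            start, dur = self.puff_window
            if start < 0 or dur <= 0 or start + dur > self.sweep_duration:
                raise ProtocolError("puff window must lie inside the sweep")
        if self.paired_pulse is not None:
            pp = self.paired_pulse
            longest = pp.pre_hold_ms + pp.prepulse_ms + max(pp.intervals_ms) + pp.test_ms
            if longest > self.sweep_duration:
                raise ProtocolError("paired-pulse structure extends beyond sweep")
            if self.n_sweeps != len(pp.intervals_ms):
                raise ProtocolError("paired_pulse needs one sweep per interval")
        elif self.step_levels and self.n_sweeps != len(self.step_levels):
            raise ProtocolError("step family needs one sweep per level")
        if self.n_sweeps < 1:
            raise ProtocolError("protocol needs at least one sweep")

    # ------------------------------------------------------------------
    def n_samples(self, sampling_rate: float) -> int:
        return int(round(self.sweep_duration / 1000.0 * sampling_rate))

    def time_base(self, sampling_rate: float) -> np.ndarray:
        """Sweep time base in seconds."""
        return np.arange(self.n_samples(sampling_rate)) / sampling_rate

    def command_waveforms(self, sampling_rate: float) -> np.ndarray:
        """(n_sweeps, n_samples) matrix of command potentials in mV."""
        n = self.n_samples(sampling_rate)
        out = np.full((self.n_sweeps, n), self.holding_potential, dtype=float)
        dt_ms = 1000.0 / sampling_rate
        if self.paired_pulse is not None:
            pp = self.paired_pulse
            pre0 = int(round(pp.pre_hold_ms / dt_ms))
            pre1 = int(round((pp.pre_hold_ms + pp.prepulse_ms) / dt_ms))
            for i, gap in enumerate(pp.intervals_ms):
                t0 = int(round((pp.pre_hold_ms + pp.prepulse_ms + gap) / dt_ms))
                t1 = int(round((pp.pre_hold_ms + pp.prepulse_ms + gap + pp.test_ms) / dt_ms))
                out[i, pre0:pre1] = pp.prepulse_mV
                out[i, t0:min(t1, n)] = pp.test_mV
        elif self.step_levels:
            i0 = int(round(self.step_onset / dt_ms))
            i1 = int(round((self.step_onset + self.step_duration) / dt_ms))
            for i, lev in enumerate(self.step_levels):
                out[i, i0:i1] = lev
        return out

    def membrane_waveforms(self, sampling_rate: float) -> np.ndarray:
        """Effective membrane potential (command + junction potential), mV."""
        return self.command_waveforms(sampling_rate) + self.junction_potential

    def step_window_samples(self, sampling_rate: float) -> tuple[int, int]:
        if not self.step_levels:
            raise ProtocolError("protocol has no step family")
        dt_ms = 1000.0 / sampling_rate
        return (int(round(self.step_onset / dt_ms)),
                int(round((self.step_onset + self.step_duration) / dt_ms)))

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.paired_pulse is not None:
            d["paired_pulse"] = asdict(self.paired_pulse)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimProtocol":
        d = dict(d)
        if d.get("paired_pulse"):
            pp = dict(d["paired_pulse"])
            pp["intervals_ms"] = tuple(pp["intervals_ms"])
            d["paired_pulse"] = PairedPulseSpec(**pp)
        d["step_levels"] = tuple(d.get("step_levels", ()))
        if d.get("puff_window"):
            d["puff_window"] = tuple(d["puff_window"])
        return cls(**d)


def make_protocol(kind: str, **params) -> StimProtocol:
    """Build a stimulus protocol of one of the canonical kinds.

    Kinds
    -----
    ``step_family``
        Depolarizing/hyperpolarizing step series, e.g. 16 steps of +5 mV
        from a −70 mV hold.  Params: ``holding_mV``, ``increment_mV``,
        ``n_steps``, ``step_onset_ms``, ``step_duration_ms``,
        ``sweep_duration_ms`` (or explicit ``levels_mV``).
    ``fixed_hold``
        Constant holding potential, ``n_sweeps`` repeats of
        ``sweep_duration_ms``.
    ``puff``
        Fixed hold plus a puff window (``puff_start_ms``, ``puff_duration_ms``).
    ``paired_pulse``
        Prepulse/test recovery protocol; params ``prepulse_mV``
        (default −40 command), ``intervals_ms`` etc.
    """
    jp = params.pop("junction_potential", DEFAULT_JUNCTION_POTENTIAL_MV)
    if kind == "step_family":
        hold = float(params.pop("holding_mV"))
        if "levels_mV" in params:
            levels = tuple(float(v) for v in params.pop("levels_mV"))
        else:
            inc = float(params.pop("increment_mV"))
            n = int(params.pop("n_steps"))
            levels = tuple(hold + inc * (i + 1) for i in range(n))
        onset = float(params.pop("step_onset_ms", 50.0))
        dur = float(params.pop("step_duration_ms", 200.0))
        sweep = float(params.pop("sweep_duration_ms", onset + dur + 100.0))
        _reject_extra(params)
        return StimProtocol(hold, levels, onset, dur, sweep,
                            n_sweeps=max(len(levels), 1) if levels else 1,
                            junction_potential=jp)
    if kind == "fixed_hold":
        hold = float(params.pop("holding_mV"))
        sweep = float(params.pop("sweep_duration_ms", 1000.0))
        n = int(params.pop("n_sweeps", 1))
        _reject_extra(params)
        return StimProtocol(hold, (), sweep_duration=sweep, n_sweeps=n,
                            junction_potential=jp)
    if kind == "puff":
        hold = float(params.pop("holding_mV"))
        sweep = float(params.pop("sweep_duration_ms", 2000.0))
        start = float(params.pop("puff_start_ms"))
        dur = float(params.pop("puff_duration_ms"))
        n = int(params.pop("n_sweeps", 1))
        _reject_extra(params)
        return StimProtocol(hold, (), sweep_duration=sweep, n_sweeps=n,
                            puff_window=(start, dur), junction_potential=jp)
    if kind == "paired_pulse":
        hold = float(params.pop("holding_mV", -80.0))
        pp = PairedPulseSpec(
            prepulse_mV=float(params.pop("prepulse_mV", -30.0)),
            prepulse_ms=float(params.pop("prepulse_ms", 500.0)),
            test_mV=float(params.pop("test_mV", -30.0)),
            test_ms=float(params.pop("test_ms", 100.0)),
            intervals_ms=tuple(float(x) for x in params.pop("intervals_ms")),
            pre_hold_ms=float(params.pop("pre_hold_ms", 50.0)),
        )
        tail = float(params.pop("tail_ms", 100.0))
        sweep = pp.pre_hold_ms + pp.prepulse_ms + max(pp.intervals_ms) + pp.test_ms + tail
        _reject_extra(params)
        return StimProtocol(hold, (), sweep_duration=sweep,
                            n_sweeps=len(pp.intervals_ms), paired_pulse=pp,
                            junction_potential=jp)
    raise ProtocolError(f"unknown protocol kind: {kind!r}")


def _reject_extra(params: dict) -> None:
    if params:
        raise ProtocolError(f"unrecognized protocol parameters: {sorted(params)}")
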