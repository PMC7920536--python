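"""Kinetic descriptors of synaptic and voltage-gated currents.

Three small model classes in the statsmodels mould — construct from data,
call :meth:`fit`, get a Results object with parameter estimates, standard
errors, an R² and a ``summary()`` table:

* :class:`SigmoidRise` — four-parameter logistic fit to an activation or
  event rising phase; reports the 10–90% rise time (``ln 81 × slope``).
* :class:`ExponentialDecay` — single exponential ``A·e^(−t/τ) + C`` fitted
  from the peak of a decaying transient.
* :class:`RecoveryCurve` — double-exponential recovery from inactivation
  ``1 − a₁·e^(−t/τ₁) − a₂·e^(−t/τ₂)`` fitted to paired-pulse amplitude
  ratios; τ₁ is the fast and τ₂ the slow phase (τ₂ ≥ 3·τ₁ is enforced for
  identifiability).

Convenience wrappers (:func:`fit_rise_sigmoid`, :func:`fit_decay_exponential`,
:func:`decay_vs_voltage`, :func:`fit_recovery_double_exp`) operate directly on
sampled waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError

__all__ = [
    "SigmoidRise", "RiseFitResults", "ExponentialDecay", "DecayFitResults",
    "RecoveryCurve", "RecoveryFitResults", "fit_rise_sigmoid",
    "fit_decay_exponential", "decay_vs_voltage", "fit_recovery_double_exp",
]

LN81 = math.log(81.0)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


@dataclass
class _BaseResults:
    """Shared Results behaviour: params, standard errors, R², summary()."""

    params: dict = field(default_factory=dict)
    bse: dict = field(default_factory=dict)
    rsquared: float = float("nan")
    nobs: int = 0
    model_name: str = ""

    def summary(self) -> str:
        lines = [f"{self.model_name} fit", "=" * 40,
                 f"{'parameter':<16}{'estimate':>12}{'std err':>12}"]
        for k, v in self.params.items():
            se = self.bse.get(k, float("nan"))
            lines.append(f"{k:<16}{v:>12.5g}{se:>12.3g}")
        lines.append("-" * 40)
        lines.append(f"R-squared: {self.rsquared:.5f}   n = {self.nobs}")
        return "\n".join(lines)


@dataclass
class RiseFitResults(_BaseResults):
    """Logistic rise fit: midpoint, slope, derived 10–90% rise time (μs)."""

    rise_10_90_us: float = float("nan")
    midpoint_ms: float = float("nan")

    def __post_init__(self):
        if not self.rise_10_90_us > 0:
            raise FitError(f"fitted 10–90% rise must be positive, got {self.rise_10_90_us}")


@dataclass
class DecayFitResults(_BaseResults):
    tau_ms: float = float("nan")
    amplitude_pA: float = float("nan")
    offset_pA: float = float("nan")

    def __post_init__(self):
        if not self.tau_ms > 0:
            raise FitError(f"fitted decay tau must be positive, got {self.tau_ms}")


@dataclass
class RecoveryFitResults(_BaseResults):
    tau1_ms: float = float("nan")
    tau2_ms: float = float("nan")
    frac_fast: float = float("nan")
    frac_slow: float = float("nan")
    tau2_identifiable: bool = True
    immediate_recovery: bool = False

    def predict(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        if self.immediate_recovery:
            return np.ones_like(t)
        return (1.0 - self.frac_fast * np.exp(-t / self.tau1_ms)
                - self.frac_slow * np.exp(-t / self.tau2_ms))

    def plot(self, intervals_ms=None, ratios=None, ax=None):
        """Fitted recovery curve (and the measured ratios when given)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if intervals_ms is not None and ratios is not None:
            ax.semilogx(intervals_ms, ratios, "ko", label="test/prepulse")
            tgrid = np.geomspace(min(intervals_ms), max(intervals_ms), 200)
        else:
            tgrid = np.geomspace(1.0, 10.0 * self.tau2_ms, 200)
        ax.semilogx(tgrid, self.predict(tgrid), "r-", label="double-exp fit")
        ax.set_xlabel("inter-pulse interval (ms)")
        ax.set_ylabel("fractional recovery")
        ax.legend()
        return ax


class SigmoidRise:
    """Four-parameter logistic model of a rising phase.

    ``y(t) = y0 + A / (1 + exp((t50 − t)/k))``; the fitted 10–90% rise time
    is ``ln(81)·k`` (closed form for the logistic).
    """

    def __init__(self, t_ms: np.ndarray, y: np.ndarray):
        self.t = np.asarray(t_ms, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.t.shape != self.y.shape or self.t.size < 5:
            raise FitError("rise fit needs matching arrays of at least 5 samples")

    def fit(self) -> RiseFitResults:
        t, y = self.t, self.y
        span = float(y[-1] - y[0])
        if span <= 0:
            raise FitError("rising segment must increase toward the peak")
        half = y[0] + 0.5 * span
        t50_0 = float(t[np.argmin(np.abs(y - half))])
        k0 = max((t[-1] - t[0]) / 10.0, 1e-6)

        def model(tt, y0, amp, t50, k):
            return y0 + amp / (1.0 + np.exp(np.clip((t50 - tt) / k, -50, 50)))

        try:
            popt, pcov = curve_fit(
                model, t, y, p0=[float(y[0]), span, t50_0, k0],
                bounds=([-np.inf, 0.0, t[0] - (t[-1] - t[0]), 1e-9],
                        [np.inf, np.inf, t[-1] + (t[-1] - t[0]), (t[-1] - t[0])]),
                maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"sigmoid rise fit did not converge: {exc}") from exc
        perr = np.sqrt(np.diag(pcov))
        names = ["baseline", "amplitude", "t50_ms", "slope_ms"]
        return RiseFitResults(
            params=dict(zip(names, popt)), bse=dict(zip(names, perr)),
            rsquared=_r_squared(y, model(t, *popt)), nobs=t.size,
            model_name="SigmoidRise",
            rise_10_90_us=LN81 * popt[3] * 1000.0, midpoint_ms=popt[2],
        )


class ExponentialDecay:
    """Single-exponential decay ``A·e^(−t/τ) + C`` from a transient peak."""

    def __init__(self, t_ms: np.ndarray, y: np.ndarray):
        self.t = np.asarray(t_ms, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.t.shape != self.y.shape or self.t.size < 4:
            raise FitError("decay fit needs matching arrays of at least 4 samples")

    def _initial_tau(self) -> float:
        """Log-linear regression estimate of τ on the offset-stripped segment."""
        y = self.y - self.y[-1]
        sign = 1.0 if y[0] >= 0 else -1.0
        y = sign * y
        # regress on the contiguous prefix above 5% of the initial amplitude,
        # so a long noisy tail cannot dominate the log-linear estimate
        peak = y.max()
        below = np.flatnonzero(y < max(0.05 * peak, 1e-12))
        stop = below[0] if below.size else y.size
        stop = max(stop, 4)
        seg_t, seg_y = self.t[:stop], y[:stop]
        mask = seg_y > max(1e-12, 1e-3 * peak)
        if mask.sum() < 3:
            return max((self.t[-1] - self.t[0]) / 3.0, 1e-3)
        slope = np.polyfit(seg_t[mask], np.log(seg_y[mask]), 1)[0]
        if slope >= 0:
            raise FitError("segment does not decay toward its final value")
        return -1.0 / slope

    def fit(self) -> DecayFitResults:
        t0 = self.t[0]
        t = self.t - t0
        y = self.y
        if abs(y[0] - y[-1]) < 1e-30:
            raise FitError("decay segment is flat")
        tau0 = self._initial_tau()
        a0 = float(y[0] - y[-1])

        def model(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c

        try:
            popt, pcov = curve_fit(
                model, t, y, p0=[a0, tau0, float(y[-1])],
                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"exponential decay fit did not converge: {exc}") from exc
        if np.sign(popt[0]) != np.sign(a0) and abs(a0) > 0:
            raise FitError("segment trends away from its baseline (not a decay)")
        if popt[1] > 3.0 * (t[-1] - t[0]):
            # the optimizer fled to the linear regime: the segment does not
            # turn over within the window (e.g. an upward-accelerating trend)
            raise FitError("no resolvable exponential decay inside the segment")
        perr = np.sqrt(np.diag(pcov))
        names = ["amplitude_pA", "tau_ms", "offset_pA"]
        return DecayFitResults(
            params=dict(zip(names, popt)), bse=dict(zip(names, perr)),
            rsquared=_r_squared(y, model(t, *popt)), nobs=t.size,
            model_name="ExponentialDecay",
            tau_ms=float(popt[1]), amplitude_pA=float(popt[0]),
            offset_pA=float(popt[2]),
        )


class RecoveryCurve:
    """Double-exponential recovery from inactivation.

    Fitted to test/prepulse amplitude ratios as a function of the
    inter-pulse interval: ``r(t) = 1 − a₁·e^(−t/τ₁) − a₂·e^(−t/τ₂)``.
    The slow constant is parameterized as a multiple (≥ 3) of the fast one,
    enforcing τ₁ < τ₂ and keeping the two phases identifiable.
    """

    MIN_TAU_RATIO = 3.0

    def __init__(self, intervals_ms: np.ndarray, ratios: np.ndarray):
        self.t = np.asarray(intervals_ms, dtype=float)
        self.r = np.asarray(ratios, dtype=float)
        if self.t.shape != self.r.shape:
            raise FitError("intervals and ratios must have equal length")
        if self.t.size < 6:
            raise FitError("recovery fit needs at least 6 interval points")
        if np.any(self.r < 0) or np.any(self.r > 1.2):
            raise FitError("recovery ratios must lie in [0, 1.2]")

    def fit(self) -> RecoveryFitResults:
        t, r = self.t, self.r
        if np.all(np.abs(r - 1.0) < 0.02):
            return RecoveryFitResults(
                params={}, bse={}, rsquared=1.0, nobs=t.size,
                model_name="RecoveryCurve", tau1_ms=float("nan"),
                tau2_ms=float("nan"), frac_fast=0.0, frac_slow=0.0,
                tau2_identifiable=False, immediate_recovery=True)

        # single-exponential initialization
        def single(tt, a, tau):
            return 1.0 - a * np.exp(-tt / tau)

        try:
            p_single, _ = curve_fit(single, t, r, p0=[1.0 - r[0], np.median(t)],
                                    bounds=([0.0, 1e-6], [1.2, 1e7]), maxfev=20000)
        except (RuntimeError, ValueError):
            p_single = [max(1.0 - r[0], 0.1), float(np.median(t))]

        def model(tt, a1, tau1, a2, ratio):
            return 1.0 - a1 * np.exp(-tt / tau1) - a2 * np.exp(-tt / (tau1 * ratio))

        p0 = [0.8 * p_single[0], 0.7 * p_single[1], 0.2 * p_single[0], 6.0]
        try:
            popt, pcov = curve_fit(
                model, t, r, p0=p0,
                bounds=([0.0, 1e-6, 0.0, self.MIN_TAU_RATIO],
                        [1.0, 1e7, 1.0, 1e4]),
                maxfev=40000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"double-exponential recovery fit did not converge: {exc}") from exc
        a1, tau1, a2, ratio = popt
        tau2 = tau1 * ratio
        perr = np.sqrt(np.diag(pcov))
        # τ2 is unidentifiable when the slow phase carries no weight or its
        # uncertainty dwarfs the estimate
        tau2_se = math.hypot(perr[1] * ratio, perr[3] * tau1)
        identifiable = bool(a2 > 0.01 and np.isfinite(tau2_se) and tau2_se < 5.0 * tau2)
        names = ["frac_fast", "tau1_ms", "frac_slow", "tau_ratio"]
        return RecoveryFitResults(
            params=dict(zip(names, popt)), bse=dict(zip(names, perr)),
            rsquared=_r_squared(r, model(t, *popt)), nobs=t.size,
            model_name="RecoveryCurve",
            tau1_ms=float(tau1), tau2_ms=float(tau2),
            frac_fast=float(a1), frac_slow=float(a2),
            tau2_identifiable=identifiable)


# ----------------------------------------------------------------------
# waveform-level conveniences
# ----------------------------------------------------------------------

def _oriented(waveform: np.ndarray) -> tuple[np.ndarray, float]:
    """Return the waveform flipped positive-going, and the sign applied."""
    w = np.asarray(waveform, dtype=float)
    dev = w - np.median(w)
    sign = 1.0 if abs(dev.max()) >= abs(dev.min()) else -1.0
    return sign * w, sign


def fit_rise_sigmoid(waveform: np.ndarray, sampling_rate: float) -> RiseFitResults:
    """Fit the rising phase (start → peak) of a transient with a logistic.

    The waveform should start at baseline; polarity is detected
    automatically.  Returns the 10–90% rise time from the fitted curve.
    """
    w = np.asarray(waveform, dtype=float)
    # orient against the leading baseline: every rise segment starts at (or
    # before) onset, so the first few samples are the baseline reference
    base = float(np.median(w[: max(3, w.size // 20)]))
    ext = int(np.argmax(np.abs(w - base)))
    if w[ext] < base:
        w = 2 * base - w   # reflect about the baseline: rise now positive
    peak = int(np.argmax(w[: ext + 1]))
    if peak < 3:
        raise FitError("waveform peaks too early to resolve a rising phase")
    t_ms = np.arange(peak + 1) * (1000.0 / sampling_rate)
    return SigmoidRise(t_ms, w[: peak + 1]).fit()


def fit_decay_exponential(waveform: np.ndarray, sampling_rate: float,
                          from_peak: bool = True) -> DecayFitResults:
    """Fit a single exponential to the decay of a transient.

    When ``from_peak`` the segment runs from the waveform's extremum to
    5 initial decay constants beyond it (initial τ from log-linear
    regression); otherwise the whole waveform is used.  Fitted amplitudes
    and taus are reported on the original (signed) waveform scale.
    """
    w, sign = _oriented(waveform)
    start = int(np.argmax(w)) if from_peak else 0
    if from_peak:
        # skip one rise-duration past the peak: the activation gate is still
        # completing there, which would bias τ upward for slow-rising
        # transients.  The rise duration is read off the waveform itself
        # (10%-of-peak crossing to peak).
        peak_idx, peak_val = start, w[start]
        above = np.flatnonzero(w[:peak_idx + 1] >= 0.1 * peak_val)
        rise_dur = peak_idx - int(above[0]) if above.size else 0
        start = min(peak_idx + 2 * rise_dur, w.size - 4)
    seg = w[start:]
    if seg.size < 4:
        raise FitError("decay segment too short")
    dt_ms = 1000.0 / sampling_rate
    t_ms = np.arange(seg.size) * dt_ms
    tau0 = ExponentialDecay(t_ms, seg)._initial_tau()
    stop = min(seg.size, max(int(round(5.0 * tau0 / dt_ms)), 4))
    res = ExponentialDecay(t_ms[:stop], seg[:stop]).fit()
    res.amplitude_pA *= sign
    res.offset_pA *= sign
    res.params["amplitude_pA"] *= sign
    res.params["offset_pA"] *= sign
    return res


def decay_vs_voltage(events_by_voltage: dict[float, np.ndarray],
                     sampling_rate: float, min_events: int = 5) -> pd.DataFrame:
    """Per-voltage decay constants from averaged events.

    ``events_by_voltage`` maps holding potential (mV) to a 2-D array of
    onset-aligned event waveforms (n_events × n_samples).  The per-voltage
    average is fitted; the τ standard error of the fit is reported as SEM.
    Voltages with fewer than ``min_events`` events are flagged.
    """
    if len(events_by_voltage) < 2:
        raise FitError("decay-voltage table needs at least two voltages")
    rows = []
    for v in sorted(events_by_voltage):
        ev = np.atleast_2d(np.asarray(events_by_voltage[v], dtype=float))
        res = fit_decay_exponential(ev.mean(axis=0), sampling_rate)
        rows.append({
            "voltage_mV": float(v), "tau_ms": res.tau_ms,
            "sem_ms": res.bse.get("tau_ms", float("nan")),
            "n_events": ev.shape[0], "rsquared": res.rsquared,
            "flagged": ev.shape[0] < min_events,
        })
    return pd.DataFrame(rows)


def fit_recovery_double_exp(intervals_ms: Sequence[float],
                            ratios: Sequence[float]) -> RecoveryFitResults:
    """Fit the double-exponential recovery curve to paired-pulse ratios."""
    return RecoveryCurve(np.asarray(intervals_ms), np.asarray(ratios)).fit()
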