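"""Current-level analyses: leak subtraction, variance, and I–V fitting.

The two I–V models follow the Model/Results convention:

* :class:`LinearIV` — straight-line fit of averaged-event peak amplitude
  versus membrane potential; the slope is the synaptic peak conductance (nS)
  and the x-intercept the reversal potential (mV).
* :class:`BoltzmannIV` — the ohmic-Boltzmann model of a voltage-gated
  current's peak I–V relation,

  ``I(V) = G_max · (V − E_ion) / (1 + exp((V_0.5 − V)/z))``,

  fitted by multi-start nonlinear least squares over a grid of activation
  midpoints.

Supporting operations: junction-potential correction (applied exactly once),
scaled linear leak subtraction, single-exponential trend subtraction for
current-variance analysis, windowed variance, fixed-timepoint current
inventories, and paired-pulse recovery ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from scipy.optimize import curve_fit

from .bundle import SweepBundle
from .errors import FitError
from .kinetics import _BaseResults, ExponentialDecay

__all__ = [
    "IVCurve", "LinearIV", "LinearIVResults", "BoltzmannIV",
    "BoltzmannIVResults", "LeakFit", "VarianceResult",
    "correct_junction_potential", "subtract_leak", "detrend_exponential",
    "window_variance", "event_iv_fit", "fit_boltzmann_ohmic",
    "fixed_timepoint_measures", "paired_pulse_ratios",
]


@dataclass
class IVCurve:
    """A (voltage, current) relation; voltages are junction-corrected mV."""

    voltages_mV: np.ndarray
    currents_pA: np.ndarray
    n_per_point: Optional[np.ndarray] = None
    timepoint_ms: Optional[float] = None

    def __post_init__(self):
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        if self.voltages_mV.shape != self.currents_pA.shape:
            raise ValueError("voltage and current arrays must match")
        if np.any(np.diff(self.voltages_mV) <= 0):
            raise ValueError("voltages must be strictly increasing")


# ----------------------------------------------------------------------
# junction potential
# ----------------------------------------------------------------------

def correct_junction_potential(voltages_mV: np.ndarray, jp_mV: float = -10.0,
                               already_corrected: bool = False) -> np.ndarray:
    """Convert command potentials to reported membrane potentials.

    ``V_reported = V_command + jp``.  Pass the metadata's corrected flag as
    ``already_corrected``; applying the offset twice is an error, not a
    silent shift.
    """
    if already_corrected:
        raise ValueError("junction potential correction already applied")
    return np.asarray(voltages_mV, dtype=float) + jp_mV


# ----------------------------------------------------------------------
# leak subtraction
# ----------------------------------------------------------------------

@dataclass
class LeakFit:
    g_nS: float
    e_rev_mV: float
    rsquared: float
    window_mV: tuple[float, float]


def subtract_leak(bundle: SweepBundle,
                  leak_window_mV: tuple[float, float] = (-90.0, -78.0),
                  measure_window_ms: tuple[float, float] = (0.4, 0.7),
                  measure: str = "early",
                  fit_intercept: bool = False) -> tuple[SweepBundle, LeakFit]:
    """Fit and remove the scaled passive (ohmic) component from every sweep.

    The leak conductance is estimated from baseline-referenced current
    deltas ``ΔI = I(early) − I(pre-step)`` at step levels whose effective
    potential falls inside ``leak_window_mV`` (below the activation range of
    the gated conductances), and a through-origin fit of ``ΔI = G·ΔV``.
    With ``measure="early"`` the deltas are measured ``measure_window_ms``
    after step onset — late enough for the acquisition filter to settle,
    early enough that slow gates are still frozen at their holding-state
    values, so slowly activating currents and any window current cancel out
    of the estimate.  With ``measure="steady"`` the trailing 20% of the step
    is used instead — the lower-noise choice when the leak window holds
    truly passive levels (e.g. hyperpolarizing leak steps in a
    potassium-blocked recording).  Each sweep then has
    ``baseline + G·(V(t) − V_hold)`` removed.
    """
    prot = bundle.protocol
    fs = bundle.sampling_rate
    v_steps = np.asarray(prot.step_levels, dtype=float) + prot.junction_potential
    if v_steps.size == 0:
        raise ValueError("leak subtraction needs a step-family protocol")
    i0, i1 = prot.step_window_samples(fs)
    if measure == "steady":
        e0 = i1 - max(int((i1 - i0) * 0.2), 1)
        e1 = i1
    elif measure == "early":
        e0 = i0 + int(round(measure_window_ms[0] / 1000.0 * fs))
        e1 = i0 + int(round(measure_window_ms[1] / 1000.0 * fs))
    else:
        raise ValueError("measure must be 'early' or 'steady'")
    if not i0 < e0 < e1 <= i1:
        raise ValueError("leak measurement window must lie inside the step")
    base_n = max(int(0.02 * fs), 1)   # trailing 20 ms of the pre-step hold
    baselines = bundle.sweeps_pA[:, max(i0 - base_n, 0):i0].mean(axis=1)
    early = bundle.sweeps_pA[:, e0:e1].mean(axis=1)

    lo, hi = sorted(leak_window_mV)
    v_hold = prot.holding_potential + prot.junction_potential
    sel = (v_steps >= lo) & (v_steps <= hi) & (v_steps != v_hold)
    if sel.sum() < 2:
        raise ValueError(
            f"need >=2 step levels inside the leak window {leak_window_mV}, "
            f"got {int(sel.sum())}")
    dv = v_steps[sel] - v_hold
    di = early[sel] - baselines[sel]
    if fit_intercept:
        # slope-only estimate: insensitive to a standing current at the
        # holding potential (e.g. window current of a partially open gate)
        g = float(np.polyfit(dv, di, 1)[0])
    else:
        g = float(np.sum(di * dv) / np.sum(dv * dv))
    # the acquisition filter has not fully settled inside the early window;
    # normalize by its own step response averaged over the same samples
    fc = bundle.metadata.get("bessel_fc_Hz")
    if fc:
        from .filters import bessel_lowpass
        step = np.zeros(i1)
        step[i0:] = 1.0
        resp = bessel_lowpass(step, fc, fs, bundle.metadata.get("bessel_poles", 4))
        settle = float(resp[e0:e1].mean())
        if settle > 0.1:
            g /= settle
    pred = g * dv
    ss_tot = float(np.sum(di ** 2))
    r2 = 1.0 - float(np.sum((di - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    e_rev = v_hold - float(baselines.mean()) / g if abs(g) > 1e-12 else float("nan")

    v_all = bundle.membrane_potentials()
    leak_term = g * (v_all - v_hold)
    fc = bundle.metadata.get("bessel_fc_Hz")
    if fc:
        # pass the leak template through the same acquisition filter as the
        # data, so the subtraction is clean across step edges
        from .filters import bessel_lowpass
        leak_term = bessel_lowpass(leak_term, fc, fs,
                                   bundle.metadata.get("bessel_poles", 4))
    subtracted = bundle.sweeps_pA - baselines[:, None] - leak_term
    out = SweepBundle(bundle.time_s, subtracted, prot,
                      {**bundle.metadata, "leak_subtracted": True},
                      bundle.ground_truth)
    return out, LeakFit(g, float(e_rev), float(r2), (lo, hi))


# ----------------------------------------------------------------------
# trend subtraction and variance
# ----------------------------------------------------------------------

def detrend_exponential(trace: np.ndarray, sampling_rate: float,
                        window: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Remove a slow voltage-activated component by single-exponential fit.

    A single exponential plus offset is fitted to the samples inside
    ``window`` (whole trace by default) and subtracted there; the residual
    has approximately zero mean, leaving fast synaptic events intact for
    variance analysis.
    """
    x = np.asarray(trace, dtype=float)
    a, b = window if window is not None else (0, x.size)
    seg = x[a:b]
    t_ms = np.arange(seg.size) * 1000.0 / sampling_rate
    try:
        res = ExponentialDecay(t_ms, seg).fit()
        trend = res.amplitude_pA * np.exp(-t_ms / res.tau_ms) + res.offset_pA
    except FitError:
        # no resolvable exponential trend: remove the mean only
        trend = np.full(seg.size, seg.mean())
    out = x.copy()
    out[a:b] = seg - trend
    return out


@dataclass
class VarianceResult:
    variance_pA2: float
    window_s: tuple[float, float]
    detrend_rsquared: Optional[float] = None

    def __post_init__(self):
        if self.variance_pA2 < 0:
            raise ValueError("variance must be non-negative")


def window_variance(trace: np.ndarray, sampling_rate: float,
                    start_s: float, length_s: float = 0.5) -> VarianceResult:
    """Sample variance of a (detrended) analysis window, pA²."""
    x = np.asarray(trace, dtype=float)
    i0 = int(round(start_s * sampling_rate))
    i1 = int(round((start_s + length_s) * sampling_rate))
    if i0 < 0 or i1 > x.size or i1 <= i0:
        raise ValueError("variance window must lie inside the trace")
    return VarianceResult(float(np.var(x[i0:i1])), (start_s, start_s + length_s))


# ----------------------------------------------------------------------
# linear (synaptic) I–V
# ----------------------------------------------------------------------

@dataclass
class LinearIVResults(_BaseResults):
    conductance_nS: float = float("nan")
    reversal_mV: float = float("nan")


class LinearIV:
    """Straight-line model of event amplitude versus membrane potential."""

    def __init__(self, iv: IVCurve):
        if iv.voltages_mV.size < 3:
            raise FitError("linear I–V fit needs at least 3 voltages")
        self.iv = iv

    def fit(self) -> LinearIVResults:
        v, i = self.iv.voltages_mV, self.iv.currents_pA
        coef, cov = np.polyfit(v, i, 1, cov=True)
        slope, intercept = coef
        if abs(slope) < 1e-12:
            raise FitError("zero-slope I–V relation has no reversal potential")
        reversal = -intercept / slope
        pred = np.polyval(coef, v)
        ss_tot = np.sum((i - i.mean()) ** 2)
        r2 = 1.0 - np.sum((i - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
        se = np.sqrt(np.diag(cov))
        # delta-method SE for the x-intercept
        rev_se = abs(reversal) * np.hypot(se[0] / slope, se[1] / intercept) \
            if intercept != 0 else float("nan")
        return LinearIVResults(
            params={"conductance_nS": float(slope), "reversal_mV": float(reversal)},
            bse={"conductance_nS": float(se[0]), "reversal_mV": float(rev_se)},
            rsquared=float(r2), nobs=v.size, model_name="LinearIV",
            conductance_nS=float(slope), reversal_mV=float(reversal))


def event_iv_fit(iv: IVCurve) -> LinearIVResults:
    """Fit the sIPSC amplitude–voltage relation with a straight line."""
    return LinearIV(iv).fit()


# ----------------------------------------------------------------------
# ohmic-Boltzmann I–V
# ----------------------------------------------------------------------

@dataclass
class BoltzmannIVResults(_BaseResults):
    gmax_nS: float = float("nan")
    v_half_mV: float = float("nan")
    z_mV: float = float("nan")
    e_ion_mV: float = float("nan")

    def predict(self, v_mV: np.ndarray) -> np.ndarray:
        v = np.asarray(v_mV, dtype=float)
        return self.gmax_nS * (v - self.e_ion_mV) / (
            1.0 + np.exp((self.v_half_mV - v) / self.z_mV))

    def plot(self, iv: Optional["IVCurve"] = None, ax=None):
        """Fitted curve (and measured points when ``iv`` is given)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if iv is not None:
            ax.plot(iv.voltages_mV, iv.currents_pA, "ko", label="measured")
            vgrid = np.linspace(iv.voltages_mV.min(), iv.voltages_mV.max(), 200)
        else:
            vgrid = np.linspace(self.v_half_mV - 30, self.v_half_mV + 30, 200)
        ax.plot(vgrid, self.predict(vgrid), "r-", label="Boltzmann-ohmic fit")
        ax.set_xlabel("membrane potential (mV)")
        ax.set_ylabel("current (pA)")
        ax.legend()
        return ax


def _boltzmann_ohmic(v, gmax, v_half, z, e_ion):
    return gmax * (v - e_ion) / (1.0 + np.exp((v_half - v) / z))


class BoltzmannIV:
    """Ohmic-Boltzmann model of a peak I–V relation.

    ``G_max ≥ 0`` and ``z > 0`` are enforced through bounds; the activation
    midpoint is multi-started over a −80…−20 mV grid so the optimizer cannot
    settle in a shoulder of the squared-error surface.  The reversal
    potential is free by default but can be pinned.
    """

    V_HALF_GRID = tuple(range(-80, -19, 10))

    def __init__(self, iv: IVCurve, e_ion_mV: Optional[float] = None):
        if iv.voltages_mV.size < 6:
            raise FitError("Boltzmann fit needs at least 6 I–V points")
        self.iv = iv
        self.e_ion_fixed = e_ion_mV

    def fit(self) -> BoltzmannIVResults:
        v, i = self.iv.voltages_mV, self.iv.currents_pA
        if np.allclose(i, 0.0, atol=1e-9):
            raise FitError("all-zero currents: Boltzmann fit is degenerate")
        scale = np.max(np.abs(i))
        g0 = scale / max(np.ptp(v), 1.0)
        best, best_sse = None, np.inf
        for v_half0 in self.V_HALF_GRID:
            try:
                if self.e_ion_fixed is None:
                    p0 = [g0, v_half0, 5.0, v[np.argmin(np.abs(i))]]
                    bounds = ([0.0, -150.0, 0.1, -100.0],
                              [np.inf, 50.0, 50.0, 150.0])
                    popt, pcov = curve_fit(_boltzmann_ohmic, v, i, p0=p0,
                                           bounds=bounds, maxfev=20000,
                                           xtol=1e-12, ftol=1e-12)
                else:
                    e = self.e_ion_fixed
                    f = lambda vv, gmax, v_half, z: _boltzmann_ohmic(vv, gmax, v_half, z, e)
                    popt, pcov = curve_fit(f, v, i, p0=[g0, v_half0, 5.0],
                                           bounds=([0.0, -150.0, 0.1],
                                                   [np.inf, 50.0, 50.0]),
                                           maxfev=20000, xtol=1e-12, ftol=1e-12)
                    popt = np.append(popt, e)
                    pcov = np.pad(pcov, ((0, 1), (0, 1)))
            except (RuntimeError, ValueError):
                continue
            pred = _boltzmann_ohmic(v, *popt)
            sse = float(np.sum((i - pred) ** 2))
            if sse < best_sse:
                best, best_sse, best_cov = popt, sse, pcov
        if best is None:
            raise FitError("Boltzmann fit failed from every start")
        ss_tot = float(np.sum((i - i.mean()) ** 2))
        r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else 1.0
        names = ["gmax_nS", "v_half_mV", "z_mV", "e_ion_mV"]
        perr = np.sqrt(np.abs(np.diag(best_cov)))
        return BoltzmannIVResults(
            params=dict(zip(names, best)), bse=dict(zip(names, perr)),
            rsquared=float(r2), nobs=v.size, model_name="BoltzmannIV",
            gmax_nS=float(best[0]), v_half_mV=float(best[1]),
            z_mV=float(best[2]), e_ion_mV=float(best[3]))


def fit_boltzmann_ohmic(iv: IVCurve,
                        e_ion_mV: Optional[float] = None) -> BoltzmannIVResults:
    return BoltzmannIV(iv, e_ion_mV=e_ion_mV).fit()


# ----------------------------------------------------------------------
# fixed-timepoint inventories
# ----------------------------------------------------------------------

DEFAULT_TIMEPOINTS_MS = {"outward_peak": 1.8, "inward": 4.0, "instantaneous": 5.7}


def fixed_timepoint_measures(bundle: SweepBundle,
                             timepoints_ms: Optional[dict[str, float]] = None,
                             smooth_ms: float = 0.3) -> pd.DataFrame:
    """Per-sweep current measures at fixed latencies after step onset.

    Returns one row per step level with the (leak-subtracted, baseline-
    referenced) current at each named timepoint, the minimum current over the
    step, and the time-dependent component — the difference between the
    minimum current and the instantaneous level.  A light boxcar smoothing
    reduces single-sample noise bias at the fixed latencies.
    """
    timepoints_ms = timepoints_ms or DEFAULT_TIMEPOINTS_MS
    prot = bundle.protocol
    fs = bundle.sampling_rate
    i0, i1 = prot.step_window_samples(fs)
    for name, tp in timepoints_ms.items():
        if not 0 <= tp <= (i1 - i0) * 1000.0 / fs:
            raise ValueError(f"timepoint {name}={tp} ms outside the step window")
    k = max(int(round(smooth_ms / 1000.0 * fs)), 1)
    kernel = np.ones(k) / k
    rows = []
    v_eff = np.asarray(prot.step_levels, dtype=float) + prot.junction_potential
    for s in range(bundle.n_sweeps):
        sm = np.convolve(bundle.sweeps_pA[s], kernel, mode="same")
        base = sm[:i0].mean() if i0 > 0 else 0.0
        step = sm[i0:i1] - base
        row = {"level_mV": v_eff[s]}
        for name, tp in timepoints_ms.items():
            row[f"{name}_pA"] = float(step[min(int(round(tp / 1000.0 * fs)),
                                               step.size - 1)])
        row["min_pA"] = float(step.min())
        row["max_pA"] = float(step.max())
        if "instantaneous" in timepoints_ms:
            row["time_dependent_pA"] = row["min_pA"] - row["instantaneous_pA"]
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# paired-pulse recovery ratios
# ----------------------------------------------------------------------

def paired_pulse_ratios(bundle: SweepBundle, smooth_ms: float = 0.3,
                        settle_fraction: float = 0.2,
                        edge_skip_ms: float = 1.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Test/prepulse peak-amplitude ratios from a paired-pulse bundle.

    Within each sweep the transient amplitude of a pulse is the minimum
    current during the pulse minus the settled level over the pulse's
    trailing ``settle_fraction`` (the transient has fully inactivated by
    then).  The first ``edge_skip_ms`` of each pulse are excluded so the
    acquisition filter's step-edge ramp cannot masquerade as an inward
    transient.  Returns ``(intervals_ms, ratios)`` ordered by interval,
    ready for :func:`clampkit.kinetics.fit_recovery_double_exp`.
    """
    prot = bundle.protocol
    pp = prot.paired_pulse
    if pp is None:
        raise ValueError("bundle has no paired-pulse protocol")
    fs = bundle.sampling_rate
    dt_ms = 1000.0 / fs
    k = max(int(round(smooth_ms / 1000.0 * fs)), 1)
    kernel = np.ones(k) / k

    def pulse_amp(sweep: np.ndarray, t0_ms: float, dur_ms: float) -> float:
        a = int(round((t0_ms + edge_skip_ms) / dt_ms))
        b = int(round((t0_ms + dur_ms) / dt_ms))
        seg = np.convolve(sweep, kernel, mode="same")[a:b]
        settle = seg[-max(int(seg.size * settle_fraction), 1):].mean()
        return float(seg.min() - settle)

    intervals, ratios = [], []
    for s, gap in enumerate(pp.intervals_ms):
        sweep = bundle.sweeps_pA[s]
        pre = pulse_amp(sweep, pp.pre_hold_ms, pp.prepulse_ms)
        test = pulse_amp(sweep, pp.pre_hold_ms + pp.prepulse_ms + gap, pp.test_ms)
        if pre == 0:
            raise FitError("prepulse transient amplitude is zero")
        intervals.append(gap)
        ratios.append(test / pre)
    return np.asarray(intervals, dtype=float), np.asarray(ratios, dtype=float)
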