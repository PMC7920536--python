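"""End-to-end analysis experiments and cell-type classification.

The experiment functions wire the full chain together — simulate →
detect/measure → fit — for the canonical protocols:

* :func:`ipsc_decay_experiment` — spontaneous IPSC train at one holding
  potential; template built from the data, matched-template detection,
  event averaging, single-exponential decay fit.
* :func:`event_iv_experiment` — IPSC trains across holding potentials;
  per-voltage averaged-event amplitudes, linear I–V fit (peak conductance
  and reversal).
* :func:`t_type_experiment` — depolarizing step family from −90 mV;
  leak subtraction, peak I–V, ohmic-Boltzmann fit, activation rise and
  inactivation decay at the canonical potentials.
* :func:`recovery_experiment` — paired-pulse protocol on a potassium-blocked
  cell; test/prepulse ratios and double-exponential recovery fit.
* :func:`str_frequency_experiment` — threshold-counter event frequency
  under a pharmacology condition (e.g. strychnine).
* :func:`variance_experiment` — trend-subtracted current variance during a
  depolarizing step, one value per cell type.

Classification: :func:`build_profile` maps measured inventories to boolean
channel calls via documented thresholds; :func:`classify_offcbc` matches the
profile against an editable rule table and returns a ranked candidate set
(FMB and DB1 are separable only by morphology, so both are returned unless
a morphology flag is supplied).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, InsufficientEventsError
from .events import (EventTemplate, build_template, count_events_threshold,
                     detect_events, extract_average_event, baseline_stats)
from .iv import (IVCurve, event_iv_fit, detrend_exponential,
                 fit_boltzmann_ohmic, fixed_timepoint_measures,
                 paired_pulse_ratios, subtract_leak, window_variance)
from .kinetics import (fit_decay_exponential, fit_recovery_double_exp,
                       fit_rise_sigmoid)
from .presets import PharmacologyState, SimPreset, get_preset, cs_internal
from .protocols import StimProtocol, make_protocol
from .simulate import simulate_ipsc_train, simulate_voltage_gated

__all__ = [
    "CellTypeProfile", "RuleTable", "DEFAULT_RULES", "RunConfig",
    "membrane_hold_protocol", "ipsc_decay_experiment", "event_iv_experiment",
    "t_type_experiment", "recovery_experiment", "str_frequency_experiment",
    "variance_experiment", "inventory_experiment", "build_profile",
    "classify_offcbc",
    "run_experiment",
]

log = logging.getLogger("clampkit")

#: assumed T-type calcium reversal potential used when fitting the
#: ohmic-Boltzmann model with a pinned driving force (mV)
T_TYPE_EREV_MV = 16.5

#: smoothing applied before single-sweep kinetic measurements (ms)
KINETIC_SMOOTH_MS = 0.3

#: detection operating point for dense (~20 Hz) spontaneous trains: a short
#: sliding-fit window avoids neighbour-event corruption, compensated by a
#: higher criterion threshold
DENSE_TRAIN_FIT_WINDOW = 2.0
DENSE_TRAIN_CRITERION = 5.0


def membrane_hold_protocol(v_membrane_mV: float, duration_ms: float,
                           jp_mV: float = -10.0) -> StimProtocol:
    """Fixed-hold protocol whose *effective* membrane potential is as given.

    The command potential is ``V_m − jp`` so that the junction correction,
    applied once, lands on the requested membrane potential.
    """
    return make_protocol("fixed_hold", holding_mV=v_membrane_mV - jp_mV,
                         sweep_duration_ms=duration_ms, junction_potential=jp_mV)


def _smoothed(x: np.ndarray, fs: float, ms: float = KINETIC_SMOOTH_MS) -> np.ndarray:
    k = max(int(round(ms / 1000.0 * fs)), 1)
    return np.convolve(x, np.ones(k) / k, mode="same")


def _event_polarity(v_membrane: float, expected_reversal_mV: float) -> str:
    return "inward" if v_membrane < expected_reversal_mV else "outward"


# ----------------------------------------------------------------------
# IPSC experiments
# ----------------------------------------------------------------------

def ipsc_decay_experiment(preset: SimPreset, v_membrane_mV: float,
                          duration_s: float = 60.0, seed: int = 1,
                          criterion_threshold: float = DENSE_TRAIN_CRITERION,
                          expected_reversal_mV: float = -76.0) -> dict:
    """Simulate an sIPSC train and recover its decay kinetics.

    Returns a dict with the fitted decay τ (ms), rise time (μs), event
    counts and the detection settings used.
    """
    prot = membrane_hold_protocol(v_membrane_mV, duration_s * 1000.0)
    bundle = simulate_ipsc_train(preset, prot, seed=seed)
    fs = bundle.sampling_rate
    trace = bundle.sweeps_pA[0]
    polarity = _event_polarity(v_membrane_mV, expected_reversal_mV)
    _, sd = baseline_stats(trace)
    template = build_template(trace, fs, amplitude_threshold_pA=4.0 * sd,
                              polarity=polarity)
    events = detect_events(trace, template,
                           criterion_threshold=criterion_threshold,
                           fit_window_decay_constants=DENSE_TRAIN_FIT_WINDOW)
    avg, sem, n_used = extract_average_event(trace, events, fs)
    decay = fit_decay_exponential(avg, fs)
    rise = fit_rise_sigmoid(avg[: int(np.argmax(np.abs(avg))) + 1], fs)
    return {
        "v_membrane_mV": v_membrane_mV,
        "tau_ms": decay.tau_ms, "decay_r2": decay.rsquared,
        "rise_10_90_us": rise.rise_10_90_us,
        "amplitude_pA": float(avg[np.argmax(np.abs(avg))]),
        "n_detected": len(events), "n_averaged": n_used,
        "template_decay_ms": template.decay_tau_ms,
        "criterion_threshold": criterion_threshold, "seed": seed,
    }


def event_iv_experiment(preset: SimPreset,
                        voltages_mV: Sequence[float] = tuple(range(-100, -19, 10)),
                        duration_s: float = 30.0, seed: int = 3,
                        criterion_threshold: float = DENSE_TRAIN_CRITERION,
                        expected_reversal_mV: float = -76.0) -> dict:
    """Averaged-event amplitude versus voltage and its linear fit.

    Voltages adjacent to the expected reversal carry little signal; the
    template there is regenerated from the kinetics measured at the most
    hyperpolarized potential rather than rebuilt from data.
    """
    amps, volts, counts = [], [], []
    template_kinetics: Optional[tuple[float, float]] = None
    rng = np.random.SeedSequence([seed])
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 rng.spawn(len(voltages_mV))]
    for v, s in zip(voltages_mV, sub_seeds):
        prot = membrane_hold_protocol(v, duration_s * 1000.0)
        bundle = simulate_ipsc_train(preset, prot, seed=s)
        fs = bundle.sampling_rate
        trace = bundle.sweeps_pA[0]
        polarity = _event_polarity(v, expected_reversal_mV)
        _, sd = baseline_stats(trace)
        try:
            template = build_template(trace, fs, amplitude_threshold_pA=4.0 * sd,
                                      polarity=polarity)
            template_kinetics = (template.rise_10_90_us, template.decay_tau_ms)
        except InsufficientEventsError:
            if template_kinetics is None:
                raise
            template = EventTemplate.from_kinetics(*template_kinetics, fs,
                                                   polarity=polarity)
        events = detect_events(trace, template,
                               criterion_threshold=criterion_threshold,
                               fit_window_decay_constants=DENSE_TRAIN_FIT_WINDOW)
        if not events:
            continue
        avg, _, n_used = extract_average_event(trace, events, fs)
        amps.append(float(avg[np.argmax(np.abs(avg))]))
        volts.append(v)
        counts.append(n_used)
    iv = IVCurve(np.asarray(volts), np.asarray(amps),
                 n_per_point=np.asarray(counts))
    fit = event_iv_fit(iv)
    return {
        "voltages_mV": volts, "amplitudes_pA": amps, "n_events": counts,
        "conductance_nS": fit.conductance_nS, "reversal_mV": fit.reversal_mV,
        "rsquared": fit.rsquared, "seed": seed,
    }


def str_frequency_experiment(preset: SimPreset, drug: str = "STR",
                             v_membrane_mV: float = -20.0,
                             duration_s: float = 60.0, seed: int = 6,
                             expected_reversal_mV: float = -76.0) -> dict:
    """Threshold-counter event frequency under a bath pharmacology state."""
    prot = membrane_hold_protocol(v_membrane_mV, duration_s * 1000.0)
    pharm = PharmacologyState.from_drug(drug)
    bundle = simulate_ipsc_train(preset, prot, pharm=pharm, seed=seed)
    freq = count_events_threshold(
        bundle.sweeps_pA[0], bundle.sampling_rate,
        polarity=_event_polarity(v_membrane_mV, expected_reversal_mV))
    return {"drug": drug, "frequency_Hz": freq, "seed": seed,
            "n_true_events": int(len(bundle.ground_truth.event_times_s[0]))}


# ----------------------------------------------------------------------
# voltage-gated experiments
# ----------------------------------------------------------------------

def depol_family_protocol(hold_membrane_mV: float = -90.0, n_steps: int = 15,
                          increment_mV: float = 5.0, jp_mV: float = -10.0,
                          step_duration_ms: float = 200.0,
                          leak_steps: bool = False) -> StimProtocol:
    """Depolarizing step family specified in membrane potentials.

    With ``leak_steps`` two hyperpolarizing steps (−5 and −10 mV from the
    hold) are prepended, giving the leak-subtraction stage levels where no
    low-voltage-activated conductance opens (the P/N idea); intended for
    potassium-blocked recordings where the inward rectifier is silent.
    """
    levels = [hold_membrane_mV + increment_mV * (i + 1) for i in range(n_steps)]
    if leak_steps:
        levels = [hold_membrane_mV - 2 * abs(increment_mV),
                  hold_membrane_mV - abs(increment_mV)] + levels
    return make_protocol(
        "step_family", holding_mV=hold_membrane_mV - jp_mV,
        levels_mV=[v - jp_mV for v in levels], step_onset_ms=50.0,
        step_duration_ms=step_duration_ms,
        sweep_duration_ms=50.0 + step_duration_ms + 50.0,
        junction_potential=jp_mV)


def t_type_experiment(preset: SimPreset, seed: int = 4,
                      hold_membrane_mV: float = -90.0,
                      e_ion_mV: float = T_TYPE_EREV_MV,
                      n_repeats: int = 3) -> dict:
    """Characterize the low-voltage-activated transient inward current.

    Steps from −90 mV (availability relieved), leak subtraction, peak
    inward I–V restricted to the activation range (one step past the I–V
    peak, before the A-type outward current contaminates the measure),
    ohmic-Boltzmann fit with the driving force pinned to the package's
    assumed calcium reversal, plus activation rise at −50 mV and
    inactivation decay at the I–V peak potential.

    The step family is acquired ``n_repeats`` times and averaged per level
    before analysis, as is standard for voltage-gated current families.
    """
    prot = depol_family_protocol(hold_membrane_mV)
    rng = np.random.SeedSequence([seed])
    subs = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(n_repeats)]
    bundles = [simulate_voltage_gated(preset, prot, seed=s) for s in subs]
    bundle = bundles[0]
    bundle.sweeps_pA = np.mean([b.sweeps_pA for b in bundles], axis=0)
    ls, leak = subtract_leak(bundle)
    ft = fixed_timepoint_measures(ls)
    v = ft["level_mV"].to_numpy()
    i = ft["min_pA"].to_numpy()
    v_peak = float(v[np.argmin(i)])
    sel = v <= v_peak + 10.0
    fit = fit_boltzmann_ohmic(IVCurve(v[sel], i[sel]), e_ion_mV=e_ion_mV)

    fs = bundle.sampling_rate
    i0, i1 = prot.step_window_samples(fs)
    peak_sweep = _smoothed(ls.sweeps_pA[int(np.argmin(i))][i0:i1], fs)
    decay = fit_decay_exponential(peak_sweep, fs)

    idx_m50 = int(np.argmin(np.abs(v - (-50.0))))
    base = int(round(0.002 * fs))   # 2-ms pre-onset baseline in the segment
    sweep50 = _smoothed(ls.sweeps_pA[idx_m50], fs)
    pk50 = i0 + int(np.argmin(sweep50[i0:i1]))
    rise = fit_rise_sigmoid(sweep50[i0 - base: pk50 + 1], fs)
    return {
        "leak_g_nS": leak.g_nS,
        "iv_voltages_mV": v.tolist(), "iv_currents_pA": i.tolist(),
        "peak_potential_mV": v_peak, "peak_current_pA": float(i.min()),
        "gmax_nS": fit.gmax_nS, "v_half_mV": fit.v_half_mV, "z_mV": fit.z_mV,
        "boltzmann_r2": fit.rsquared,
        "inactivation_tau_ms": decay.tau_ms,
        "activation_rise_ms": rise.rise_10_90_us / 1000.0,
        "seed": seed,
    }


def recovery_experiment(preset: SimPreset,
                        intervals_ms: Optional[Sequence[float]] = None,
                        seed: int = 5, jp_mV: float = -10.0,
                        n_repeats: int = 3) -> dict:
    """Paired-pulse recovery from inactivation on a K-blocked cell.

    The prepulse/test structure follows the canonical protocol: 500-ms
    prepulse from −90 to −40 mV, 100-ms test pulses at increasing
    intervals.  Potassium conductances are zeroed (cesium-internal
    condition) so the transient inward current is isolated.  The series is
    acquired ``n_repeats`` times and averaged per interval before the
    ratios are computed.
    """
    if intervals_ms is None:
        intervals_ms = np.unique(np.round(np.geomspace(10, 2000, 12))).tolist()
    prot = make_protocol("paired_pulse", holding_mV=-90.0 - jp_mV,
                         prepulse_mV=-40.0 - jp_mV, test_mV=-40.0 - jp_mV,
                         intervals_ms=list(intervals_ms), junction_potential=jp_mV)
    rng = np.random.SeedSequence([seed])
    subs = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(n_repeats)]
    bundles = [simulate_voltage_gated(cs_internal(preset), prot, seed=s)
               for s in subs]
    bundle = bundles[0]
    bundle.sweeps_pA = np.mean([b.sweeps_pA for b in bundles], axis=0)
    intervals, ratios = paired_pulse_ratios(bundle)
    fit = fit_recovery_double_exp(intervals, ratios)
    return {
        "intervals_ms": intervals.tolist(), "ratios": ratios.tolist(),
        "tau1_ms": fit.tau1_ms, "tau2_ms": fit.tau2_ms,
        "frac_fast": fit.frac_fast, "frac_slow": fit.frac_slow,
        "tau2_identifiable": fit.tau2_identifiable, "rsquared": fit.rsquared,
        "seed": seed,
    }


def variance_experiment(preset: SimPreset, seed: int = 7,
                        step_membrane_mV: float = -5.0,
                        window_s: float = 0.5) -> dict:
    """Trend-subtracted current variance during a depolarizing step.

    Emulates the spontaneous-inhibition variance measure: a single long
    step to ``step_membrane_mV`` (near the excitatory reversal), IPSC train
    and channel currents superimposed, the slow voltage-activated component
    removed by single-exponential trend subtraction, and the variance of a
    0.5-s window reported.
    """
    jp = -10.0
    prot = make_protocol(
        "step_family", holding_mV=-70.0 - jp,
        levels_mV=[step_membrane_mV - jp], step_onset_ms=100.0,
        step_duration_ms=window_s * 1000.0 + 200.0,
        sweep_duration_ms=window_s * 1000.0 + 400.0, junction_potential=jp)
    bundle = simulate_ipsc_train(preset, prot, seed=seed, include_channels=True)
    fs = bundle.sampling_rate
    i0, i1 = prot.step_window_samples(fs)
    resid = detrend_exponential(bundle.sweeps_pA[0], fs, window=(i0, i1))
    start_s = (i0 / fs) + 0.1
    var = window_variance(resid, fs, start_s, window_s)
    return {"variance_pA2": var.variance_pA2, "preset": preset.name,
            "seed": seed}


def hyperpol_family_protocol(hold_membrane_mV: float = -70.0, n_steps: int = 10,
                             increment_mV: float = -5.0, jp_mV: float = -10.0,
                             step_duration_ms: float = 500.0) -> StimProtocol:
    """Hyperpolarizing step family (K_IR / I_h protocol), membrane potentials."""
    return make_protocol(
        "step_family", holding_mV=hold_membrane_mV - jp_mV,
        increment_mV=increment_mV, n_steps=n_steps, step_onset_ms=50.0,
        step_duration_ms=step_duration_ms,
        sweep_duration_ms=50.0 + step_duration_ms + 50.0,
        junction_potential=jp_mV)


def inventory_experiment(preset: SimPreset, seed: int = 8,
                         morphology: Optional[str] = None) -> dict:
    """Measure the full channel/inhibition inventory and classify the cell.

    Runs the three canonical protocols — depolarizing families from −70 and
    −90 mV and a hyperpolarizing family from −70 mV — plus a fixed-hold
    IPSC count, builds a :class:`CellTypeProfile`, and matches it against
    the rule table.
    """
    rng = np.random.SeedSequence([seed])
    s1, s2, s3, s4 = (int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(4))

    # depolarizing family from -70: peak outward K at +10 mV, 1.8 ms
    prot70 = depol_family_protocol(-70.0, n_steps=16)
    b70 = simulate_voltage_gated(preset, prot70, seed=s1)
    ls70, _ = subtract_leak(b70, leak_window_mV=(-72.0, -55.0))
    ft70 = fixed_timepoint_measures(ls70)
    at10 = ft70.iloc[int(np.argmin(np.abs(ft70["level_mV"] - 10.0)))]
    peak_outward = float(at10["outward_peak_pA"])

    # depolarizing family from -90: transient inward (T-type range)
    prot90 = depol_family_protocol(-90.0, n_steps=15)
    b90 = simulate_voltage_gated(preset, prot90, seed=s2)
    ls90, _ = subtract_leak(b90)
    ft90 = fixed_timepoint_measures(ls90)
    transient_inward = float(ft90["min_pA"].min())

    # hyperpolarizing family from -70: instantaneous vs time-dependent inward
    proth = hyperpol_family_protocol(-70.0)
    bh = simulate_voltage_gated(preset, proth, seed=s3)
    lsh, _ = subtract_leak(bh, leak_window_mV=(-82.0, -73.0))
    fth = fixed_timepoint_measures(lsh)
    most_hyper = fth.iloc[int(np.argmin(fth["level_mV"]))]
    instantaneous = float(most_hyper["instantaneous_pA"])
    time_dependent = float(most_hyper["time_dependent_pA"])

    # spontaneous event frequency at -20 mV
    freq = str_frequency_experiment(preset, drug="none", seed=s4,
                                    duration_s=20.0,
                                    expected_reversal_mV=preset.e_cl_mV
                                    )["frequency_Hz"]

    _, base_sd = baseline_stats(ls90.sweeps_pA[0][: int(0.04 * bh.sampling_rate)])
    profile = build_profile(
        peak_outward_K_pA=peak_outward, transient_inward_pA=transient_inward,
        instantaneous_inward_pA=instantaneous,
        time_dependent_inward_pA=time_dependent, sipsc_frequency_Hz=freq,
        baseline_sd_pA=base_sd, morphology=morphology)
    candidates = classify_offcbc(profile)
    return {
        "profile": dataclasses.asdict(profile),
        "candidates": candidates, "seed": seed,
    }


# ----------------------------------------------------------------------
# cell-type profile and classification
# ----------------------------------------------------------------------

#: documented decision thresholds for boolean channel calls
THRESHOLDS = {
    "k_transient_pA": 700.0,      # midpoint between the DB1 and DB2 peak I_K
    "t_type_min_pA": 15.0,        # and 3x baseline SD, whichever is larger
    "k_ir_pA": -20.0,
    "i_h_pA": -30.0,
    "high_freq_Hz": 8.0,
}


@dataclass
class CellTypeProfile:
    """Measured current/inhibition inventory of one recorded cell."""

    peak_outward_K_pA: float
    transient_inward_pA: float
    instantaneous_inward_pA: float
    time_dependent_inward_pA: float
    sipsc_frequency_Hz: float
    k_transient: bool
    t_type: bool
    k_ir: bool
    i_h: bool
    t_v_half_mV: Optional[float] = None
    na_fast: Optional[bool] = None
    axon_stratum: Optional[str] = None      # "S1" | "S2"
    morphology: Optional[str] = None        # "midget" | "diffuse"
    thresholds: dict = field(default_factory=lambda: dict(THRESHOLDS))

    def validate(self) -> None:
        if self.t_type and self.transient_inward_pA > -5.0:
            raise ValueError("profile contradiction: T-type flagged without "
                             "a transient inward current")
        if self.k_transient and self.peak_outward_K_pA < 100.0:
            raise ValueError("profile contradiction: transient K flagged "
                             "without outward current")


def build_profile(peak_outward_K_pA: float, transient_inward_pA: float,
                  instantaneous_inward_pA: float,
                  time_dependent_inward_pA: float,
                  sipsc_frequency_Hz: float, baseline_sd_pA: float = 1.5,
                  t_v_half_mV: Optional[float] = None,
                  morphology: Optional[str] = None,
                  axon_stratum: Optional[str] = None) -> CellTypeProfile:
    """Map measured inventory scalars to boolean channel calls.

    Thresholds (documented in :data:`THRESHOLDS`): transient K if the peak
    outward current at +10 mV exceeds 700 pA; T-type if the leak-subtracted
    transient inward current from −90 mV exceeds max(3×baseline SD, 15 pA);
    K_IR / I_h from the instantaneous and time-dependent inward components
    of hyperpolarizing steps.
    """
    if not np.isfinite([peak_outward_K_pA, transient_inward_pA,
                        instantaneous_inward_pA, time_dependent_inward_pA,
                        sipsc_frequency_Hz]).all():
        raise ValueError("profile measures must be finite")
    t_thresh = max(3.0 * baseline_sd_pA, THRESHOLDS["t_type_min_pA"])
    profile = CellTypeProfile(
        peak_outward_K_pA=peak_outward_K_pA,
        transient_inward_pA=transient_inward_pA,
        instantaneous_inward_pA=instantaneous_inward_pA,
        time_dependent_inward_pA=time_dependent_inward_pA,
        sipsc_frequency_Hz=sipsc_frequency_Hz,
        k_transient=peak_outward_K_pA > THRESHOLDS["k_transient_pA"],
        t_type=transient_inward_pA < -t_thresh,
        k_ir=instantaneous_inward_pA < THRESHOLDS["k_ir_pA"],
        i_h=time_dependent_inward_pA < THRESHOLDS["i_h_pA"],
        t_v_half_mV=t_v_half_mV, morphology=morphology,
        axon_stratum=axon_stratum)
    profile.validate()
    return profile


@dataclass(frozen=True)
class Rule:
    cell_type: str
    requires: dict                 # feature name -> required boolean
    freq: Optional[str] = None     # "high" | "low" | None
    morphology: Optional[str] = None
    confidence: str = "high"


RuleTable = tuple[Rule, ...]

#: Editable rule table.  DB3a/DB3b rows are lower-confidence: their
#: inventories rest on briefer published statements than FMB/DB1/DB2.
DEFAULT_RULES: RuleTable = (
    Rule("FMB", {"k_transient": False, "t_type": False, "k_ir": False,
                 "i_h": False}, freq="high", morphology="midget"),
    Rule("DB1", {"k_transient": False, "t_type": False, "k_ir": False,
                 "i_h": False}, freq="high", morphology="diffuse"),
    Rule("DB2", {"k_transient": True, "t_type": True, "k_ir": True,
                 "i_h": True}, freq="low"),
    Rule("DB3a", {"k_transient": False, "t_type": False, "k_ir": True,
                  "i_h": True}, freq="low", confidence="low"),
    Rule("DB3b", {"k_transient": False, "t_type": True, "k_ir": True,
                  "i_h": True}, freq="low", confidence="low"),
)


def classify_offcbc(profile: CellTypeProfile,
                    rules: RuleTable = DEFAULT_RULES) -> list[tuple[str, float]]:
    """Rank candidate Off-CBC types for a measured profile.

    Returns ``[(type, score), ...]`` for every rule achieving the maximal
    score, sorted by name; the result is a *set* of candidates — a unique
    answer is never forced.  When several candidates tie and a morphology
    flag is present, it disambiguates (FMB vs DB1).  A profile matching no
    rule completely yields ``[("unclassified", 0.0)]``.
    """
    profile.validate()
    freq_class = ("high" if profile.sipsc_frequency_Hz > THRESHOLDS["high_freq_Hz"]
                  else "low")
    scored = []
    for rule in rules:
        checks = [getattr(profile, feat) == want
                  for feat, want in rule.requires.items()]
        if rule.freq is not None:
            checks.append(freq_class == rule.freq)
        score = sum(checks) / len(checks)
        scored.append((rule, score))
    best = max(s for _, s in scored)
    if best < 1.0:
        return [("unclassified", 0.0)]
    winners = [r for r, s in scored if s == best]
    if profile.morphology is not None:
        morph_matched = [r for r in winners
                         if r.morphology in (None, profile.morphology)]
        if morph_matched:
            winners = morph_matched
    return sorted((r.cell_type, best) for r in winners)


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

_EXPERIMENTS = {
    "ipsc_decay": ipsc_decay_experiment,
    "event_iv": event_iv_experiment,
    "str_frequency": str_frequency_experiment,
    "t_type": t_type_experiment,
    "recovery": recovery_experiment,
    "variance": variance_experiment,
    "inventory": inventory_experiment,
}


@dataclass
class RunConfig:
    """Serializable description of one experiment run."""

    experiment: str
    preset: str = "FMB"
    seed: int = 1
    params: dict = field(default_factory=dict)
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.experiment not in _EXPERIMENTS:
            raise ConfigError(f"unknown experiment {self.experiment!r}; "
                              f"choose from {sorted(_EXPERIMENTS)}")
        try:
            get_preset(self.preset)
        except KeyError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def run_experiment(config: RunConfig) -> dict:
    """Execute one configured experiment; returns (and optionally writes)
    a JSON-serializable report.

    Identical configurations produce identical reports: all randomness is
    driven by the config seed, and no timestamps enter the report body.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    log.info("running experiment %s (preset %s, seed %d)",
             config.experiment, config.preset, config.seed)
    fn = _EXPERIMENTS[config.experiment]
    preset = get_preset(config.preset)
    result = fn(preset, seed=config.seed, **config.params)
    report = {"config": config.to_dict(), "result": result}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"{config.experiment}_{config.preset}_seed{config.seed}.json"
        path.write_text(json.dumps(report, indent=1, sort_keys=True,
                                   default=float))
        log.info("report written to %s", path)
    return report
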