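"""Ground-truth biophysical parameter sets for synthetic Off cone bipolar cells.

Each :class:`SimPreset` bundles the glycinergic IPSC statistics and the
voltage-gated channel inventory of one Off-CBC type (FMB, DB1, DB2, DB3a,
DB3b).  The packaged presets encode the measured values for those types:
IPSC rates and kinetics, chloride reversal, and the T-type calcium current's
Boltzmann activation (G_max 2.6 nS, V_0.5 −66 mV, z 3.6 mV), inactivation
(τ 6.7 ms), activation rise (1.9 ms) and recovery (fast τ1 166 ms).

Conventions
-----------
* All potentials are *effective membrane* potentials in mV (already
  junction-corrected); the simulator applies the junction offset to command
  voltages exactly once before evaluating any preset quantity.
* T-type and A-type maximal conductances are *apparent* peak-IV
  conductances: the value a Boltzmann-ohmic fit to the peak current–voltage
  relation reports.  The simulator rescales the gating time course so that
  the peak transient reproduces G·m∞(V)·(V−E) under the calibration step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "TTypeParams", "KAParams", "KSustainedParams", "KIRParams", "IhParams",
    "LeakParams", "SimPreset", "PharmacologyState", "PRESETS", "get_preset",
    "cs_internal",
]


@dataclass(frozen=True)
class TTypeParams:
    """Low-voltage-activated (Ca_V3.x-like) calcium current."""

    gmax_nS: float          # apparent peak-IV conductance
    v_half_mV: float        # activation midpoint
    z_mV: float             # activation slope factor
    e_rev_mV: float         # reversal potential
    activation_rise_ms: float   # 10–90% rise of the transient at −50 mV
    inactivation_tau_ms: float
    recovery_tau1_ms: float     # fast recovery phase
    recovery_tau2_ms: float     # slow recovery phase
    recovery_frac_fast: float = 0.75
    inact_v_half_mV: float = -80.0   # steady-state availability midpoint
    inact_z_mV: float = 3.0

    def __post_init__(self):
        _require(self.gmax_nS >= 0, "T-type gmax must be >= 0")
        _require(self.z_mV > 0 and self.inact_z_mV > 0, "slope factors must be > 0")
        _require(self.activation_rise_ms > 0 and self.inactivation_tau_ms > 0,
                 "T-type time constants must be > 0")
        _require(0 < self.recovery_tau1_ms < self.recovery_tau2_ms,
                 "recovery taus must satisfy 0 < tau1 < tau2")
        _require(0 <= self.recovery_frac_fast <= 1, "recovery fraction in [0,1]")


@dataclass(frozen=True)
class KAParams:
    """A-type (transient) potassium current."""

    gmax_nS: float
    v_half_mV: float = -5.0
    z_mV: float = 10.0
    e_rev_mV: float = -90.0
    activation_tau_ms: float = 0.6
    inactivation_tau_ms: float = 8.0
    inact_v_half_mV: float = -45.0
    inact_z_mV: float = 8.0

    def __post_init__(self):
        _require(self.gmax_nS >= 0, "K_A gmax must be >= 0")
        _require(self.activation_tau_ms > 0 and self.inactivation_tau_ms > 0,
                 "K_A time constants must be > 0")


@dataclass(frozen=True)
class KSustainedParams:
    """Sustained delayed-rectifier-like potassium current."""

    gmax_nS: float
    v_half_mV: float = -20.0
    z_mV: float = 12.0
    e_rev_mV: float = -90.0
    activation_tau_ms: float = 1.0

    def __post_init__(self):
        _require(self.gmax_nS >= 0, "K gmax must be >= 0")
        _require(self.activation_tau_ms > 0, "K tau must be > 0")


@dataclass(frozen=True)
class KIRParams:
    """Instantaneous inward-rectifier potassium current (Kir2.x-like)."""

    gmax_nS: float
    e_rev_mV: float = -90.0
    rect_v_half_mV: float = -105.0  # conducts below this potential
    rect_z_mV: float = 6.0

    def __post_init__(self):
        _require(self.gmax_nS >= 0, "K_IR gmax must be >= 0")
        _require(self.rect_z_mV > 0, "rectification slope must be > 0")


@dataclass(frozen=True)
class IhParams:
    """Slow hyperpolarization-activated cation current."""

    gmax_nS: float
    e_rev_mV: float = -30.0
    v_half_mV: float = -105.0
    z_mV: float = 5.0
    activation_tau_ms: float = 200.0

    def __post_init__(self):
        _require(self.gmax_nS >= 0, "I_h gmax must be >= 0")
        _require(self.activation_tau_ms > 0, "I_h tau must be > 0")


@dataclass(frozen=True)
class LeakParams:
    g_nS: float = 1.0
    e_rev_mV: float = -55.0

    def __post_init__(self):
        _require(self.g_nS >= 0, "leak conductance must be >= 0")


@dataclass(frozen=True)
class SimPreset:
    """Ground-truth parameters for one synthetic bipolar cell.

    IPSC decay is voltage dependent: the decay time constant is linearly
    interpolated (and clamped) between the anchors at −100 mV and 0 mV
    effective membrane potential.
    """

    name: str
    ipsc_rate_Hz: float
    ipsc_peak_conductance_nS: float
    ipsc_amplitude_cv: float
    ipsc_rise_10_90_us: float
    ipsc_decay_tau_at_minus100_ms: float
    ipsc_decay_tau_at_0_ms: float
    e_cl_mV: float
    k_sustained: Optional[KSustainedParams] = None
    k_a: Optional[KAParams] = None
    t_type: Optional[TTypeParams] = None
    k_ir: Optional[KIRParams] = None
    i_h: Optional[IhParams] = None
    leak: LeakParams = field(default_factory=LeakParams)
    noise_sd_pA: float = 2.0
    sampling_rate_Hz: float = 10_000.0
    bessel_fc_Hz: Optional[float] = 2000.0
    bessel_poles: int = 4
    series_resistance_MOhm: float = 20.0

    def __post_init__(self):
        _require(self.ipsc_rate_Hz >= 0, "IPSC rate must be >= 0")
        _require(self.ipsc_peak_conductance_nS >= 0, "IPSC conductance must be >= 0")
        _require(self.ipsc_rise_10_90_us > 0, "IPSC rise must be > 0")
        _require(self.ipsc_decay_tau_at_minus100_ms > 0 and self.ipsc_decay_tau_at_0_ms > 0,
                 "IPSC decay taus must be > 0")
        _require(self.noise_sd_pA >= 0, "noise SD must be >= 0")
        _require(self.sampling_rate_Hz > 0, "sampling rate must be > 0")

    def ipsc_decay_tau_ms(self, v_mV: float) -> float:
        """Decay time constant at membrane potential ``v_mV`` (clamped interpolation)."""
        t0, t1 = self.ipsc_decay_tau_at_minus100_ms, self.ipsc_decay_tau_at_0_ms
        frac = min(max((v_mV + 100.0) / 100.0, 0.0), 1.0)
        return t0 + frac * (t1 - t0)

    def replace(self, **changes) -> "SimPreset":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PharmacologyState:
    """Bath or puff drug condition applied to a simulation.

    ``rate_multiplier`` scales the glycinergic event rate; strychnine (STR)
    forces it to zero.  Puff-scoped states apply the multiplier only inside
    the protocol's puff window, emulating focal CPPG application in the
    presence of bath L-AP4.
    """

    drug: str = "none"
    rate_multiplier: float = 1.0
    puff_scoped: bool = False

    # multipliers for the bath drugs follow the measured mean frequency
    # ratios: L-AP4 1.4/19.2, GYKI 3.6/18; CPPG puff default 5x.
    _KNOWN = {
        "none": (1.0, False),
        "STR": (0.0, False),
        "L-AP4": (1.4 / 19.2, False),
        "GYKI": (3.6 / 18.0, False),
        "CPPG_puff": (5.0, True),
    }

    def __post_init__(self):
        _require(self.rate_multiplier >= 0, "rate multiplier must be >= 0")
        if self.drug == "STR":
            _require(self.rate_multiplier == 0.0, "STR must have multiplier 0")

    @classmethod
    def from_drug(cls, drug: str, rate_multiplier: Optional[float] = None) -> "PharmacologyState":
        if drug not in cls._KNOWN:
            raise ValueError(f"unknown drug {drug!r}; choose from {sorted(cls._KNOWN)}")
        default_mult, scoped = cls._KNOWN[drug]
        mult = default_mult if rate_multiplier is None else rate_multiplier
        if drug == "STR":
            mult = 0.0
        return cls(drug=drug, rate_multiplier=mult, puff_scoped=scoped)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


_DB2_TTYPE = TTypeParams(
    gmax_nS=2.6, v_half_mV=-66.0, z_mV=3.6, e_rev_mV=16.5,
    activation_rise_ms=1.9, inactivation_tau_ms=6.7,
    recovery_tau1_ms=166.0, recovery_tau2_ms=1000.0, recovery_frac_fast=0.75,
)

#: Packaged presets for the five Off-CBC types.  FMB/DB1 carry the measured
#: IPSC statistics (rate, conductance, reversal, kinetics); DB2 carries the
#: measured channel inventory.  DB3a/DB3b inventories are plausible fills for
#: types whose quantitative inventory is only qualitatively constrained.
PRESETS: dict[str, SimPreset] = {
    "FMB": SimPreset(
        name="FMB", ipsc_rate_Hz=19.1, ipsc_peak_conductance_nS=0.97,
        ipsc_amplitude_cv=0.4, ipsc_rise_10_90_us=180.0,
        ipsc_decay_tau_at_minus100_ms=2.1, ipsc_decay_tau_at_0_ms=4.0,
        e_cl_mV=-76.0,
        k_sustained=KSustainedParams(gmax_nS=1.0),
    ),
    "DB1": SimPreset(
        name="DB1", ipsc_rate_Hz=15.0, ipsc_peak_conductance_nS=0.80,
        ipsc_amplitude_cv=0.4, ipsc_rise_10_90_us=240.0,
        ipsc_decay_tau_at_minus100_ms=2.7, ipsc_decay_tau_at_0_ms=5.3,
        e_cl_mV=-73.0,
        k_sustained=KSustainedParams(gmax_nS=4.2),
        i_h=IhParams(gmax_nS=0.25),
    ),
    "DB2": SimPreset(
        name="DB2", ipsc_rate_Hz=0.2, ipsc_peak_conductance_nS=0.5,
        ipsc_amplitude_cv=0.4, ipsc_rise_10_90_us=250.0,
        ipsc_decay_tau_at_minus100_ms=2.5, ipsc_decay_tau_at_0_ms=5.0,
        e_cl_mV=-75.0,
        k_a=KAParams(gmax_nS=14.4),
        t_type=_DB2_TTYPE,
        k_ir=KIRParams(gmax_nS=1.6),
        i_h=IhParams(gmax_nS=0.48),
    ),
    "DB3a": SimPreset(
        name="DB3a", ipsc_rate_Hz=4.0, ipsc_peak_conductance_nS=0.4,
        ipsc_amplitude_cv=0.4, ipsc_rise_10_90_us=250.0,
        ipsc_decay_tau_at_minus100_ms=2.5, ipsc_decay_tau_at_0_ms=5.0,
        e_cl_mV=-75.0,
        k_a=KAParams(gmax_nS=5.0),
        k_ir=KIRParams(gmax_nS=1.2),
        i_h=IhParams(gmax_nS=0.5),
    ),
    "DB3b": SimPreset(
        name="DB3b", ipsc_rate_Hz=0.1, ipsc_peak_conductance_nS=0.4,
        ipsc_amplitude_cv=0.4, ipsc_rise_10_90_us=250.0,
        ipsc_decay_tau_at_minus100_ms=2.5, ipsc_decay_tau_at_0_ms=5.0,
        e_cl_mV=-75.0,
        k_a=KAParams(gmax_nS=3.0),
        t_type=dataclasses.replace(_DB2_TTYPE, gmax_nS=1.5),
        k_ir=KIRParams(gmax_nS=1.0),
        i_h=IhParams(gmax_nS=0.5),
    ),
}


def get_preset(name: str) -> SimPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


def cs_internal(preset: SimPreset) -> SimPreset:
    """Variant with potassium (and I_h) conductances blocked.

    Emulates recording with a cesium-based internal solution, the condition
    used to isolate T-type calcium currents for recovery-from-inactivation
    measurements.
    """
    return preset.replace(k_sustained=None, k_a=None, k_ir=None, i_h=None)
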