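# Methods

`clampkit` couples a biophysical voltage-clamp simulator with the analysis
pipeline used to characterize glycinergic inhibition and voltage-gated
current inventories in primate Off cone bipolar cells (Off-CBCs).  Because
no public recordings exist for this preparation, every analysis stage is
validated by *parameter recovery*: the simulator is configured with the
published measurements as ground truth, and the pipeline must recover them
from the raw synthetic sweeps.  This note describes the generative model,
the estimators, the numerical conventions, and what the synthetic data do
and do not establish.

## The generative model

A cell is a single isopotential compartment under ideal voltage clamp.
Each sweep's membrane potential is the command potential plus the liquid
junction potential (−10 mV by default), applied exactly once; all preset
parameters are expressed on the corrected (membrane-potential) scale.

### Glycinergic IPSC trains

Spontaneous IPSCs arrive as a homogeneous Poisson process at the preset
rate (19.1 Hz for FMB, 15 Hz for DB1, ≤4 Hz for the other types).  Each
event contributes a conductance

    g(t) = A · (1 − e^(−t/τ_r)) · e^(−t/τ_d),

unit-normalized at its peak, with the peak conductance `A` drawn from a
log-normal distribution (FMB mean 0.97 nS, DB1 0.80 nS; CV 0.4 — the
source reports means only, so the spread is a modelling choice).  Current
is `g(t)·(V_m(t) − E_Cl)` with the driving force evaluated pointwise, so
voltage steps mid-sweep behave correctly.  The decay constant is linearly
interpolated in membrane potential between the −100 mV and 0 mV anchors
(FMB 2.1 → 4.0 ms, DB1 2.7 → 5.3 ms), the only two points the measurements
constrain.  E_Cl is −76 mV (FMB) / −73 mV (DB1), the measured reversal of
the averaged events.

Bath pharmacology scales the event rate: strychnine to zero, the mGluR6
agonist condition by 1.4/19.2, the AMPA-receptor antagonist condition by
3.6/18 (ratios of the reported mean frequencies).  A puff-applied mGluR6
antagonist multiplies the rate (default 5×, configurable — the source
states only a significant increase) inside the protocol's puff window.

### Voltage-gated inventory

Channels are Hodgkin–Huxley-style first-order gates with Boltzmann steady
states, integrated analytically over the piecewise-constant command
segments:

* **T-type Ca** (DB2, weakly DB3b): activation midpoint −66 mV, slope
  3.6 mV — the published fit.  The maximal conductance (2.6 nS) is the
  *apparent* peak-IV conductance: the gating product is rescaled so the
  peak transient reproduces `G_max·m∞(V)·(V − E_Ca)` under the calibration
  step.  The reversal potential is not printed; +16.5 mV is derived from
  the published fit values together with the −171 pA peak at −50 mV, and
  is overridable.  Inactivation uses two recovery pools (fractions
  0.75/0.25) so recovery from inactivation at the holding potential follows
  a double exponential with τ₁ = 166 ms (printed) and τ₂ = 1000 ms (not
  printed; configurable default).  Steady-state availability is a falling
  Boltzmann at −80 mV / 3 mV — steep enough that inactivation is complete
  above −70 mV (no window-current plateau in the peak I–V) while
  availability from −90 mV stays ≈ 0.96; the source prints no availability
  curve, so this is the generator's own choice.
* **A-type K** (DB2 prominently): fast activation (τ 0.6 ms, midpoint
  −5 mV) and inactivation (τ 8 ms); conductance set so the peak outward
  current at +10 mV from a −70 mV hold is ≈ 1132 pA, the reported DB2
  mean.
* **Sustained K** (DB1): slower Boltzmann-gated conductance tuned to the
  reported 318 pA at +10 mV.
* **K_IR**: instantaneous inward rectifier, conductance gated by a falling
  Boltzmann with midpoint −105 mV so it is silent in the leak-estimation
  window yet passes ≈ −45 pA at −120 mV (DB2).
* **I_h**: slow (τ 200 ms) hyperpolarization-activated cation current
  (midpoint −105 mV, E ≈ −30 mV), sized to the reported time-dependent
  inward components (≈ −40 pA DB2, ≈ −20 pA DB1 at the deepest step).
* **Leak**: ohmic, 1 nS at −55 mV by default.

Gaussian white noise (SD 2 pA) is added and the trace passes a causal
four-pole Bessel low-pass (−3 dB at 2 kHz) before 10 kHz sampling — the
emulated acquisition chain.  One integer seed drives every stochastic
draw; identical seeds give bit-identical bundles.

### Measurement-procedure calibration

The published kinetic values are *measurement descriptors*, not raw gate
constants: a sigmoid fitted to the rising phase and a single exponential
fitted from the peak read systematically differently from the underlying
τ's of a rise×decay product (activation keeps growing past the transient
peak, and the acquisition filter reshapes fast onsets).  The generator
therefore calibrates its gate constants numerically so that the noiseless
waveform, pushed through the same filter, sampling, and fitting procedure
the pipeline applies, returns exactly the preset descriptor.  Rise times
follow one package-wide convention: the logistic is fitted to a segment
containing a 2-ms pre-onset baseline plus the rise to the peak (logistic
fits to concave-saturating rises are otherwise sensitive to where the
segment starts).

## The analysis pipeline

**Event detection.**  The matched-template detector slides an idealized
event waveform along the trace; at each lag the template is optimally
scaled and offset by least squares and the detection criterion is
scale / residual-SD (the standard scaled-template statistic).  Detections
are criterion local maxima above threshold (default 3.5), at least 1 ms
apart, with a prominence floor (max of 1.0 and 25% of the local criterion)
that suppresses duplicate detections on the flanks of large events.  The
residual SD is floored at 10⁻⁶ of the trace SD so numerically flat windows
cannot produce unbounded criteria.  The sliding fit uses the leading
rise + 2τ of the 5τ template by default in the dense-train pipelines: at
≈20 Hz one third of events have a neighbour inside a 5τ window, which
inflates the residual and masks detections; the short window restores
recall at a small matched-filter cost and is paired with a higher
criterion threshold (5.0).  Operating points were chosen by a
recall/false-discovery scan on synthetic ground truth.  Templates are
built from the data: threshold-crossing candidates aligned at their
50%-rise crossing, averaged, fitted (sigmoid rise, exponential decay), and
regenerated analytically from the fitted kinetics.  Regeneration fidelity
is a few percent because a single exponential fitted from the peak of the
product waveform reads slightly high; this is bounded in the tests.

**Threshold counter.**  For pharmacology quantification, events are
contiguous excursions beyond 2 SD of the baseline in the event-polarity
direction lasting ≥ 1 ms; baseline mean/SD come from iterative 3σ
clipping (3 iterations) so the events themselves do not inflate the
threshold.  The 1-ms width floor makes the false-positive rate on filtered
noise effectively zero.

**Kinetics.**  Rise: four-parameter logistic; the 10–90% rise is
`ln(81)·k` of the fitted slope.  Decay: `A·e^(−t/τ) + C` fitted from two
rise-durations past the peak (skipping the shoulder where activation is
still completing) over five initial decay constants, the initial τ from
log-linear regression; fits whose τ exceeds 3× the segment are rejected as
unresolvable.  Recovery: `1 − a₁e^(−t/τ₁) − a₂e^(−t/τ₂)` with the slow
constant parameterized as ≥ 3× the fast one for identifiability, and
degenerate (fully recovered) series flagged rather than fitted.

**Leak subtraction.**  The leak slope is estimated from
baseline-referenced current deltas at step levels below channel
activation, fitted through the origin.  The deltas are measured 0.4–0.7 ms
after step onset — after the acquisition filter settles (the estimate is
normalized by the filter's own step response over the same window) but
before slow gates move — so slowly activating currents cancel.  With the
published T-type activation there is measurable current at −75 mV even in
the first millisecond, so the default window is −90…−78 mV.  For
potassium-blocked recordings the cleaner option is hyperpolarizing leak
steps (−95/−100 mV from the −90 hold) measured at steady state with a free
intercept, which also removes any standing window current at the hold.
The fitted leak template passes the same Bessel filter as the data before
subtraction, so step edges subtract cleanly.

**I–V fitting.**  Synaptic amplitude–voltage relations use a straight
line (slope = peak conductance, x-intercept = reversal).  Voltage-gated
peak I–V relations use the ohmic-Boltzmann model

    I(V) = G_max (V − E_ion) / (1 + e^((V_0.5 − V)/z)),

multi-started over a −80…−20 mV grid of activation midpoints.  For the
T-type characterization the reversal is pinned to the package's +16.5 mV
convention (with only the activation limb measurable, G_max and E_ion
trade off along a ridge), and the fit uses points from the foot through
one step past the I–V peak — above that, the A-type outward current
contaminates the inward measure in potassium-based recordings, exactly as
in the real experiment.

**Experiments.**  The end-to-end experiment functions average three
repeated acquisitions per protocol before analysis (standard practice for
voltage-gated families; the source figures show averaged currents), and
single-sweep kinetic measures apply a 0.3-ms boxcar before peak-finding.

**Statistics.**  Paired comparisons use the exact two-sided Wilcoxon
signed-rank test; note that for 7 paired observations the exact two-sided
minimum is 2/2⁷ ≈ 0.0156, so smaller p-values reported for n = 7 elsewhere
must come from an approximation or a one-sided variant — the package does
not reproduce them.  Unpaired comparisons use Welch's t; multi-group
comparisons use one-way ANOVA with Tukey's HSD (α = 0.05).

**Classification.**  Measured inventories map to boolean channel calls via
documented thresholds: transient K if the peak outward current at +10 mV
exceeds 700 pA (midpoint between the reported DB1 and DB2 distributions),
T-type if the leak-subtracted transient inward from −90 mV exceeds
max(3× baseline SD, 15 pA), K_IR below −20 pA instantaneous, I_h below
−30 pA time-dependent, and "high" spontaneous-event frequency above 8 Hz
(midpoint of the simulated sparse and frequent groups).  The rule table is
data, user-editable; matching returns the full set of maximally scoring
types — FMB and DB1 share an inventory and are separated only when a
morphology flag is supplied.  DB3a/DB3b rows are marked lower-confidence:
their inventories rest on briefer published statements.

## What the synthetic data do and do not show

Passing recovery benchmarks establishes that the estimators are unbiased
and correctly implemented *under the generative model*: Poisson event
trains, a single rise×decay event shape with log-normal amplitudes,
first-order gating, stationary Gaussian noise, ideal clamp.  Real
recordings add multiquantal and correlated release, event-shape
heterogeneity, 1/f and line noise, series-resistance and space-clamp
errors, and capacitive transients — none of which are modelled (the
series-resistance quality flag at 35 MΩ is bookkeeping, not correction).
Recovery on synthetic data is therefore necessary, not sufficient,
evidence of accuracy on real cells.

## Problem sizes and numerical choices

Benchmarks use 60-s trains for decay and pharmacology measures, 30 s per
holding potential for the amplitude–voltage relation (−100…−20 mV in
10-mV steps), 5-mV step families of 200-ms steps for voltage-gated
currents, and 12 log-spaced paired-pulse intervals between 10 ms and 2 s.
Nonlinear fits use `scipy.optimize.curve_fit` with bounded parameters and
tolerances of 10⁻¹²; detection convolutions are FFT-based.  Rectifying
degeneracies (all-zero currents, flat segments, fully recovered series)
raise typed errors or set flags rather than returning nonsense.

## Known limitations

* The logistic is not the true shape of a first-order activation rise;
  the package makes the measurement well-defined by fixing the segment
  convention and calibrating the generator through it, but rise values
  from other conventions will differ by tens of μs.
* Sub-200-μs rise times are not resolvable at 10 kHz through a 2-kHz
  Bessel filter; measured rises inflate roughly in quadrature with the
  filter's ≈170-μs step response, as the tests bound.
* The matched-template detector does not decompose overlapping events;
  at 19 Hz a few percent of events within ≈2 ms of a neighbour are
  reported as one.
* The apparent T-type G_max recovered from the full pipeline runs ≈5–10%
  low (finite availability at −90 mV, residual leak-estimate error, filter
  attenuation); activation midpoint and slope are unaffected.
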