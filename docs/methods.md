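# Methods

This note documents the models behind each patchkit stage, the estimators
and their numerical choices, what the synthetic generators do and do not
emulate, and the limitations a user should know before trusting a number.

## Two-state gating model

All kinetic analysis assumes the minimal scheme

    C  —β→  O,   O  —α→  C

with exponentially distributed dwell times (rates in s⁻¹). The stationary
open probability is β/(α+β) and the equilibrium constant K = β/α. This is
deliberately the simplest adequate model: aggregated multi-state Markov
models with hidden states (and HMM-based idealization) are out of scope.

The simulator draws a Gillespie sequence starting in the closed state (a
resting channel before agonist; `start_state` overrides this), truncates
the final dwell at the requested duration, and point-samples the
piecewise-constant current: the state at each sampling instant is the
state occupied at that instant, so a dwell shorter than one sample period
can vanish from the sample vector while remaining in the ground-truth
event list. Defaults mimic a standard rig: 10 kHz sampling, unitary
current rendered on a 0 pA baseline, additive Gaussian noise (default
0.15 pA against a 1 pA opening), and a single low-pass stage.

The low-pass stage is a Gaussian kernel whose −3 dB point equals the
cutoff (default 2.9 kHz): σ_t = √(ln 2)/(2π f_c). A Gaussian kernel has a
monotone, ringing-free step response close to the multi-pole Bessel
filters used in patch amplifiers, and needs no filter-design machinery.
No further hardware emulation (amplifier dynamics, quantization) is
attempted. The noise magnitude and effective filter order of a real rig
are free parameters; only the cutoff is pinned by convention.

## Dose–response fitting and gating decomposition

Responses are modelled as `R(c) = Rmax·cⁿ/(cⁿ + EC50ⁿ)`. The fit is
nonlinear least squares over all replicate points (not the means), with
multi-start initialization: EC50 starts at the geometric mean of the
concentrations and at the concentration nearest half-maximum, n at 1 and
2, and the plateau at the maximum mean response. Among converged starts
the lowest residual sum of squares wins, ties broken by the smaller EC50.
All-zero responses and concentration-independent responses are hard
errors, not silently returned fits. `max_fixed` pins the plateau when
Po_max is known independently (e.g. from noise analysis).

Whether the Hill coefficient should be shared across genotypes is an open
design choice; the module refits n per curve, since pooling assumptions
across mutants is the stronger claim.

The decomposition inverts EC50 = Kd/(1+L) and Po_max = L/(1+L). It is
defined only for a partial agonist (0 < Po_max < 1); at Po_max → 1, L and
Kd diverge, and the code refuses rather than extrapolates. Note the
generator/fit convention: responses must be calibrated to absolute open
probability for the decomposition to be meaningful, and the
`po_calibrated` flag on `ConcentrationResponse` makes that explicit
rather than guessed.

Uncertainty on Kd and L is by nonparametric bootstrap over replicate rows
(default 1000 resamples, seeded); a delta-method propagation from the
fitted standard errors is also available. The bootstrap was chosen
because the sampling distribution of Kd = EC50·(1+L) is skewed when
Po_max approaches 1 and a linearized propagation understates that.

## Mutant-cycle energetics

LnΩ = Ln(Kd₁·Kd₄/(Kd₂·Kd₃)) with corners (WT, ligand), (mutant, ligand),
(WT, analog), (mutant, analog). The implementation computes it as a
difference of log-products for numerical symmetry, making unit invariance
and the swap symmetries exact to rounding. Coupling energy is reported as
|LnΩ| in kT multiples (bar-plot convention) with the signed LnΩ retained;
conversion to kcal/mol uses CODATA k_B and N_A and the thermochemical
calorie (4184 J). The default temperature is 297.15 K (24 °C, the
conventional conversion temperature) even though recordings are typically
at 22 °C — temperature is always an explicit argument. Classification is
strict: energy > 1.5 kT. Coupling is computed on Kd only, never on L.

## Idealization and rate estimation

Half-amplitude idealization thresholds at the midpoint of the baseline
and open levels; samples exactly at threshold keep the previous sample's
state (deterministic, hysteresis-free). Runs become dwell events. Dead
time (default 0.32 ms) is imposed retrospectively: any interior event
shorter than the dead time is merged into its predecessor, adjacent
same-state events are coalesced, and the scan repeats until stable. Edge
events are never merged away, and are flagged by position (first/last)
rather than by a separate field. A dead time below one sample period
cannot remove anything and warns.

Amplitude levels come from a 256-bin all-point histogram: the counts are
lightly smoothed (σ = 2 bins, zero-padded so edge modes keep their
prominence), the two most prominent modes at least 10 % of the range
apart are taken, and each level is refined to the mean of the samples
within a quarter-separation window around its mode — exact on noise-free
data, mode-centred under Gaussian noise. A unimodal histogram yields an
explicit one-level result instead of an invented open level. Conductance
is i/V in pS when the holding potential is given.

Rates are the exponential MLEs 1/mean(dwell), computed from interior
events only (edge dwells are censored by the record boundaries), with
standard errors rate/√n. No missed-event correction is applied by
default, since none is standard for this design; an optional first-order
correction subtracts the dead time from each dwell before averaging and
is labelled as such in the result. Open probability is the summed open
duration over the record duration, edge events included (they carry real
open time).

Φ is the unweighted OLS slope of log₁₀(opening rate) on
log₁₀(equilibrium constant) across the mutant series at one site
(minimum three points, distinct abscissae). Per-point weighting is
possible in principle but plots of three to five mutants are
conventionally fitted unweighted. Interpretation caveats (parallel
activation pathways) are interpretive, not computational, and are not
encoded.

## Stationary noise analysis

For N independent identical channels, I = N·i·Po and
σ² = N·i²·Po(1−Po), hence N = I²/(i·I − σ²) and Po = I/(N·i). The
unitary current i is an input (measured from the all-point histogram of
a single-channel record), not estimated from a variance–mean parabola;
nonstationary ensemble analysis is out of scope. Variance uses the
unbiased (n−1) estimator. An optional background variance (channels
shut) is subtracted before the identity. When σ² ≥ i·I the count is
undefined and the code raises; Po up to 1.02 is clipped to 1 (sampling
jitter), anything larger raises an inconsistency error. N is reported as
a real number; rounding is a display decision. Extra, unsubtracted
instrumentation variance biases N upward — asserted directionally in the
tests. Segment choice (stationarity, exclusion of solution-exchange
artifacts) is the user's responsibility; the analysis takes whatever
segment it is given.

## Emission spectra

The skewed band shape is an exponentially modified Gaussian: a Gaussian
of width σ (nm) convolved with a one-sided exponential of time constant
τ = |skew|·σ, mirrored for negative skew. The original analyses in this
field fit "a skewed Gaussian" in commercial software without publishing
the form; the EMG is a declared choice, and equivalence is asserted only
against this package's own generator. The generator is parameterized so
that `peak` is the mode of the curve and `amplitude` its height above
baseline.

Fitting runs three restricted least-squares branches — symmetric
Gaussian, red-skewed EMG, blue-skewed EMG (the free-location EMG is
smooth in all parameters, which matters for the optimizer) — and keeps
the lowest-RSS branch, preferring the symmetric form on ties. The
reported peak is the numerically located mode of the fitted curve, not
the Gaussian centre; for a skewed band the two differ by roughly a
half-width times the skew. Shifts are ligand minus control, classified
red/blue/no-change against a detection limit (default 2 nm, the typical
resolution of an imaging spectrograph setup); at exactly the limit the
classification is no-change. Temperature and pH covariates are assumed
experimentally controlled and are not modelled.

## Synthetic study conditions

The demo study (`make_demo_dataset`) fixes the conditions used throughout
the tests: dose–response curves at the reference WT values (Kd 975.8 µM,
L 4.263, n_H 1.74 for the primary ligand — implying EC50 185.4 µM and
Po_max 0.81 — and Kd 1564 µM, L 0.923, n_H 1.5 for the analog), 8
concentrations spanning 0.1–10× EC50, 5 replicates, response noise 0.02;
a mutant cycle with the mutant weakening ligand binding 4-fold and a
constructed LnΩ = 2 (a specific coupling); a four-mutant series at
Φ = 0.7 with ΔlogK ∈ {−0.6, −0.3, 0, +0.3} and ~2500 events per trace; a
100-channel stationary patch at Po 0.81 with 1 pA unitary current; and
spectrum pairs with true shifts +6.6, −2.5 and 0 nm at 1 % noise. The
acceptance script uses traces of ~110 s (≈2200 events) and 25–50 seeded
repeats per statistic; these sizes make every recovery criterion
statistically meaningful while keeping a full run to seconds.

What the generators do **not** emulate: baseline drift and seal
instability, correlated (1/f) noise, multi-channel contamination of
"single-channel" patches, solution-exchange transients in macroscopic
recordings, photobleaching and spectrograph calibration error. Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to every artifact of real recordings —
artifact rejection remains an upstream, user-controlled step.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give bit-identical outputs, and every simulated object
  records its seed.
- Dwell durations from idealization are integer multiples of the sample
  period; boundary samples at exact event starts belong to the new event;
  a sample exactly at threshold keeps the previous state.
- Events shorter than the dead time are removed strictly
  (duration < dead time, with a 10⁻¹² s guard against float rounding).
- Report export fixes column order and serializes floats at 10
  significant digits, so identical inputs produce identical bytes.
- Physical constants are CODATA (via scipy.constants); kcal means the
  thermochemical calorie.

## Known limitations

- Exponential-MLE rates are biased low by missed events; at the default
  conditions (dead time 0.32 ms against mean dwells of 20/80 ms) the bias
  is ~1–2 %, far below the sampling error of a few-thousand-event record,
  but it grows quickly as dwells approach the dead time. The optional
  first-order correction mitigates, not eliminates, this.
- The Hill fit treats replicates as exchangeable and homoscedastic.
- Mutant-cycle error bars rely on bootstrap resampling of replicates; with
  3–5 replicates per curve the bootstrap undercovers slightly.
- The EMG mode is found by bounded scalar optimization over the fitted
  range; spectra whose true peak lies outside the scanned wavelength
  window are extrapolations and flagged only by the fit bounds.
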