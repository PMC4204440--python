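# Methods

`glyqsp` is a mechanistic (quantitative systems pharmacology) model of how
extracellular glycine shifts cortical excitation/inhibition balance through
NMDA-receptor subunit pharmacology, and of how that shift propagates to the
imaging-level readouts (BOLD, striatal activity) used as a proxy for
negative symptoms in schizophrenia. This note records the model equations,
the parameter choices that matter, what the synthetic data emulate, and the
numerical decisions, in the package's own words.

## Glycine-site pharmacodynamics (`pharmacology`)

Glycine potentiation of NMDA conductance per synapse class follows a Hill
relation `g = gmax * Gly^n / (Gly^n + EC50^n)`. Two lumped classes are
used: **e-e** (pyramidal-pyramidal, NR2A/NR2B-dominated) and **e-i**
(pyramidal-to-interneuron, NR2C/NR2D-dominated). Per-subunit EC50/slope
estimates from five published whole-cell studies are shipped as
`GLYCINE_SUBUNIT_STUDIES`; `subunit_averages` takes arithmetic means over
non-missing cells.

The mechanistically central quantity is the **e-i/e-e potentiation ratio**.
When the e-e class has the higher Hill slope (and usually higher EC50), the
ratio dips below 1 over a window of glycine concentrations: excitation is
transiently potentiated more than inhibition, and the network outcome
passes through a maximum — an inverse-U dose-response. `find_ratio_extremum`
locates the ratio minimum by a 1000-point log-spaced scan plus bounded
scalar refinement in log-concentration (ties toward the lowest glycine;
a flat curve, relative range ≤ 1e-12, is never flagged as a minimum).
`classify_dose_response` labels parameter pairs `beneficial_U` (interior
minimum in 0.5-10 µM with ratio < 1), `subphysiological_minimum`
(minimum below 0.5 µM) or `monotonic`. Two analytic facts worth recording:
a ratio of equal-slope Hill curves is always monotone (so the 1:1
slope-ratio plane contains no beneficial cells), and the minimum location
scales with the EC50 pair.

With the lumped literature-style parameters (e-e 0.35 µM/1.84, e-i
0.25 µM/1.1) the dense-grid minimum is 0.9366 at 1.26 µM. The published
figure caption for these parameters reports 0.93 at 1.1 µM and a
re-crossing of 1 near 30 µM; the re-crossing is impossible for pure Hill
forms (the ratio approaches 1 from below), so the plotted currents likely
carry extra scaling. Tests therefore assert tolerance bands
(ratio ∈ [0.90, 0.96], location ∈ [0.8, 1.6] µM) rather than those exact
figures.

Receptor internalization at high glycine is an optional second Hill factor
`(1 - hill(Gly; EC50_int, n_int))` per class, with EC50 near 40 µM and
slope defaulting to 1 (only the EC50 range is established experimentally).

## GlyT1 transporter (`transporter`)

GlyT1 cotransports glycine with 2 Na⁺ and 1 Cl⁻ (net +1 charge inward).
Setting the electrochemical free energy of a cycle to zero gives

    Gly_out = Gly_in · (Na_in/Na_out)² · (Cl_in/Cl_out) · exp(F·Vm/(R·T))

Every factor is monotone, so the maximum over a physiological box sits at
the corner maximizing each factor; `max_equilibrium_over_ranges` evaluates
all corners and reports the maximizer. Defaults: Na_out 140 mM (standard
extracellular value; not stated in the source literature), Cl_out 120 mM,
Na_in 10-20 mM, Cl_in 6-12 mM (two values — 6 and 12 mM — are reported in
different places; both ends are kept rather than picking one), Gly_in up
to 5 mM, Vm −75 to −40 mV (union of the reported astrocyte ranges), 310 K
with RT/F computed from `scipy.constants`. Over this box the ceiling is
≈ 2.3 µM, comfortably below 10 µM — which is what makes the low-micromolar
ratio minimum pharmacologically reachable and high-glycine saturation
hard to achieve in vivo. Uptake kinetics are Michaelis-Menten with
Km 15 µM and turnover 10 s⁻¹.

## Cortical network (`cortical`)

20 pyramidal cells and 10 interneurons, single-compartment
Wang-Buzsáki-type Hodgkin-Huxley membranes (instantaneous Na⁺ activation,
first-order h/n gating; gating temperature factor φ = 5 for interneurons,
1 for pyramids), plus two neuromodulation-target channels on pyramids: a
slow K⁺ current I_ks (0.25 mS/cm², τ = 75 ms) and a high-voltage-activated
Ca²⁺ current (0.02 mS/cm²). Synapses are exponential AMPA (τ 2 ms), GABA-A
(τ 8 ms, E = −70 mV) and NMDA (τ 100 ms) with the standard Mg²⁺ block
`1/(1 + [Mg]/3.57 · exp(−0.062 V))`. Gating uses Rush-Larsen exponential
updates and the membrane explicit Euler at dt = 0.05 ms.

Glycine enters by scaling NMDA maximal conductances with the
class-appropriate potentiation: e-e weights by the NR2A/B factor, e-i
weights by the NR2C/D factor. The same subunit segregation is applied to
the **background synaptic bombardment**: each neuron receives Poisson
AMPA-like events plus an NMDA component whose amplitude is glycine-scaled
(NR2A/B on pyramids, NR2C/D on interneurons). This extrinsic-afferent NMDA
route is what lets glycine shift tonic E vs I drive smoothly; a purely
recurrent route makes a 30-neuron circuit switch all-or-none.

The circuit's operating point is the package's own calibration (the
original authors' calibrated network is unpublished). It was chosen once,
by measuring the sensitivity of the pyramidal rate to separate ±20%
perturbations of the e-e and e-i NMDA factors and placing their ratio near
1 (≈ 0.93 at the default point): in that inhibition-tracking balanced
regime a *common* scaling of both classes cancels (identical e-e/e-i
pharmacodynamics give a glycine-flat outcome, relative range ≈ 6%) while
*differential* scaling moves the rate, reproducing the ratio-driven
inverse U. The load-bearing defaults: interneurons tonically depolarized
(bias 0.9 µA/cm², so they respond linearly rather than rectifying),
pyramidal bias 2.5 µA/cm², per-neuron bias jitter σ = 0.25 (heterogeneity
smooths the population transfer function), i→e GABA 0.05 mS/cm² at
connection probability 0.8, background NMDA amplitudes 0.004 (e) and
0.0028 (i), recurrent NMDA 0.005 (e-e) and 0.025 (e-i). Schizophrenia
pathology — fractional NMDA and GABA conductance reductions, a
dopamine-coupling deficit, and a background-noise increase (placeholder
default 0.3 each, inside the sensitivity sweep ranges) — is applied before
simulation; the NMDA reduction acts on the recurrent weights, with
extrinsic-afferent pathology carried by the noise term.

Protocol: a 3 µA/cm² current pulse to 10 pyramidal cells at t = 2000 ms
for 50 ms triggers a synchronized epoch that degrades under noise and five
independently driven distractor pyramids. Readouts: spike trains, the mean
pyramidal rate over stimulus-onset→end (the "network outcome"), and
population activities binned at 10 ms, smoothed (5-bin moving average) and
normalized to a pre-stimulus baseline of 1 with a 0.5 Hz floor (so silent
traces normalize to a flat 1 rather than 0/0). Runs are bit-reproducible
given the seed. dt-halving changes the seed-averaged rate by < 2%.

Receptor→channel couplings are a table `(receptor, parameter, gain)`;
a parameter is scaled by `1 + gain · X_eff` (clipped at 0, stacking
multiplicatively). Only D1 ships nonzero gains (I_ks −0.5, HVA Ca +0.3,
the classic cortical dopamine signature); other receptors are accepted
with zero gains because no coupling magnitudes are established — gains are
user data.

## Ventral striatum (`striatum`)

The medium spiny neuron integrates Kir2, A-type K⁺, Cl⁻, L-type Ca²⁺,
slow K⁺ (the otherwise-undefined slow potassium term), leak, and standard
Na⁺/K⁺ spike currents (added so spike-count readouts exist), driven by
gated cortical glutamate. Kir2 is implemented literally as printed:
`g = 1.2 / (1 + exp(−(V+111)/−11))` mS/cm², E_K = −90 mV, times the D1
activation scale u — with V_c = −11 mV the conductance *falls* with
depolarization (inward rectification), and g(V_h) = ḡ/2 exactly
(I = −12.6 µA/cm² at V_h with u = 1). A-type/Cl⁻/Ca²⁺/slow-K kinetics are
standard textbook Boltzmann forms; their half-activations and time
constants are labeled assumptions recorded in `MSNParams`.

Three classes are simulated (SP⁺/D1 direct, Enk⁺/D2 indirect, dual).
Modulation algebra: serotonergic receptors shift dopamine release
linearly, `da = 1 + k_2C·(−ΔX_5HT2C) + k_3·ΔX_5HT3` (clipped at 0); the
class-appropriate dopamine factor `(1 + X_D1,2)·da` scales Kir2 and L-type
Ca²⁺ (D1 cells) or A-type K⁺ and presynaptic glutamate (D2 cells,
inhibitory on release); M1 scales the Cl⁻ channel, M2 the afferent drive,
α1A the hippocampal/amygdala gate (default gate: square pulse). All linear
gains default to 0.5 and are calibration tunables, not measured constants.
The population readout is a class-weighted mean firing rate (equal weights
by default) — a documented choice, since no combining formula is
established; it is linear in spike counts and 0 for a silent population.

## BOLD hemodynamics (`bold`)

Normalized drives u_e, u_i (baseline 1) pass through a logistic transfer
(steepness c = 2.5, threshold d = 1.6) rescaled so baseline 1 maps to 1
(the sigmoid's placement is not specified in the source; applying it to
the neural drives preserves the baseline fixed point). Delayed drives
(δ = 0.5 s) enter damped second-order responses for normalized glucose
consumption g_e, g_i (efficacies a_e = 1.2, a_i = 0.4; τ = 1 s) and a
flow-inducing signal (ε = 3.0, τ_s = 0.8 s, τ_f = 0.4 s). Oxygen
consumption mixes `m = (γ·m_e + m_i)/(γ+1)` with `m_e = g_e(2−x)/(2−x0)`;
the oxygen-glucose index x defaults to the constant x0 = 1 (its dynamics
are nowhere defined; a hook accepts an external x(t)). The venous balloon
uses transit time t₀ = 1 s, viscoelastic τ = 10 s and Grubb exponent
α = 0.4, with the implicit outflow coupling solved algebraically:
`dv/dt = (f − v^(1/α))/(t₀+τ)`, `f_out = v^(1/α) + τ·dv/dt`. BOLD is
`y = V₀(a₁(1−q) − a₂(1−v))` with V₀ = 0.02, a₁ = 3.4, a₂ = 1.0 (a₂'s
source citation is garbled, so the neutral value 1.0 is used,
configurable). ε = 3.0 places the steady flow response about twice the
oxygen-consumption response — the physiological flow-metabolism
uncoupling; with a Friston-style ε = 0.5 the metabolic term dominates and
the step response comes out negative. Integration is fixed-step RK4,
dt ≤ 0.01 s; at baseline every derivative vanishes identically, and
halving dt moves the step-response peak by < 1%.

## Receptor competition (`receptors`)

Steady-state mass action at one receptor: ligand occupancy
`(C/Ki)/(1 + Σ C_j/Ki_j)`, activation = occupancy-weighted intrinsic
activity (neurotransmitter = full agonist; antipsychotics default to
neutral antagonists). Presynaptic autoreceptor feedback rescales release
by `1 + gain·(baseline − activation)` and is solved by damped fixed-point
iteration to 1e-8. This steady-state layer is a documented simplification
of the time-resolved, voltammetry-calibrated synapse models it stands in
for; the interface (context + ligand list) admits a dynamic backend.
`occupancy_to_concentration` inverts the binding relation (closed form
without feedback, Brent root-finding with it) — the step that turns a PET
tracer displacement into a functional intrasynaptic concentration. The
relative-activation statistic `(A − C)/C` is the interface to the circuit
modules. Feedback gains and transmitter baselines are config-level user
data (none are established per synapse).

## Calibration (`calibration`) and pipeline (`pipeline`)

The negative-symptom proxy is `0.4·cortical + 0.6·striatal`, with cortical
= Balloon BOLD summary (×1000, percent-signal-change scale; peak by
default, time-integral optional) and striatal = MSN population rate (Hz).
The weights are applied to these natural units; the subsequent linear fit
absorbs any affine rescaling. The MSNs are driven by the *absolute*
smoothed cortical rate (normalized by a nominal 15 Hz reference) — the
baseline-normalized u_e would cancel exactly the glycine dependence the
striatum is supposed to inherit. Replicate trials pool by
patient-count-weighted means; `calibrate` fits ordinary (optionally
n-weighted) least squares and reports Pearson r, slope SE and residuals;
a linear map is used throughout (the proxy→PANSS functional form is not
established; the scatter-plot framing of the published calibration is
consistent with linear).

Seed fan-out: a global seed spawns independent per-stage streams through
`numpy.random.SeedSequence((global, stage, index))`, all below 2³¹, so any
stage can be re-run in isolation.

## Synthetic trials (`synthetic`)

The real calibration database (34 drug-dose records) is not deposited.
The generator emulates its schema: per-drug log-uniform Ki (1-3000 nM)
over 7 receptors, doses mapped to synaptic concentration at a fixed
50 nM/mg conversion, D2 occupancy via the competition layer, and a
deterministic surrogate proxy — a fixed linear read of the per-receptor
relative activations (synthetic stand-in for a full circuit evaluation,
which no fixed truth map could anchor without the clinical data).
Observed ΔPANSS = truth map (slope 3, intercept −2) + noise. Two noise
modes: plain Gaussian (`noise_sd`, for Monte-Carlo slope-recovery tests),
or — the default — noise orthogonalized against the proxy and scaled so
the realized sample correlation equals the target (0.65). The second mode
interprets "noise tuned to a target correlation" exactly; it also makes
the fitted slope coincide with the truth by construction (orthogonal
residuals leave OLS unchanged), which the recovery tests state rather than
hide. What passing recovery tests show is that the calibration machinery
is correct and well-conditioned at the published n = 34 and r ≈ 0.65 —
not that the real clinical correlation is reproduced; that claim would
need the undeposited database.

## Sensitivity (`sensitivity`)

Range-based only: a parameter is excursed by fractions of its calibrated
value, the model outcome (default: the dose-response optimum of the
composite proxy) is re-evaluated seed-averaged on the grid, and
`effect_size = ((max% − min%)/100)/(hi_frac − lo_frac)`. The published
table of ten effect sizes is reproduced from its printed extreme/range
columns for nine rows; the GABA-reduction row does not satisfy the stated
formula (the printed extremes over ±10% give 2.66, not the printed 1.620)
and is asserted as inconsistent rather than silently corrected.
Asymmetric printed ranges (±41%, ±24%) are honored per row.

## Problem sizes and test design

Default simulations are sized for a single CPU: network runs are 6 s of
simulated time at dt = 0.05 ms (≈ 0.4 s wall each, numba-compiled), the
inverse-U check uses 7 log-spaced glycine points × 10 paired seeds per
pharmacodynamic condition, the calibration-recovery check 100 generator
seeds × 34 trials, the classification map 20×20 EC50 cells × 5 slope
ratios. Statistical claims use paired seeds (common random numbers) and
sign tests at ≥ 9/10; the "flat" control is asserted as relative range
< 15% and < 1/3 of the inverse-U curve's range, with no both-sided
interior-maximum signature.

## Known limitations

* The circuit is 30 neurons; its operating point is a designed balanced
  regime, not a fit to primate recordings or the original calibrated
  platform. Absolute rates and effect magnitudes are therefore not
  comparable to the published clinical point predictions (the 2-2.5
  PANSS-point effect and the internalization collapse thresholds), which
  depend on the authors' unpublished calibration.
* The ee=ei "flat" control is flat to ~6%, not exactly flat: a spiking
  network only approximates pure ratio dependence.
* D-serine (Na⁺-independent transport), zinc/polyamine/neurosteroid
  modulation, comedication interactions, and downstream basal-ganglia
  pathways are out of scope by design.
* The receptor layer is steady-state; fast transmitter transients and
  presynaptic facilitation/depression are not represented.
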