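# Methods

`acxsim` implements a microcircuit model of primary auditory cortex with
one excitatory population (Exc) and two inhibitory subpopulations
(parvalbumin-positive, PV; somatostatin-positive, SST), at two levels of
description that share the same stimulus and optogenetic machinery: a
dimensionless Wilson-Cowan rate model and a conductance-based spiking
network of adaptive exponential integrate-and-fire (AdEx) neurons.

## Rate tier

### Single iso-frequency unit

Each population activity x ∈ {u (Exc), p (PV), s (SST)} is a normalized
rate in [0, 1] obeying

    τ_x dx/dt = −x + f(drive_x − θ_x),

with a saturating threshold-linear gain f (slope r = 3, clipped to
[0, 1]), thresholds θ = (0.7, 1, 1) for (Exc, PV, SST), and membrane time
constants τ = 10 ms.  The within-unit weight matrix (rows postsynaptic
e, p, s; columns presynaptic) is

    W = [[1.1, 2, 1],
         [1,   2, 2],
         [6,   0, 0]],

so SSTs receive no inhibition and no thalamic drive — their tone response
is disynaptic (through Exc) and therefore delayed relative to PV, which is
the temporal asymmetry behind most of the circuit's effects.

Tones enter Exc and PV as q·g(t)·i(t): i(t) jumps to 1 at tone onset and
decays with τ_q = 10 ms; the slow thalamic depression resource g obeys

    dg/dt = (1 − g)/τ_d1 − g·i/τ_d2,    τ_d1 = 1500 ms, τ_d2 = 20 ms,

so repeated tones deplete the drive over seconds (the substrate of
stimulus-specific adaptation) and recovery is slow.  Optogenetic
perturbations are additive terms inside the PV and SST gain arguments.

### Three-unit tonotopy

Three copies of the unit (f1, center f*, f2) are coupled by lateral
Exc-sourced weights (Exc→Exc 0.667, Exc→PV 1.25, Exc→SST 0.125; edges
connect to the center, the center receives the mean of the edges) and a
facilitating lateral SST→Exc synapse (−b·F_i·s_lat with b = 1).  Thalamic
input spreads to the adjacent unit with fraction α = 0.65.  The PV→Exc
weight depresses as w_ep − a(1−D_i) with a = 0.5.  By default F_i = 1−g_i
and D_i = g_i (the depression resource is reused as a proxy, since both
are driven by the same input); the full first-order ODEs are available
via `use_proxies=False`.

The published model description gives the facilitation strength `b` two
different values (2 and 1); we default to 1, under which the lateral
facilitating term reduces to the plain −F_i·s form.

### Baseline-inhibition regimes

A slow facilitation variable integrates all thalamic input,
dFbar/dt = −Fbar²/1500 + Ibar/100, and its asymptote against the
threshold F_th = 0.22 selects the baseline state: weak inhibition (W
above, s_th = 1) or strong inhibition (w_ep = 3, w_es = 3, s_th = 0).  A
sigmoidal blend of the two regimes (gain 25) is available, but the
default is the hard switch resolved once per paradigm before the run.

The implemented Fbar integration does not reproduce the published
per-paradigm classification at the stated constants: under every input
reading we constructed (unit-amplitude tone kernels, duty-cycle square
waves, q- or g-scaled traces) all four paradigms integrate to asymptotes
on the same side of 0.22, because the stimulus duty cycles differ by at
most a factor ~2 while the threshold would need a factor ~8 separation.
The paradigm presets therefore pin the regime stated per paradigm —
oddball (SSA) weak; forward suppression, tuning-curve adaptation and the
PV-activation paradigm strong — and `regime="auto"` exposes the
Fbar-threshold path.  Note on forward suppression: the source states both
regimes in different places; only the strong regime reproduces the
bidirectional PV/SST effects (see Design choices), so the preset ships
strong.

### Integration

Fixed-step classical RK4 at dt = 0.1 ms from the rest state (activities
0, g = 1, F = 0, D = 1, Fbar = 0; no burn-in).  Tone onsets are exact
jumps of the input state applied on the step grid; within a step the
input decays analytically, and tone-locked optogenetic windows are
evaluated pointwise at the RK4 stage times.  Because the gain function is
only piecewise smooth, the effective convergence order drops at threshold
crossings; RK4 at dt = 0.1 ms agrees with explicit Euler at dt = 1 µs to
better than 1e-3 (maximum absolute error over activity traces), which is
far below any quantity reported here.  Long oddball streams (500 tones,
200 s) integrate in a few seconds (numba-compiled kernel).

## Spiking tier

Three units of 1600 Exc, 200 PV and 200 SST neurons.  Somatic
compartments follow the AdEx equation

    C_m dV/dt = −g_L(V−E_L) + g_L Δ_T exp((V−V_T)/Δ_T) − w + I(t),

with per-population constants: Exc (180 pF, −60 mV, 6.25 nS, Δ_T = 1 mV,
V_T = −40 mV, 350 pA baseline), PV (80 pF, 5 nS, Δ_T = 0.25 mV, V_T =
−40 mV, 50 pA), SST (80 pF, 5 nS, Δ_T = 1 mV, V_T = −45 mV, 25 pA).
Adaptation obeys τ_w dw/dt = a_w(V−E_L) − w with a spike-triggered
increment; a_w = 4 nS, τ_w = 150 ms, b_w = 0.08 nA, refractory 2 ms, and
spike cutoff V_T + 5Δ_T are conventional AdEx values chosen by this
package (the source states none), exposed in `SpikingPopulationParams`.

Excitatory neurons are two-compartment ball-and-stick models: the
dendrite (same C_m, g_L) couples to the soma through g_sd = 18.75 nS with
somatic-to-total surface ratio κ = 0.3, receives all SST inhibition, and
the soma-side coupling current is scaled by (1 + b·F) with b = 3 and a
slow facilitation F driven by the tone square wave (τ 1000/250 ms).

Synapses are conductance-based with exponential decay (1 ms everywhere
except Exc→PV 25 ms and Exc→SST 15 ms; E_exc = 0 mV, E_inh = −67 mV).  A
presynaptic spike increments the class conductance by g_max/n_X with n_X
the presynaptic population size per unit; peak conductances

    Gmax = [[20, 40, 20], [240, 40, 12], [120, 0, 0]] nS

follow the same zero structure as the rate model (the printed matrix is
typographically ambiguous; this parsing keeps g_ep/g_es consistent with
the weak-regime override 38/19 nS and gives SSTs their Exc drive).  The
PV→Exc current is additionally scaled by a·D(t) (a = 1.7) with a slow
depression D driven by the tone square wave (τ 1000/250 ms).

Thalamic current to Exc and PV is q·I_fast·D_slow·D_fast per unit, with
τ_I = 1 ms, τ_D,fast = 10 ms (within-tone depression toward zero under
the grouping d(D_fast)/dt = (1 − D_fast − I_sq)/τ), and the slow pair
1000/250 ms; adjacent units receive a 0.85-scaled copy.  q = 5 nA for
tone paradigms (1.3 nA for forward suppression), reusing the rate-tier
numbers on the nA scale.

Connectivity is Bernoulli per ordered pair: within-unit p = 0.1 (Exc→Exc)
and 0.6 (all other classes), adjacent-unit p = 0.1 for excitatory-source
classes only; no self-connections.  Membrane noise is an additive
Euler-Maruyama voltage term with per-step standard deviation
σ√(2dt/τ_m), σ = 20 mV — the stationary free-membrane voltage std is
then 20 mV (soma only; the source states only the std).  Integration is
Euler-Maruyama at dt = 0.05 ms with exact conductance decay between
spikes; runs are bit-reproducible per (network seed, simulation seed).

## Paradigms

All stimulus timing is fixed: oddball 100 ms tones every 400 ms on the
two edge units with 90/10 standard/deviant probabilities (deviants never
first, never consecutive; two counterbalanced blocks swap the roles with
identical timing); forward suppression 50 ms masker + 20 ms gap + 50 ms
probe to the center, one independent trial per masker frequency plus a
masker-absent reference trial, each from rest; tuning-curve adaptation
trains of eight 100 ms tones (300 ms ISI) per unit, 2400 ms between
trains; single-tone 50 ms at 0.1 s in a 1 s trial.  Oddball blocks
default to 500 tones (the source does not state trial counts; the CSI is
stable to ~0.01 beyond ~200 tones).

Optogenetics: tone-locked suppression windows open 100 ms before tone
onset and close 100 ms after tone offset; tone-locked *activation*
windows coincide with the tone.  The pre-onset lead is documented for
suppression only, and applying it to SST activation (amplitude 1.2 above
the SST threshold 1) would tonically activate SSTs before every tone and
collapse the standard response entirely — the tone-coincident reading
reproduces the published CSI predictions.  Sustained mode (tuning-curve
adaptation, PV activation) covers the whole run.

## Metrics

* **Tone response**: peak (default for CSI, forward suppression, tuning
  curves) or mean of the center-unit Exc trace over the tone window.  The
  peak convention is what makes the published validity floor (standard
  response < 0.1 masked) consistent with an unmasked control point.
* **CSI**: (d(f1)+d(f2)−s(f1)−s(f2)) / (d(f1)+d(f2)+s(f1)+s(f2)), with
  deviants pooled over all deviant tones and standards over positions ≥ 2
  after a deviant, from the two counterbalanced blocks; masked invalid
  below the response floor or at Exc saturation.
* **Feedforward correlation**: Pearson correlation between the Exc trace
  and the thalamic input over tone onset → +300 ms.  Rate tier: the input
  profile i(t) itself (the depression resource is a separate variable,
  not part of the plotted input), no alignment.  Spiking tier: the
  thalamic current trace; the PV-activated (delayed) response is aligned
  by its cross-correlation peak before comparison.
* **E/I balance**: least-squares slope through the origin of excitatory
  on inhibitory current into Exc, pooled over all suprathreshold samples
  of runs across input strengths.  Rate tier: single-unit circuit,
  recurrent w_ee·u against w_ep·p + w_es·s (the thalamic drive is the
  varied input, not a circuit current) — at saturation this ratio is
  pinned at w_ee/(w_ep+w_es) = 1.1/3 ≈ 0.37.  Spiking tier: mean
  synaptic currents into center Exc neurons, thalamic current counted as
  excitatory drive.

## Design choices on genuinely open points

* Forward-suppression trials are independent runs from rest; running them
  back-to-back would accumulate center-unit thalamic depression until the
  q = 1.3 probe drive falls below the Exc threshold and the reference
  response vanishes.
* Forward suppression operates in the strong-inhibition regime.  In the
  weak regime the same-frequency probe sits exactly on the Exc threshold
  and the published bidirectional effects (PV suppression deepens,
  SST suppression weakens the preferred-frequency suppression) cannot be
  expressed; in the strong regime all three directional claims hold with
  the tabulated amplitudes.
* Population rates are 1 ms spike-count histograms normalized per neuron,
  Gaussian-smoothed with σ = 5 ms.
* Spiking experiments default to 5 seeds (feedforward correlation) and
  3 seeds (balance) with mean reporting.

## Known limitations

* The spiking tier's printed conductance matrix admits several parsings;
  under the adopted one the Exc→PV drive (240 nS, 25 ms decay) makes PV
  and SST tonic rates high (hundreds of Hz) and leaves the Exc response
  tightly locked to the thalamic current.  Consequences: the spiking
  control feedforward correlation computes to ≈ 0.96 rather than the
  published 0.87 (the PV-activated value ≈ 0.96 matches 0.95), and the
  spiking balance slope is composition-sensitive (≈ 3.3 with thalamic
  drive counted as excitatory, ≈ 0.08 without, against a published 2.5).
  Alternative parsings can be explored through `SynapseParams.Gmax`.
* The model has no population-spike mechanism, no NMDA/GABA-B kinetics,
  no subthreshold modulation, and the tonotopy is three abstract
  iso-frequency channels (no frequency axis in Hz).
* The synthetic protocols are noiseless and perfectly periodic apart from
  the Bernoulli deviant placement; real recordings add trial-to-trial
  gain variability that none of the passing tests here probe.
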