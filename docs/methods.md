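# Model and methods

## Morphology and passive properties

The cell is a simplified L5 pyramidal neuron: a cylindrical soma
(35 x 23 um) carrying one apical dendrite (350 x 3.5 um), two basal dendrites
(200 x 1.2 um each) and an axon. The axon comprises a 45-um, 1.2-um-thick AIS
(three equal parts: proximal, middle, distal; the partition is configurable), a
50-um myelinated segment, then alternating 1-um nodes of Ranvier and 2-um
myelinated internodes. Passive parameters are uniform: R_m = 25,000 Ohm cm^2,
C_m = 1 uF/cm^2 (0.5 in myelinated internodes), R_i = 150 Ohm cm. Everything
is discretized into isopotential cylindrical compartments of at most 1 um
(lateral-surface area convention, ends excluded), giving ~1,370 compartments
at the defaults.

Two morphological choices are ours. First, with 2-um internodes the
node/internode chain is electrically compact, so the default axon carries 150
node/internode pairs (~460 um past the myelinated segment) to keep the sealed
axon end electrotonically remote from the AIS; a short stub otherwise steals
spike initiation at its tip. Second, the axon terminates in a passive
5 x 5 um bleb, the standard representation of the cut axon end in acute
slices; it suppresses the artefactual excitability of a sealed thin tip.
Both are config knobs (`morphology.n_node_pairs`, `morphology.terminal_bleb`).

## Channels

Na conductance densities (pS/um^2) follow the immunohistochemistry-motivated
layout: Na_V1.2 at 200 in soma and apical dendrite, 40 in basal dendrites, a
200->800 linear ramp along the proximal AIS and constant 800 in the middle
AIS; Na_V1.6 ramping 800->0 along the distal AIS and 1200 at nodes;
no Na in internodes. Na_V1.6 steady-state activation and inactivation are
left-shifted by 6 and 3 mV relative to Na_V1.2. E_K = -85 mV. E_Na is fixed
at the Nernst value of the resting pools ([Na]_i/[Na]_o = 4/151 mmol/l,
+91.1 mV at 18 degC); a dynamic-Nernst mode is available but off by default
because [Na]_i excursions in these protocols are small.

Kinetics are Boltzmann steady states with bell-shaped voltage-dependent time
constants, m^3 h for Na, n^4 for the delayed rectifier (Kv) and n for a fast
subthreshold-activating Kv1-type conductance; all parameters live in the
canonical YAML (`axoprop/configs/default_model.yaml`) and can be swapped
without code changes. The absolute Na kinetics and all K-channel parameters
are reconstructions, defined directly at the 18 degC nominal temperature
(no Q10 applied; a global `tau_scale` knob exists for exploration). They were
calibrated once, during model construction, to place the model in the regime
the biology describes: single-site initiation at the distal AIS boundary, a
slow Na_V1.2-dependent backward invasion of the soma, and forward conduction
that is insensitive to Na_V1.2 gating. The load-bearing choices are a fast
Kv1 (V1/2 = -50 mV, k = 8 mV, tau <= 0.55 ms) that is dense enough in the
soma (120 pS/um^2) and node region (800, with 300 under the myelin and 1500
of nodal Kv) to hold those compartments back during the subthreshold
approach, and Na activation that is slow near threshold (tau_m peaking at
~0.46 ms at -45 mV). The per-compartment leak reversal is solved so that the
configured resting potential (-75 mV) is an exact equilibrium.

## Numerics

Voltage is advanced by a Crank-Nicolson-style semi-implicit step: ionic
conductances are frozen at the current gating state, the resulting linear
tree system is solved exactly by Hines elimination (parent-before-child
ordering, O(n) per step), and gating variables advance by exact exponential
(Rush-Larsen) integration at the pre-step voltage. [Na+]_i follows channel
influx (-I_Na/(F x volume)) plus explicit axial diffusion with symmetric
pairwise fluxes (exact amount conservation; sealed ends). The default step is
1 us; halving it changes the somatic AP peak by <0.1 mV and fitted velocities
by <1% (tested). Voltage clamp is ideal: penalty rows impose the command on
all soma compartments and the clamp current is the residual of the
unconstrained membrane equation. Divergence (non-finite or |V| > 500 mV) and
negative concentrations abort with a diagnostic. The integrator is a single
numba kernel; runs are bitwise deterministic for a given configuration.

## The propagation experiment

A 2-ms somatic current pulse is applied at 1.31x the bisected 2-ms threshold
of the *unshifted* model; the same absolute amplitude is reused for every
Na_V1.2 shift, mirroring the within-cell experimental design. The factor
places the stimulus in the middle of the amplitude window in which the model
propagates reproducibly; the AP then arises ~2 ms after the pulse. Voltage is
recorded every 2 um along the axon at 5-us intervals. Event times are the
first prominent peak (>= 50% of the window maximum, parabolic sub-sample
interpolation) of dV/dt after the stimulus window; delays are taken relative
to the somatic dV/dt maximum. Velocities come from a two-segment linear fit
of delay vs distance over sites within 95 um of the soma edge (AIS plus the
first myelinated segment), with the breakpoint — the initiation zone — found
by exhaustive search over splits between adjacent sites (ties break toward
the proximal candidate); backward velocity is the inverse slope of the
proximal branch, forward of the distal branch.

Site timing uses a low (2 mV) excursion floor rather than requiring a full
local spike, i.e. it times the passing wavefront, much as loose-patch action
currents do. This matters because of a known model limitation: in the default
parameterization the node chain beyond the first myelinated segment does not
re-fire (its strong K complement suppresses re-excitation), so forward
conduction there is partially passive. The reported forward velocity is the
apparent wavefront velocity over the distal AIS and first myelinated segment.

A second limitation of the same calibration: the model fires single APs to
brief suprathreshold pulses but does not fire repetitive trains during long
(400-ms) current steps — the fast subthreshold Kv1 outpaces the slow Na
activation under slow depolarization. Simulator firing tests therefore use
the brief-pulse regime, and F-I gain analysis is validated on synthetic spike
trains.

## Analysis procedures

* **I_NaP G-V**: the clamp current of the 2-s, -70 -> 0 mV somatic ramp is
  decomposed into linear leak + Boltzmann Na current by a joint least-squares
  fit seeded from a plain leak fit over the -70..-65 mV window (a plain
  window fit alone over-subtracts, because the activation foot is already
  ~5% open at -65 mV, and biases V1/2 left by >1 mV). The Na component is
  converted to conductance via (V - E_Na), normalized to its plateau and
  fitted with a Boltzmann; at zero noise the decomposition is exact.
* **F-I gain**: per step, mean of reciprocal interspike intervals within the
  pulse (spike times are interpolated threshold crossings); gain is the
  least-squares slope over steps with >= 2 spikes. Zero-spike steps only
  enter rheobase bookkeeping.
* **Passive fit**: R_in from the steady-state deflection (last 10% of the
  pulse) over the amplitude; tau_m from a monoexponential fit to the
  off-transient.
* **EPSP metrics**: baseline-corrected peak, trapezoidal integral and
  post-peak monoexponential decay; the set-level integral-vs-peak slope is a
  through-origin least-squares fit (e x tau for a shared alpha-function tau).

## Synthetic data

Each analysis has a generator with embedded ground truth
(`TraceSet.meta['truth']`), seeded and deterministic: multi-site biphasic
action currents (derivative-of-Gaussian template; per-sweep time jitter;
programmable side velocities, preset 0.32/0.10 m/s), ramp I_NaP traces
(Boltzmann conductance + linear leak, optional paired V1/2 shift), RC step
responses, regular or jittered spike trains following f = gain x I, and
alpha-function EPSP families with optionally peak-dependent decay. The
generators emulate the statistical structure the estimators assume (additive
Gaussian noise, event-time jitter); they do not emulate electrode artefacts,
filtering, line noise or fluorescence photophysics, so estimator-recovery
tests demonstrate correctness of the procedures, not robustness to every
experimental nuisance.

## What the defaults are (quick reference)

| parameter | default | unit |
|---|---|---|
| dt | 0.001 | ms |
| V_rest | -75 | mV |
| E_K / E_Na | -85 / +91.1 | mV |
| D_Na | 0.6 | um^2/ms |
| [Na]_i / [Na]_o | 4 / 151 | mmol/l |
| AIS length / partition | 45, equal thirds | um |
| node pairs / bleb | 150 / 5x5 | -, um |
| pulse / amplitude | 2 ms / 1.31x threshold | |
| profile window | <= 95 | um |
| leak window (ramp) | -70..-65 | mV |

All of these are overridable through the YAML config or keyword arguments;
the shipped `default_model.yaml` is the reference parameterization and is
covered by a test asserting it matches the in-code defaults.
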