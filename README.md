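# axoprop

Compartmental model of a layer-5 (L5) cortical pyramidal neuron with graded
Na_V1.2 / Na_V1.6 channel distributions along the axon initial segment (AIS),
plus the analysis procedures used in axonal electrophysiology: action-potential
(AP) propagation-velocity estimation from delay-distance profiles, persistent
sodium current (I_NaP) Boltzmann activation fits, frequency-current (F-I) gain,
passive membrane properties (R_in, tau_m) and EPSP shape metrics.

## The scientific problem

In cortical pyramidal cells APs initiate in the AIS. Na_V1.6 channels in the
distal AIS and nodes of Ranvier drive forward propagation into the axon, while
Na_V1.2 channels in the soma, dendrites and proximal AIS drive backpropagation
into the somatodendritic compartment. SUMOylation of Na_V1.2 at Lys38 shifts
its activation V½ leftward (SENP1-mediated deSUMOylation shifts it rightward);
Na_V1.6 carries no SUMO site. Because the two isoforms segregate spatially,
this single-channel modulation is predicted to regulate *backward* propagation
velocity selectively.

`axoprop` implements this as a multicompartment Hodgkin-Huxley cable model
(~1,370 isopotential 1-um compartments; semi-implicit Crank-Nicolson voltage
update with a Hines tree solve at 1-us steps; Rush-Larsen gating; intracellular
Na+ diffusion with D = 0.6 um^2/ms) and represents SUMOylation purely as a
voltage shift `dV` of the Na_V1.2 activation midpoint:

```
m_inf(V) = 1 / (1 + exp(-(V - (V_half + dV)) / k)),   open = m^3 h
```

A `K38Q` (Lys38Gln) genotype flag makes the shift a structural no-op.

## Worked example

```python
from axoprop import run_backprop_experiment

report = run_backprop_experiment()   # default config: shifts 0 and -6 mV, WT
for row in report["rows"]:
    print(row["shift_mV"], round(row["backward_m_per_s"], 3),
          round(row["forward_m_per_s"], 3), round(row.get("fold_backward", 1), 2))
```

prints (about a minute on one CPU, including the threshold search):

```
0.0  0.121  0.458  1.0
-6.0 0.254  0.483  2.09
```

Reading: in the unshifted model the AP initiates in the distal AIS and invades
the soma at an apparent backward velocity of 0.121 m/s while the wavefront
travels forward at 0.458 m/s (back/forward ratio 0.26). Shifting Na_V1.2
activation by -6 mV — the modelled effect of SUMO1 — roughly doubles the
backward velocity (fold 2.09) while the forward velocity changes by only ~5%.
With `run_backprop_experiment({"experiment": {"genotype": "K38Q"}})` the fold
is exactly 1.0: the shift is a no-op without the SUMO site.

The same package generates synthetic loose-patch, voltage-ramp, current-step
and EPSP data with known ground truth (`axoprop.synth`) and recovers the
programmed parameters with the estimators in `axoprop.analysis`; see
`tests/test_analysis.py` for tolerances.

A CLI wraps the library: `axoprop simulate|analyze|generate|experiment --help`.

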