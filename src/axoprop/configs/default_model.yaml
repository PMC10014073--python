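# Canonical model and protocol configuration for the layer-5 pyramidal cell.
# All values are explicit in the units noted; this file is the bit-stable
# reference parameterization the package defaults to.
model:
  morphology:
    soma:      {length: 35.0, diameter: 23.0}        # um
    apical:    {length: 350.0, diameter: 3.5}
    basal:     {length: 200.0, diameter: 1.2, count: 2}
    ais:       {length: 45.0, diameter: 1.2, fractions: [0.3333333333333333, 0.3333333333333333, 0.3333333333333333]}
    myelin0:   {length: 50.0, diameter: 1.2}
    node:      {length: 1.0, diameter: 1.2}
    internode: {length: 2.0, diameter: 1.2}
    n_node_pairs: 150
    terminal_bleb: {length: 5.0, diameter: 5.0}      # passive cut-end bleb
  passive:
    rm: 25000.0          # Ohm cm^2
    cm: 1.0              # uF/cm^2
    cm_internode: 0.5    # uF/cm^2
    ri: 150.0            # Ohm cm
  max_segment_um: 1.0
  densities:             # pS/um^2; [a, b] = linear ramp along the region
    nav12:
      soma: 200.0
      apical: 200.0
      basal: 40.0
      ais_proximal: [200.0, 800.0]
      ais_middle: 800.0
    nav16:
      ais_distal: [800.0, 0.0]
      node: 1200.0
    kv:
      soma: 60.0
      apical: 10.0
      basal: 10.0
      ais_proximal: 150.0
      ais_middle: 150.0
      ais_distal: 150.0
      node: 1500.0
    kv1:
      soma: 120.0
      apical: 30.0
      basal: 30.0
      ais_proximal: 60.0
      ais_middle: 60.0
      ais_distal: 30.0
      node: 800.0
      internode: 300.0
  gating:                # V1/2 and k in mV, tau parameters in ms/mV
    nav12:
      act:       {vhalf: -30.0, k: 7.0}
      inact:     {vhalf: -62.0, k: -7.0}
      tau_act:   {base: 0.06, amp: 0.8, vmid: -45.0, width: 12.0}
      tau_inact: {base: 0.5, amp: 10.0, vmid: -55.0, width: 14.0}
      exponent: 3
      p_persist: 0.0
    nav16_shift: {act: -6.0, inact: -3.0}            # mV, relative to Nav1.2
    kv:
      act:     {vhalf: -20.0, k: 10.0}
      tau_act: {base: 0.5, amp: 4.0, vmid: -30.0, width: 20.0}
      exponent: 4
      reversal: -85.0
    kv1:
      act:     {vhalf: -50.0, k: 8.0}
      tau_act: {base: 0.15, amp: 0.8, vmid: -50.0, width: 20.0}
      exponent: 1
      reversal: -85.0
  ions:
    v_rest: -75.0        # mV
    ek: -85.0            # mV
    na_i: 4.0            # mmol/l
    na_o: 151.0          # mmol/l
    ena_mode: fixed      # fixed Nernst at rest (~ +91.1 mV) or 'dynamic'
    d_na: 0.6            # um^2/ms
    temperature_c: 18.0
protocol:
  propagation:
    pulse_ms: 2.0        # somatic pulse duration
    rel_amplitude: 1.31  # stimulus = rel_amplitude x 2-ms threshold
    amplitude_nA: null   # set to fix the stimulus explicitly
    t_total_ms: 25.0
    spacing_um: 2.0      # axonal recording pitch
    rec_interval_ms: 0.005
    max_distance_um: 95.0  # delay-profile window: AIS + first myelinated segment
  ramp:
    v_start: -70.0       # mV
    v_end: 0.0
    duration_ms: 2000.0
    dt_ms: 0.02
  steps:
    start_nA: -0.15
    increment_nA: 0.05
    n_steps: 14
    duration_ms: 400.0
experiment:
  shifts_mV: [0.0, -6.0]
  genotype: WT
  dt_ms: 0.001           # 1 us integration step
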