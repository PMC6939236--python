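# Full-scale cortical microcircuit model (~1 mm^2 of early sensory cortex):
# 8 populations in 4 layers, 77,169 neurons, ~0.3e9 recurrent synapses.
# Parameter values transcribed from Potjans & Diesmann (2014),
# "The cell-type specific cortical microcircuit", Cereb. Cortex 24:785-806.
# Units: ms, mV, pA, MOhm, kHz throughout.
schema_version: 1
name: cortical-microcircuit
dt: 0.1
duration: 10000.0
discard: 1000.0
seed: 12345

neuron_defaults: &lif
  tau_m: 10.0       # membrane time constant
  tau_syn: 0.5      # synaptic current decay
  R: 40.0           # membrane resistance (tau_m / Cm, Cm = 250 pF)
  V_rest: -65.0
  V_reset: -65.0
  V_theta: -50.0
  I_DC: 0.0         # filled in at build time for DC-input mode
  t_ref: 2.0

# init_V approximates relaxed (steady-state-like) membrane potentials;
# draws above threshold are clipped to V_theta at build time.
populations:
  - {name: L23E, size: 20683, kind: excitatory, neuron: *lif, init_V: {mean: -58.0, sd: 5.0}}
  - {name: L23I, size: 5834,  kind: inhibitory, neuron: *lif, init_V: {mean: -58.0, sd: 5.0}}
  - {name: L4E,  size: 21915, kind: excitatory, neuron: *lif, init_V: {mean: -58.0, sd: 5.0}}
  - {name: L4I,  size: 5479,  kind: inhibitory, neuron: *lif, init_V: {mean: -58.0, sd: 5.0}}
  - {name: L5E,  size: 4850,  kind: excitatory, neuron: *lif, init_V: {mean: -58.0, sd: 5.0}}
  - {name: L5I,  size: 1065,  kind: inhibitory, neuron: *lif, init_V: {mean: -58.0, sd: 5.0}}
  - {name: L6E,  size: 14395, kind: excitatory, neuron: *lif, init_V: {mean: -58.0, sd: 5.0}}
  - {name: L6I,  size: 2948,  kind: inhibitory, neuron: *lif, init_V: {mean: -58.0, sd: 5.0}}

# Weight magnitudes (sign applied by source kind): excitatory sources
# 87.8 +/- 8.78 pA (L4E -> L23E doubled: 175.6 +/- 8.78), inhibitory sources
# 351.2 +/- 35.32 pA. Delays: 1.5 +/- 0.75 ms (exc), 0.75 +/- 0.375 ms (inh).
projection_defaults:
  weight_exc: &we {mean: 87.8, sd: 8.78}
  weight_inh: &wi {mean: 351.2, sd: 35.32}
  delay_exc: &de {mean: 1.5, sd: 0.75}
  delay_inh: &di {mean: 0.75, sd: 0.375}

projections:
  # to L23E
  - {source: L23E, target: L23E, p_connect: 0.101,  weight: *we, delay: *de}
  - {source: L23I, target: L23E, p_connect: 0.169,  weight: *wi, delay: *di}
  - {source: L4E,  target: L23E, p_connect: 0.044,  weight: {mean: 175.6, sd: 8.78}, delay: *de}
  - {source: L4I,  target: L23E, p_connect: 0.082,  weight: *wi, delay: *di}
  - {source: L5E,  target: L23E, p_connect: 0.032,  weight: *we, delay: *de}
  - {source: L6E,  target: L23E, p_connect: 0.008,  weight: *we, delay: *de}
  # to L23I
  - {source: L23E, target: L23I, p_connect: 0.135,  weight: *we, delay: *de}
  - {source: L23I, target: L23I, p_connect: 0.137,  weight: *wi, delay: *di}
  - {source: L4E,  target: L23I, p_connect: 0.032,  weight: *we, delay: *de}
  - {source: L4I,  target: L23I, p_connect: 0.052,  weight: *wi, delay: *di}
  - {source: L5E,  target: L23I, p_connect: 0.075,  weight: *we, delay: *de}
  - {source: L6E,  target: L23I, p_connect: 0.004,  weight: *we, delay: *de}
  # to L4E
  - {source: L23E, target: L4E,  p_connect: 0.008,  weight: *we, delay: *de}
  - {source: L23I, target: L4E,  p_connect: 0.006,  weight: *wi, delay: *di}
  - {source: L4E,  target: L4E,  p_connect: 0.050,  weight: *we, delay: *de}
  - {source: L4I,  target: L4E,  p_connect: 0.135,  weight: *wi, delay: *di}
  - {source: L5E,  target: L4E,  p_connect: 0.007,  weight: *we, delay: *de}
  - {source: L5I,  target: L4E,  p_connect: 0.0003, weight: *wi, delay: *di}
  - {source: L6E,  target: L4E,  p_connect: 0.045,  weight: *we, delay: *de}
  # to L4I
  - {source: L23E, target: L4I,  p_connect: 0.069,  weight: *we, delay: *de}
  - {source: L23I, target: L4I,  p_connect: 0.003,  weight: *wi, delay: *di}
  - {source: L4E,  target: L4I,  p_connect: 0.079,  weight: *we, delay: *de}
  - {source: L4I,  target: L4I,  p_connect: 0.160,  weight: *wi, delay: *di}
  - {source: L5E,  target: L4I,  p_connect: 0.003,  weight: *we, delay: *de}
  - {source: L6E,  target: L4I,  p_connect: 0.106,  weight: *we, delay: *de}
  # to L5E
  - {source: L23E, target: L5E,  p_connect: 0.100,  weight: *we, delay: *de}
  - {source: L23I, target: L5E,  p_connect: 0.062,  weight: *wi, delay: *di}
  - {source: L4E,  target: L5E,  p_connect: 0.051,  weight: *we, delay: *de}
  - {source: L4I,  target: L5E,  p_connect: 0.006,  weight: *wi, delay: *di}
  - {source: L5E,  target: L5E,  p_connect: 0.083,  weight: *we, delay: *de}
  - {source: L5I,  target: L5E,  p_connect: 0.373,  weight: *wi, delay: *di}
  - {source: L6E,  target: L5E,  p_connect: 0.020,  weight: *we, delay: *de}
  # to L5I
  - {source: L23E, target: L5I,  p_connect: 0.055,  weight: *we, delay: *de}
  - {source: L23I, target: L5I,  p_connect: 0.027,  weight: *wi, delay: *di}
  - {source: L4E,  target: L5I,  p_connect: 0.026,  weight: *we, delay: *de}
  - {source: L4I,  target: L5I,  p_connect: 0.002,  weight: *wi, delay: *di}
  - {source: L5E,  target: L5I,  p_connect: 0.060,  weight: *we, delay: *de}
  - {source: L5I,  target: L5I,  p_connect: 0.316,  weight: *wi, delay: *di}
  - {source: L6E,  target: L5I,  p_connect: 0.009,  weight: *we, delay: *de}
  # to L6E
  - {source: L23E, target: L6E,  p_connect: 0.016,  weight: *we, delay: *de}
  - {source: L23I, target: L6E,  p_connect: 0.007,  weight: *wi, delay: *di}
  - {source: L4E,  target: L6E,  p_connect: 0.021,  weight: *we, delay: *de}
  - {source: L4I,  target: L6E,  p_connect: 0.017,  weight: *wi, delay: *di}
  - {source: L5E,  target: L6E,  p_connect: 0.057,  weight: *we, delay: *de}
  - {source: L5I,  target: L6E,  p_connect: 0.020,  weight: *wi, delay: *di}
  - {source: L6E,  target: L6E,  p_connect: 0.040,  weight: *we, delay: *de}
  - {source: L6I,  target: L6E,  p_connect: 0.225,  weight: *wi, delay: *di}
  # to L6I
  - {source: L23E, target: L6I,  p_connect: 0.036,  weight: *we, delay: *de}
  - {source: L23I, target: L6I,  p_connect: 0.001,  weight: *wi, delay: *di}
  - {source: L4E,  target: L6I,  p_connect: 0.003,  weight: *we, delay: *de}
  - {source: L4I,  target: L6I,  p_connect: 0.001,  weight: *wi, delay: *di}
  - {source: L5E,  target: L6I,  p_connect: 0.028,  weight: *we, delay: *de}
  - {source: L5I,  target: L6I,  p_connect: 0.008,  weight: *wi, delay: *di}
  - {source: L6E,  target: L6I,  p_connect: 0.066,  weight: *we, delay: *de}
  - {source: L6I,  target: L6I,  p_connect: 0.144,  weight: *wi, delay: *di}

# Background drive: K_ext external inputs per neuron firing at 8 Hz, delivered
# either as Poisson spike trains (rate = K_ext * 8 Hz, in kHz) or as the
# equivalent mean direct current K_ext * 8 Hz * w * tau_syn.
background:
  mode: poisson
  weight: 87.8
  rate_per_neuron:
    L23E: 12.8    # K_ext = 1600
    L23I: 12.0    # K_ext = 1500
    L4E: 16.8     # K_ext = 2100
    L4I: 15.2     # K_ext = 1900
    L5E: 16.0     # K_ext = 2000
    L5I: 15.2     # K_ext = 1900
    L6E: 23.2     # K_ext = 2900
    L6I: 16.8     # K_ext = 2100
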