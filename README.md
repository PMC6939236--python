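# spinsim

A portable software simulator of the **heterogeneous core-ensemble
parallelization scheme** for hard-real-time simulation of spiking cortical
networks on many-core neuromorphic hardware, together with the spiketrain
statistics used to validate such simulations.

The benchmark model is the full-scale cortical microcircuit (~1 mm² of
early sensory cortex): 8 populations in 4 layers, 77,169 leaky
integrate-and-fire neurons with current-based exponential synapses and
roughly 0.3 × 10⁹ probabilistic recurrent connections, driven by DC or
Poisson background input. Running it in hard real time — every 0.1 ms model
step computed in 100 µs of wall clock — requires splitting the work that a
single CPU core cannot finish in time across a cooperating *ensemble* of
cores, and accepting that spikes which cannot be processed before the
deadline are dropped (*flushed*). `spinsim` reproduces that scheme in
software so its mapping arithmetic, routing, timing budget and accuracy
consequences can be studied without the hardware.

## The model and the scheme

Neuron dynamics (per step, exact exponential integration):

```
dV/dt     = (-(V - V_rest) + (I_syn + I_DC)·R) / τ_m      spike & reset at V > V_θ
dI_syn/dt = -I_syn / τ_syn + Σ_j w_j δ(t - t_j)
```

The parallelization scheme:

* populations are tiled into **64-neuron sub-populations**; each one is
  served by an ensemble of a neuron core, two excitatory synapse cores
  (S_L / S_U, fed by the lower / upper half of each source population),
  one inhibitory synapse core, and a Poisson core when background input is
  spike-based — 4 cores per ensemble in DC mode, 5 in Poisson mode;
* spikes travel as 32-bit **AER multicast keys**
  `[17-bit routing | 9-bit partition | 6-bit neuron]`, addressing
  populations of up to 512 × 64 = 32,768 neurons; a receiving core resolves
  a key with a binary search of its **master population table** (one entry
  per source population) and a partition-jump into the row-indexed synaptic
  matrix;
* each synaptic word adds its signed weight to a per-neuron **255-slot ring
  buffer** at slot `(t + delay) mod 256`, giving a 25.5 ms delay horizon at
  Δt = 0.1 ms; the slot for step t+1 is handed to the neuron core at the
  end of step t;
* a **virtual cost model** charges 2.68 µs for the input state read,
  1.05 µs per neuron update, and 3.55 µs per single-target spike; spike
  processing must finish 10 µs before the 100 µs period ends, and the
  unprocessed tail of the spike buffer is flushed — hard real time is kept,
  at the price of counted, reported spike loss;
* per-board clock drift and the beacon rate-correction / start-signal phase
  alignment protocol are modelled in `spinsim.clocksync`.

A deliberately plain flat dense simulator (`spinsim.reference`) of the same
sampled network acts as an independent oracle: with an unlimited budget the
ensemble engine must match it spike for spike.

## Worked example

```bash
spinsim map --config src/spinsim/data/microcircuit.yaml --mode dc --out cores.tsv
# 1210 partitions -> 1210 ensembles, 4840 cores on 303 chips (dc)

spinsim map --config src/spinsim/data/microcircuit.yaml --mode poisson --out cores.tsv
# 1210 partitions -> 1210 ensembles, 6050 cores on 404 chips (poisson)

spinsim run --toy two_pop_balanced --seed 7 --steps 2000 \
    --cost-model unlimited --out out/
# 7 spikes over 2000 steps; 34 synaptic events; 0 flushed

spinsim profile-report --profiles out/profiles.tsv
# received 14, processed 14, flushed 0 (max in one core-step: 0), zero-target 0, peak arrivals/step 2
```

The mapping lines reproduce the scheme's core arithmetic: 1210 = Σ
⌈N_pop/64⌉ sub-populations, × 4 cores (DC) = 4840 or × 5 (Poisson) = 6050.
In the toy run, every received spike is accounted for as processed +
flushed; `zero-target` counts spikes whose row on the receiving core holds
no synapses (an overhead the scheme's profiling highlights). Chip counts
are a greedy-packing lower bound — physical placements depend on the
placer and machine, and are out of scope.

Library use mirrors the CLI:

```python
from spinsim import canonical_microcircuit, generate_toy_net, build_network
from spinsim import Simulation, CostModel, map_network, run_flat

spec = generate_toy_net("two_pop_balanced", {"duration": 1000.0}, seed=7)
net = build_network(spec)
result = Simulation(net, map_network(spec), cost=CostModel()).run()
result.step_counts          # total / excitatory / inhibitory spikes per step
result.core_profiles        # per-core received / processed / flushed counters
```

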