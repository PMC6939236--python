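# Methods

This note documents the model semantics, numerical choices and calibrations
behind `spinsim`, and what the synthetic test conditions do and do not
demonstrate about real simulations.

## Neuron model and integration

Neurons are single-compartment leaky integrate-and-fire units with
current-based exponentially decaying synapses:

```
dV/dt     = (-(V - V_rest) + (I_syn + I_DC)·R) / τ_m
dI_syn/dt = -I_syn / τ_syn
```

Units are fixed package-wide: ms, mV, pA, MΩ, kHz (so R·I converts to mV
with a factor 10⁻³). Synaptic and background input act as **deltas on
I_syn at step boundaries**: the combined input for step t (assembled during
step t−1) is added to I_syn, then the coupled linear (I_syn, V) system is
advanced by one **exact exponential propagator** step:

```
I' = I·e^(−Δt/τ_syn)
V' = V∞ + (V − V∞)·e^(−Δt/τ_m) + c·I,   V∞ = V_rest + I_DC·R
c  = R·τ_syn/(τ_syn − τ_m) · (e^(−Δt/τ_syn) − e^(−Δt/τ_m))
```

with the α-function limit `c = R·(Δt/τ_m)·e^(−Δt/τ_m)` when
τ_syn = τ_m. Forward-Euler was rejected: at Δt = 0.1 ms it shifts spike
times enough to break event-for-event comparisons. The propagator is
verified against the matrix exponential of the system to ≤ 10⁻¹⁰ relative
error (the flat reference simulator *uses* the expm route, keeping the two
integration paths independent).

Threshold test is strict (`V > V_θ`) after the propagator step; a spiking
neuron is reset and held at `V_reset` for `t_ref` (rounded to steps).
`t_ref` defaults to 0 in the neuron type — the governing equations carry no
refractory term — but the shipped microcircuit configuration sets the
cited reference's 2 ms.

## Network instantiation

* **Connectivity**: independent Bernoulli trial per ordered (source,
  target) pair with the projection's `p_connect` (autapses allowed). The
  cited reference model also admits a fixed-total-count rule; the
  Bernoulli-pair rule is the package default and the only implemented one.
* **Weights**: normal magnitudes (pA); negative draws are clipped to 0
  (probability ~10⁻²³ at the microcircuit's parameters, so the clip exists
  for validity, not effect). The sign is applied at accumulation time by
  the source population's kind, enforcing Dale's law structurally.
* **Delays**: normal (ms), divided by Δt, rounded half-away-from-zero and
  clipped to **[1, 255] steps** — the floor forced by the one-slot-ahead
  buffer hand-off, the ceiling by the 255 usable ring-buffer slots. At the
  microcircuit's 1.5 ± 0.75 ms excitatory delays this quantization biases
  the mean upward by ≈ 0.009 ms (closed form in the tests).
* **Initial V**: per-population normal, clipped at V_θ so nothing starts
  above threshold. The full-scale config uses −58 ± 5 mV as a
  steady-state-like ("relaxed") initialization; the original benchmark's
  initial-condition distribution is not quantified anywhere, so this is a
  package choice.
* **Reproducibility**: every projection, population and per-ensemble
  background source draws from its own `numpy` stream keyed as
  `default_rng([seed, domain, index])`, so sampled networks and runs are
  bit-identical for a given seed regardless of construction or execution
  order.

The shipped `data/microcircuit.yaml` transcribes the full-scale benchmark
parameter table (population sizes, connection probabilities, LIF constants
τ_m = 10 ms, τ_syn = 0.5 ms, R = 40 MΩ, V_θ = −50 mV, V_rest = V_reset =
−65 mV, t_ref = 2 ms, background K_ext) from the published microcircuit
model. In DC mode the Poisson drive is replaced by its mean current
rate·w·τ_syn per neuron.

## Mapping, keys and tables

Populations tile into ≤64-neuron partitions; one ensemble per partition
(4 cores DC / 5 Poisson); greedy chip packing at ≤4 ensembles per chip
(DC, 256 neurons/chip) or ≤3 (Poisson, 192). On the full-scale config this
gives 1210 partitions → 4840 / 6050 cores. Chip totals are a lower bound:
real placements (radial placers, failed cores) are out of scope.

Keys are `[routing 17 | partition 9 | neuron 6]`. Routing ids are assigned
sequentially per (population, half): lower half = partitions with index
< ⌈P/2⌉. The two ids of one population are consecutive, so a master
population table entry matches a population with a contiguous id range —
one entry per source population, with the row found by the partition jump
`address = base + (partition·64 + neuron)·stride`, `stride` = the matrix's
longest row (row padding is not specified by the scheme; max-row-length
words is this package's choice). Excitatory synapse cores list only
excitatory sources (4 entries each on the full-scale config), inhibitory
cores only inhibitory ones.

With the ⌈P/2⌉ boundary, the S_L/S_U neuron split is balanced to the
boundary granularity: the halves can differ by one partition's share plus
the last partition's shortfall (worst case just under two partitions'
worth, e.g. 576 vs 489 for a 1065-neuron population in 17 partitions).

## The cost model and flushing

Virtual timing constants (µs, per 100 µs timer period): state read 2.68,
neuron update 1.05/neuron (so a 64-neuron core finishes by 69.88 µs),
per-spike cost `base + per_target·row_words`. Only the single-target total
(3.55 µs) is an empirically given constant; the split is calibrated here as
base = 3.35, per_target = 0.2, chosen so that the single-target constraint
holds and longer rows cost proportionally more. Spike emission offset
within the period is `2.68 + (i+1)·1.05` for local neuron i (earliest
3.73 µs); optional machine geometry adds transit at 0.5 µs per router hop
and 0.9 µs per board link. Offsets affect only budget accounting, never
dynamics.

The processing window closes 10 µs before the period ends. Spikes are
admitted FIFO by arrival offset; a spike is processed iff it can *complete*
before the window closes, and the first spike that cannot — plus the whole
remaining tail — is flushed and counted. (The completion-must-fit rule is
what a preempting deadline callback implies, and it reproduces the worked
capacity figure ⌊90/3.55⌋ = 25 single-target spikes per step.) Per core
and step, `received = processed + flushed` always; `zero_target` counts
processed spikes whose row held no synapses for this core, and
`kick_starts` counts arrivals that found the pipeline idle. Shrinking the
timer period can only increase flushed counts on a fixed stream
(monotonicity is property-tested).

Ring-buffer accumulators are float64 by default; an optional saturating
16-bit fixed-point mode (configurable pA/LSB scale) emulates hardware
buffers. The Poisson input buffer is modelled real-valued; its 16-bit
semantics are subsumed by the same option when needed.

## Background input

A Poisson core draws, per neuron per step, a count ~ Poisson(rate·Δt) and
accumulates count·weight into its buffer; the buffer is handed over at the
end of the step and cleared, so background generated during step t reaches
the neuron at t+1 — the same one-slot latency as a synapse core, and
provably identical (tested exactly) to sending the same counts as packets
through a weight-equal, delay-1 synapse.

## Clock drift and alignment

Drift is a constant relative rate error per board (crystal variability; no
temperature dependence). The beacon protocol measures the master's
inter-beacon cycle count against locally elapsed cycles and spreads the
difference over the interval's timer periods; sub-cycle corrections
accumulate and apply as whole cycles. The correction is exact for constant
drift — the residual is truncation only, below one 5 ns clock cycle per
period. Phase is not corrected by beacons; the start signal plus a
chip-specific delay `max_transit − transit(chip)` aligns it, with transit
= 500 ns/hop + 900 ns/board-link on a rectangular chip grid tiled into
8×6-chip boards (a simulation abstraction of the 48-chip board; the
physical board tiling is hexagonal) with optional torus wrap.

## Statistics

Rates, CV-ISI and binned pairwise Pearson correlations are computed after
discarding an initial transient (default 1000 ms). CV-ISI uses neurons
with ≥3 spikes. Correlation bins use the Freedman–Diaconis width
2·IQR·n^(−1/3) on the pooled spike times of the selected population
(the binning target is ambiguous in the scheme's description; pooled spike
times is this package's choice), floored at one Δt; pairs are a random
sample (default 10⁴) because full pair sets are quadratic in population
size; zero-variance trains are skipped. A histogram-overlap utility
supports run-vs-run distribution comparison without asserting a numeric
pass threshold.

## What the tests show — and what they don't

Unit and property tests run on toy networks (tens of neurons, dyadic
weights where exact floating-point equality is asserted) and on the
full-scale configuration's *structural* arithmetic only. Problem sizes
were chosen to exercise every code path at desk scale: oracle-equivalence
runs use 10⁴ steps (1 s of model time) on ~20-neuron networks, sampling
checks use 10⁶ draws. Passing them demonstrates that the ensemble
decomposition is exactly equivalent to a flat simulation when the budget
is unlimited, that the budget model flushes deterministically and
conservatively, and that the samplers and estimators recover their
configured parameters. It does **not** demonstrate full-scale dynamics:
the steady-state firing statistics of the 77k-neuron model (≈17.0
excitatory / 8.3 inhibitory spikes per step; ≈9.4 × 10⁹ synaptic events
per 10 s) require hours of CPU on the full sampled network and are
full-scale stochastic targets, reachable with `spinsim run` on the shipped
config but not part of the test suite. Downscaled configs
(`generate_scaled_config`) keep probabilities while shrinking populations,
so their in-degrees — and hence dynamics — are *not* equivalent to the
full model; they are testing surrogates only.

Other known limits: no cycle-accurate CPU/DMA emulation (fixed cost
constants stand in for contention distributions), no routing-table
compression or torus shortest-path routing, no energy model, and chip
totals are packing lower bounds.
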