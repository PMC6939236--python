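"""Clock-driven ensemble execution with a virtual hard-real-time cost model.

Each ensemble advances in lock-step with the others.  Within a 0.1 ms step
(a 100 µs timer period at real time) the neuron core reads the combined
synaptic/background input accumulated for this step during the previous one,
advances its ≤64 LIF neurons with an exact exponential propagator, and emits
AER spike keys.  Keys fan out to the synapse cores selected by the routing
plan; each synapse core resolves its master population table, jumps to the
target synaptic-matrix row and accumulates weights into per-neuron 255-slot
ring buffers at slot (t + delay) mod 256.  A virtual cost model charges
1.05 µs per neuron update after a 2.68 µs state read, and a per-spike row
cost calibrated so a single-target spike takes 3.55 µs; spike processing
must finish 10 µs before the period ends, and any spikes that cannot be
processed in time are *flushed* (discarded and counted), which is how the
scheme guarantees hard real time at the price of lost synaptic events.

Dynamics are unaffected by the cost model except through flushing: with an
unlimited budget the ensemble engine is event-for-event equivalent to a flat
dense simulation of the same sampled network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import NetworkSpec, NeuronParams, SampledNetwork, build_network
from .partition import (
    NEURONS_PER_CORE,
    Ensemble,
    MasterPopulationTable,
    NetworkMap,
    RoutingPlan,
    SubPopulation,
    SynapticMatrix,
    build_population_table,
    map_network,
    synaptic_matrices_for_core,
)
from .stats import SpikeRecording

__all__ = [
    "CostModel",
    "RingBuffer",
    "NeuronCoreState",
    "SynapseCoreState",
    "PoissonCoreState",
    "lif_propagator",
    "neuron_update",
    "step_budget",
    "poisson_update",
    "Simulation",
    "SimulationResult",
    "run",
]

#: Slots addressable by the 8-bit ring-buffer index; 255 are usable for
#: future input because the current step's slot is being drained.
RING_SLOTS = 256

# pA * MOhm = microvolt; membrane potentials are kept in mV.
_PA_MOHM_TO_MV = 1e-3


# ---------------------------------------------------------------------------
# Cost model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostModel:
    """Virtual timing constants (µs) of one timer period.

    ``spike_base`` + ``per_target`` × row words is the cost of processing one
    spike; defaults are calibrated so a single-target spike costs 3.55 µs.
    The spike-processing window closes ``deadline_margin`` before the period
    ends, when the buffer-transfer callback preempts and flushes any
    unprocessed spikes.
    """

    timer_period: float = 100.0
    neuron_update: float = 1.05
    state_read: float = 2.68
    spike_base: float = 3.35
    per_target: float = 0.2
    deadline_margin: float = 10.0
    hop_time: float = 0.5       # router transit per hop
    board_link_time: float = 0.9

    def __post_init__(self):
        for name in ("timer_period", "neuron_update", "state_read", "spike_base",
                     "per_target", "deadline_margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.deadline_margin < self.timer_period:
            raise ValueError("deadline_margin must be smaller than timer_period")

    @property
    def single_target_cost(self) -> float:
        return self.spike_base + self.per_target

    @property
    def window_end(self) -> float:
        return self.timer_period - self.deadline_margin

    def emission_offset(self, neuron_index: int) -> float:
        """When a spiking neuron's key leaves the neuron core (µs into the period)."""
        return self.state_read + (neuron_index + 1) * self.neuron_update

    def spike_cost(self, row_words: int) -> float:
        return self.spike_base + self.per_target * row_words

    @classmethod
    def unlimited(cls) -> "CostModel":
        """No deadline: every spike is processed (used for oracle comparisons)."""
        return cls(timer_period=math.inf, deadline_margin=10.0)


def step_budget(cost: CostModel, arrivals: list[tuple[float, int]]) -> tuple[int, int]:
    """FIFO spike admission under the hard deadline.

    ``arrivals`` is a list of (arrival offset µs, row word count) sorted by
    offset.  A spike is processed if it can *complete* before the window
    closes; the first spike that cannot, and the whole remaining tail, are
    flushed.  Returns (number processed, number of pipeline kick-starts).
    """
    vt = 0.0
    processed = 0
    kick_starts = 0
    end = cost.window_end
    for offset, words in arrivals:
        start = max(vt, offset)
        if offset >= vt:
            kick_starts += 1
        c = cost.spike_cost(words)
        if start + c <= end:
            processed += 1
            vt = start + c
        else:
            break
    return processed, kick_starts


# ---------------------------------------------------------------------------
# Exact integration of the LIF / exponential-synapse pair
# ---------------------------------------------------------------------------

def lif_propagator(params: NeuronParams, dt: float) -> tuple[float, float, float, float]:
    """One-step exact propagator coefficients for the linear (I_syn, V) system.

    Returns (decay_syn, decay_mem, coupling, V_inf) such that

        I' = decay_syn * I
        V' = V_inf + (V - V_inf) * decay_mem + coupling * I

    which is the closed-form solution over one step of

        dI/dt = -I / tau_syn
        dV/dt = (-(V - V_rest) + (I + I_DC) * R) / tau_m

    with inputs treated as deltas applied to I at step boundaries.
    """
    ts, tm = params.tau_syn, params.tau_m
    r = params.R * _PA_MOHM_TO_MV
    decay_syn = math.exp(-dt / ts)
    decay_mem = math.exp(-dt / tm)
    if abs(ts - tm) > 1e-12 * max(ts, tm):
        coupling = r * ts / (ts - tm) * (decay_syn - decay_mem)
    else:
        coupling = r * (dt / tm) * decay_mem
    v_inf = params.V_rest + params.I_DC * r
    return decay_syn, decay_mem, coupling, v_inf


@dataclass
class NeuronCoreState:
    """State of one neuron core: ≤64 LIF neurons of a single sub-population."""

    params: NeuronParams
    partition: SubPopulation
    V: np.ndarray
    dt: float
    I_syn: np.ndarray = None
    refractory: np.ndarray = None

    def __post_init__(self):
        n = self.partition.size
        if len(self.V) != n:
            raise ValueError("initial V length does not match partition size")
        if self.I_syn is None:
            self.I_syn = np.zeros(n)
        if self.refractory is None:
            self.refractory = np.zeros(n, dtype=np.int64)
        self._coeffs = lif_propagator(self.params, self.dt)
        self._ref_steps = int(round(self.params.t_ref / self.dt))

    def update(self, input_slot: np.ndarray) -> np.ndarray:
        """Advance one step with the given input (pA deltas); return spiker indices."""
        if len(input_slot) != self.partition.size:
            raise ValueError("input slot length does not match neuron count")
        if not (np.all(np.isfinite(self.V)) and np.all(np.isfinite(input_slot))):
            raise FloatingPointError("non-finite neuron state or input")
        a_s, a_m, c, v_inf = self._coeffs
        self.I_syn = self.I_syn + input_slot
        v_next = v_inf + (self.V - v_inf) * a_m + c * self.I_syn
        self.I_syn = self.I_syn * a_s
        in_ref = self.refractory > 0
        v_next[in_ref] = self.params.V_reset
        self.refractory[in_ref] -= 1
        spikes = np.flatnonzero((v_next > self.params.V_theta) & ~in_ref)
        v_next[spikes] = self.params.V_reset
        if self._ref_steps > 0:
            self.refractory[spikes] = self._ref_steps
        self.V = v_next
        return spikes


def neuron_update(core: NeuronCoreState, input_slot: np.ndarray, dt: float | None = None) -> np.ndarray:
    """Functional form of :meth:`NeuronCoreState.update` (dt fixed at creation)."""
    if dt is not None and not math.isclose(dt, core.dt):
        raise ValueError("dt differs from the core's configured step")
    return core.update(input_slot)


# ---------------------------------------------------------------------------
# Ring buffers
# ---------------------------------------------------------------------------

class RingBuffer:
    """Per-neuron circular accumulator of future synaptic input (pA).

    256 addressable slots, of which 255 hold future input (delays 1..255);
    a slot is zeroed when its step's content is drained.  An optional
    saturating 16-bit fixed-point mode mimics hardware accumulators: values
    are kept as integer multiples of ``fixed_scale`` and clamp at the int16
    limits.
    """

    def __init__(self, n_neurons: int, fixed_scale: float | None = None):
        self.n_neurons = n_neurons
        self.fixed_scale = fixed_scale
        if fixed_scale is None:
            self._slots = np.zeros((RING_SLOTS, n_neurons))
        else:
            self._slots = np.zeros((RING_SLOTS, n_neurons), dtype=np.int64)

    def add(self, slot: int, neuron: np.ndarray | int, value: np.ndarray | float) -> None:
        idx = slot % RING_SLOTS
        if self.fixed_scale is None:
            np.add.at(self._slots[idx], neuron, value)
        else:
            ticks = np.round(np.asarray(value) / self.fixed_scale).astype(np.int64)
            np.add.at(self._slots[idx], neuron, ticks)
            np.clip(self._slots[idx], -32768, 32767, out=self._slots[idx])

    def peek(self, slot: int) -> np.ndarray:
        row = self._slots[slot % RING_SLOTS]
        return row * self.fixed_scale if self.fixed_scale is not None else row.copy()

    def drain(self, slot: int) -> np.ndarray:
        """Return and zero the slot for the given step."""
        out = self.peek(slot)
        self._slots[slot % RING_SLOTS] = 0
        return out


# ---------------------------------------------------------------------------
# Synapse cores
# ---------------------------------------------------------------------------

@dataclass
class StepCounters:
    received: int = 0
    processed: int = 0
    flushed: int = 0
    kick_starts: int = 0
    zero_target: int = 0


@dataclass
class SynapseCoreState:
    """One synapse core: population table, matrix views and ring buffers."""

    role: str  # synapse_SL | synapse_SU | synapse_I
    ensemble_index: int
    table: MasterPopulationTable
    matrices: dict[str, SynapticMatrix]
    ring: RingBuffer
    sign: int
    counters: StepCounters = field(default_factory=StepCounters)
    arrivals: list = field(default_factory=list)

    def receive(self, offset: float, key: int, seq: int) -> None:
        self.arrivals.append((offset, seq, key))

    def row_for(self, key: int) -> tuple[str, int, np.ndarray, np.ndarray, np.ndarray]:
        pop, row, _addr = self.table.lookup(key)
        mat = self.matrices.get(pop)
        if mat is None or row >= mat.n_rows:
            empty = np.empty(0)
            return pop, row, empty.astype(np.int64), empty.astype(np.int64), empty
        return pop, row, mat.rows_tgt[row], mat.rows_delay[row], mat.rows_weight[row]

    def process_spike(self, key: int, step: int) -> str:
        """Process one admitted spike: accumulate its row into the ring buffers."""
        _pop, _row, tgt, delay, weight = self.row_for(key)
        if len(tgt) == 0:
            self.counters.zero_target += 1
            self.counters.processed += 1
            return "zero_target"
        for t, d, w in zip(tgt, delay, weight):
            self.ring.add(step + int(d), int(t), self.sign * float(w))
        self.counters.processed += 1
        return "processed"

    def finish_step(self, cost: CostModel, step: int) -> tuple[StepCounters, int]:
        """Admit arrivals FIFO under the budget, process or flush, reset state.

        Returns the step's counters and the number of synaptic events
        delivered (row words of the processed spikes).
        """
        self.arrivals.sort(key=lambda a: (a[0], a[1]))
        self.counters.received = len(self.arrivals)
        sized = [(off, len(self.row_for(key)[2])) for off, _seq, key in self.arrivals]
        n_proc, kicks = step_budget(cost, sized)
        self.counters.kick_starts = kicks
        delivered = 0
        for off, _seq, key in self.arrivals[:n_proc]:
            self.process_spike(key, step)
            delivered += len(self.row_for(key)[2])
        self.counters.flushed = len(self.arrivals) - n_proc
        done, self.counters, self.arrivals = self.counters, StepCounters(), []
        return done, delivered


# ---------------------------------------------------------------------------
# Poisson cores
# ---------------------------------------------------------------------------

@dataclass
class PoissonCoreState:
    """Dedicated background-input core: one Poisson source per neuron.

    Each step every source draws how many spikes it emits this step
    (Poisson with mean rate·Δt) and accumulates count × weight into its
    input-buffer entry; the buffer is handed over at the end of the step and
    cleared, so background generated during step t reaches the neuron core's
    input at step t + 1 (the same one-slot-ahead latency as a synapse core).
    """

    rates: np.ndarray    # kHz per neuron
    weight: float        # pA per background spike
    dt: float
    rng: np.random.Generator
    buffer: np.ndarray = None

    def __post_init__(self):
        if self.buffer is None:
            self.buffer = np.zeros(len(self.rates))

    def update(self) -> np.ndarray:
        counts = self.rng.poisson(self.rates * self.dt)
        self.buffer = self.buffer + counts * self.weight
        out, self.buffer = self.buffer, np.zeros(len(self.rates))
        return out


def poisson_update(core: PoissonCoreState, dt: float | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Functional form of :meth:`PoissonCoreState.update`."""
    if rng is not None:
        core.rng = rng
    if dt is not None and not math.isclose(dt, core.dt):
        raise ValueError("dt differs from the core's configured step")
    return core.update()


def poisson_core_rng(seed: int, ensemble_index: int) -> np.random.Generator:
    """Keyed background stream for one ensemble (order-independent)."""
    return np.random.default_rng([seed, 2, ensemble_index])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class EnsembleRuntime:
    ensemble: Ensemble
    neuron_core: NeuronCoreState
    synapse_cores: dict[str, SynapseCoreState]
    poisson_core: PoissonCoreState | None
    pending_input: np.ndarray  # combined input for the next step

    def combined_next_slot(self, next_step: int) -> np.ndarray:
        total = np.zeros(self.ensemble.partition.size)
        for role in ("synapse_SL", "synapse_SU", "synapse_I"):
            total = total + self.synapse_cores[role].ring.drain(next_step)
        if self.poisson_core is not None:
            total = total + self.poisson_core.update()
        return total


@dataclass
class SimulationResult:
    recording: SpikeRecording
    core_profiles: pd.DataFrame
    step_counts: pd.DataFrame
    n_synapses: int

    @property
    def total_flushed(self) -> int:
        return int(self.core_profiles["flushed"].sum()) if len(self.core_profiles) else 0

    @property
    def synaptic_events(self) -> int:
        """Network synaptic events delivered (one spike × one target row word)."""
        return int(self._events)

    _events: int = 0


class Simulation:
    """Ensemble-of-cores execution of a sampled network under a cost model."""

    def __init__(
        self,
        network: SampledNetwork,
        netmap: NetworkMap | None = None,
        cost: CostModel | None = None,
        seed: int | None = None,
        machine=None,
        fixed_scale: float | None = None,
        record_profiles: bool = True,
    ):
        self.network = network
        self.spec = network.spec
        self.netmap = netmap if netmap is not None else map_network(self.spec)
        self.cost = cost if cost is not None else CostModel()
        self.seed = seed if seed is not None else self.spec.seed
        self.machine = machine
        self.record_profiles = record_profiles
        self.step = 0
        routing = self.netmap.routing
        mode = self.netmap.mode
        bg = self.spec.background
        self.runtimes: list[EnsembleRuntime] = []
        strides_cache: dict[str, dict[str, int]] = {}
        for ens in self.netmap.ensembles:
            part = ens.partition
            pop = self.spec.population(part.population)
            params = pop.neuron
            if mode == "dc":
                params = replace(params, I_DC=params.I_DC + bg.dc_current(part.population, params.tau_syn))
            ncore = NeuronCoreState(
                params=params,
                partition=part,
                V=self.network.init_V[part.population][part.lo:part.hi].copy(),
                dt=self.spec.dt,
            )
            sc = {}
            for role in ("synapse_SL", "synapse_SU", "synapse_I"):
                matrices = synaptic_matrices_for_core(ens, role, self.network, routing)
                strides = {p: m.row_stride for p, m in matrices.items()}
                table = build_population_table(role, part.population, self.spec, routing, strides)
                sc[role] = SynapseCoreState(
                    role=role,
                    ensemble_index=ens.index,
                    table=table,
                    matrices=matrices,
                    ring=RingBuffer(part.size, fixed_scale=fixed_scale),
                    sign=-1 if role == "synapse_I" else +1,
                )
            pcore = None
            if mode == "poisson" and part.population in bg.rate_per_neuron:
                pcore = PoissonCoreState(
                    rates=np.full(part.size, bg.rate_per_neuron[part.population]),
                    weight=bg.weight,
                    dt=self.spec.dt,
                    rng=poisson_core_rng(self.seed, ens.index),
                )
            self.runtimes.append(
                EnsembleRuntime(
                    ensemble=ens,
                    neuron_core=ncore,
                    synapse_cores=sc,
                    poisson_core=pcore,
                    pending_input=np.zeros(part.size),
                )
            )
        # destination lookup: (source pop, upper?) -> [(runtime, role)]
        self._dest: dict[tuple[str, int], list[tuple[EnsembleRuntime, str]]] = {}
        targets_of: dict[str, set[str]] = {}
        for proj in self.spec.projections:
            targets_of.setdefault(proj.source, set()).add(proj.target)
        for pop in self.spec.populations:
            tgts = targets_of.get(pop.name, set())
            for upper in (0, 1):
                if pop.kind == "inhibitory":
                    role = "synapse_I"
                else:
                    role = "synapse_SU" if upper else "synapse_SL"
                self._dest[(pop.name, upper)] = [
                    (rt, role) for rt in self.runtimes if rt.ensemble.partition.population in tgts
                ]
        self._routing = routing
        self._events_log: list[tuple[int, int]] = []
        self._profile_rows: list[tuple] = []
        self._step_rows: list[tuple] = []
        self._kind = {p.name: p.kind for p in self.spec.populations}
        self._synaptic_events = 0

    # -- single step --------------------------------------------------------
    def advance(self) -> None:
        """Execute one simulation step across all ensembles."""
        t = self.step
        spikes_by_kind = {"excitatory": 0, "inhibitory": 0}
        seq = 0
        for rt in self.runtimes:
            part = rt.ensemble.partition
            local = rt.neuron_core.update(rt.pending_input)
            kind = self._kind[part.population]
            spikes_by_kind[kind] += len(local)
            src_chip = rt.ensemble.chip
            boundary = self._routing.half_boundary(part.population)
            upper = int(part.partition_index >= boundary)
            dests = self._dest[(part.population, upper)]
            for li in local:
                gid = self.network.pop_offset[part.population] + part.lo + int(li)
                self._events_log.append((gid, t))
                key = self._routing.key_for(part.population, part.lo + int(li))
                offset = self.cost.emission_offset(int(li))
                for dest_rt, role in dests:
                    transit = self._transit_us(src_chip, dest_rt.ensemble.chip)
                    dest_rt.synapse_cores[role].receive(offset + transit, key, seq)
                    seq += 1
        for rt in self.runtimes:
            for role, score in rt.synapse_cores.items():
                counters, delivered = score.finish_step(self.cost, t)
                self._synaptic_events += delivered
                if self.record_profiles:
                    self._profile_rows.append(
                        (t, rt.ensemble.index, role, counters.received,
                         counters.processed, counters.flushed,
                         counters.kick_starts, counters.zero_target)
                    )
                if counters.received != counters.processed + counters.flushed:
                    raise AssertionError("spike conservation violated")
        for rt in self.runtimes:
            rt.pending_input = rt.combined_next_slot(t + 1)
        self._step_rows.append(
            (t, spikes_by_kind["excitatory"] + spikes_by_kind["inhibitory"],
             spikes_by_kind["excitatory"], spikes_by_kind["inhibitory"])
        )
        self.step += 1

    def _transit_us(self, a: tuple[int, int], b: tuple[int, int]) -> float:
        if self.machine is None or a is None or b is None:
            return 0.0
        return self.machine.transit_ns(a, b) / 1000.0

    # -- full run ------------------------------------------------------------
    def run(self, n_steps: int | None = None, progress=None) -> SimulationResult:
        if n_steps is None:
            n_steps = self.spec.n_steps
        for i in range(n_steps):
            self.advance()
            if progress is not None and progress > 0 and (i + 1) % progress == 0:
                import sys
                print(f"step {i + 1}/{n_steps}", file=sys.stderr)
        events = np.array(self._events_log, dtype=np.int64).reshape(-1, 2)
        rec = SpikeRecording.from_events(events, self.spec, n_steps=self.step)
        profiles = pd.DataFrame(
            self._profile_rows,
            columns=["step", "ensemble", "role", "received", "processed",
                     "flushed", "kick_starts", "zero_target"],
        )
        counts = pd.DataFrame(self._step_rows, columns=["step", "total", "excitatory", "inhibitory"])
        result = SimulationResult(
            recording=rec,
            core_profiles=profiles,
            step_counts=counts,
            n_synapses=self.network.n_synapses,
        )
        result._events = self._synaptic_events
        return result


def run(
    spec: NetworkSpec,
    cost: CostModel | None = None,
    seed: int | None = None,
    mode: str | None = None,
    n_steps: int | None = None,
    machine=None,
    record_profiles: bool = True,
) -> SimulationResult:
    """Build, map and execute a network spec; deterministic given the seed."""
    network = build_network(spec, seed=seed)
    netmap = map_network(spec, mode=mode)
    sim = Simulation(network, netmap, cost=cost, seed=seed, machine=machine,
                     record_profiles=record_profiles)
    return sim.run(n_steps=n_steps)
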