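"""Mapping of a network onto ensembles of virtual cores.

Populations are tiled into 64-neuron sub-populations; each sub-population is
served by an *ensemble* of cooperating cores sharing one chip: a neuron core,
two excitatory synapse cores (S_L for spikes from the lower half of each
source population's partitions, S_U for the upper half), one inhibitory
synapse core, and — when background input is Poisson — a dedicated Poisson
core.  Spikes travel as 32-bit address-event (AER) multicast keys::

    [ routing id : 17 bits | partition index : 9 bits | neuron id : 6 bits ]

so a single key addresses populations of up to 512 × 64 = 32,768 neurons.
Routing ids are assigned sequentially per (population, half) so a receiving
core can resolve any member key with one *master population table* entry per
source population: the partition and neuron fields index the target row of
the population-level synaptic matrix directly (a "partition jump"), keeping
the table at one binary-searchable entry per source population instead of
one per 64-neuron partition.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import NetworkSpec, PopulationSpec, SampledNetwork

__all__ = [
    "NEURON_BITS",
    "PARTITION_BITS",
    "ROUTING_BITS",
    "MAX_POPULATION_PER_KEY",
    "NEURONS_PER_CORE",
    "APP_CORES_PER_CHIP",
    "SubPopulation",
    "Ensemble",
    "CoreAssignment",
    "CoreMap",
    "RoutingPlan",
    "MasterPopulationTable",
    "PopulationTableEntry",
    "SynapticMatrix",
    "KeyError_",
    "make_key",
    "parse_key",
    "partition_population",
    "partition_network",
    "build_ensembles",
    "pack_chips",
    "build_population_table",
    "route_targets",
    "NetworkMap",
    "map_network",
]

NEURON_BITS = 6
PARTITION_BITS = 9
ROUTING_BITS = 17
MAX_POPULATION_PER_KEY = (1 << PARTITION_BITS) * (1 << NEURON_BITS)  # 32,768

NEURONS_PER_CORE = 64
#: 18 physical cores per chip minus monitor and system cores.
APP_CORES_PER_CHIP = 16

DC_ROLES = ("neuron", "synapse_SL", "synapse_SU", "synapse_I")
POISSON_ROLES = DC_ROLES + ("poisson",)


class KeyError_(ValueError):
    """Raised on malformed or out-of-range packet key fields."""


# ---------------------------------------------------------------------------
# Packet key codec
# ---------------------------------------------------------------------------

def make_key(routing_id: int, partition_index: int, neuron_id: int) -> int:
    """Pack key fields into a 32-bit AER word (neuron id least significant)."""
    if not 0 <= neuron_id < (1 << NEURON_BITS):
        raise KeyError_(f"neuron_id {neuron_id} outside 0..{(1 << NEURON_BITS) - 1}")
    if not 0 <= partition_index < (1 << PARTITION_BITS):
        raise KeyError_(f"partition_index {partition_index} outside 0..{(1 << PARTITION_BITS) - 1}")
    if not 0 <= routing_id < (1 << ROUTING_BITS):
        raise KeyError_(f"routing_id {routing_id} outside 0..{(1 << ROUTING_BITS) - 1}")
    return (routing_id << (PARTITION_BITS + NEURON_BITS)) | (partition_index << NEURON_BITS) | neuron_id


def parse_key(key: int) -> tuple[int, int, int]:
    """Inverse of :func:`make_key`: (routing_id, partition_index, neuron_id)."""
    if not 0 <= key < (1 << 32):
        raise KeyError_(f"key {key} is not a 32-bit word")
    neuron = key & ((1 << NEURON_BITS) - 1)
    partition = (key >> NEURON_BITS) & ((1 << PARTITION_BITS) - 1)
    routing = key >> (PARTITION_BITS + NEURON_BITS)
    return routing, partition, neuron


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubPopulation:
    """A contiguous ≤64-neuron slice of a population; [lo, hi) half-open."""

    population: str
    partition_index: int
    lo: int
    hi: int

    @property
    def size(self) -> int:
        return self.hi - self.lo


def partition_population(pop: PopulationSpec, max_per_core: int = NEURONS_PER_CORE) -> list[SubPopulation]:
    """Tile a population into ceil(size / max_per_core) contiguous partitions."""
    if pop.size < 1:
        raise ValueError(f"population {pop.name!r} has size {pop.size}")
    parts = []
    for i in range(math.ceil(pop.size / max_per_core)):
        lo = i * max_per_core
        parts.append(SubPopulation(pop.name, i, lo, min(lo + max_per_core, pop.size)))
    return parts


def partition_network(spec: NetworkSpec, max_per_core: int = NEURONS_PER_CORE) -> list[SubPopulation]:
    out: list[SubPopulation] = []
    for pop in spec.populations:
        out.extend(partition_population(pop, max_per_core))
    return out


# ---------------------------------------------------------------------------
# Ensembles and chip packing
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """The group of cores serving one sub-population (4 cores DC, 5 Poisson)."""

    index: int
    partition: SubPopulation
    mode: str  # "dc" | "poisson"
    chip: tuple[int, int] | None = None
    cores: dict[str, int] = field(default_factory=dict)  # role -> core id on chip

    @property
    def roles(self) -> tuple[str, ...]:
        return POISSON_ROLES if self.mode == "poisson" else DC_ROLES

    @property
    def n_cores(self) -> int:
        return len(self.roles)


def build_ensembles(partitions: list[SubPopulation], mode: str) -> list[Ensemble]:
    """One ensemble per partition, in partition order."""
    if not partitions:
        raise ValueError("no partitions to build ensembles from")
    if mode not in ("dc", "poisson"):
        raise ValueError(f"mode must be dc|poisson, got {mode!r}")
    return [Ensemble(index=i, partition=p, mode=mode) for i, p in enumerate(partitions)]


@dataclass(frozen=True)
class CoreAssignment:
    chip: tuple[int, int]
    core_id: int
    role: str
    ensemble_index: int
    population: str
    partition_index: int


@dataclass
class CoreMap:
    """Placement of ensembles onto chips (greedy fill, partition order)."""

    ensembles: list[Ensemble]
    assignments: list[CoreAssignment]
    mode: str
    grid_width: int

    @property
    def n_cores(self) -> int:
        return len(self.assignments)

    @property
    def chips(self) -> list[tuple[int, int]]:
        return sorted({a.chip for a in self.assignments})

    @property
    def n_chips(self) -> int:
        return len({a.chip for a in self.assignments})

    def neurons_per_chip(self, sizes: dict[str, int] | None = None) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for ens in self.ensembles:
            counts[ens.chip] = counts.get(ens.chip, 0) + ens.partition.size
        return counts

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chip_x\tchip_y\tcore_id\trole\tpopulation\tpartition\n")
            for a in self.assignments:
                fh.write(
                    f"{a.chip[0]}\t{a.chip[1]}\t{a.core_id}\t{a.role}\t"
                    f"{a.population}\t{a.partition_index}\n"
                )


def pack_chips(ensembles: list[Ensemble], mode: str, grid_width: int | None = None) -> CoreMap:
    """Greedy chip packing: ≤4 ensembles/chip (DC, 256 neurons), ≤3 (Poisson, 192).

    Cores 1 and 2 of every chip are reserved (monitor + system), leaving 16
    application cores; one DC ensemble takes 4 of them, one Poisson ensemble 5.
    """
    per_chip = APP_CORES_PER_CHIP // (5 if mode == "poisson" else 4)  # 3 or 4
    n_chips = math.ceil(len(ensembles) / per_chip)
    if grid_width is None:
        grid_width = max(1, math.ceil(math.sqrt(n_chips)))
    assignments: list[CoreAssignment] = []
    for i, ens in enumerate(ensembles):
        chip_idx = i // per_chip
        chip = (chip_idx % grid_width, chip_idx // grid_width)
        slot = i % per_chip
        ens.chip = chip
        ens.cores = {}
        for j, role in enumerate(ens.roles):
            core_id = 3 + slot * ens.n_cores + j  # app cores numbered from 3
            ens.cores[role] = core_id
            assignments.append(
                CoreAssignment(
                    chip=chip,
                    core_id=core_id,
                    role=role,
                    ensemble_index=ens.index,
                    population=ens.partition.population,
                    partition_index=ens.partition.partition_index,
                )
            )
    return CoreMap(ensembles=ensembles, assignments=assignments, mode=mode, grid_width=grid_width)


# ---------------------------------------------------------------------------
# Routing plan
# ---------------------------------------------------------------------------

class RoutingPlan:
    """Sequential routing-id assignment per (population, partition half).

    The lower half of a population's partitions (partition_index <
    ceil(P / 2)) gets routing id 2·pop_index, the upper half 2·pop_index + 1,
    so the two ids of one population are consecutive and a master population
    table entry can match a population with a contiguous id range.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.pop_index = {p.name: i for i, p in enumerate(spec.populations)}
        self.n_partitions = {
            p.name: math.ceil(p.size / NEURONS_PER_CORE) for p in spec.populations
        }
        for name, n in self.n_partitions.items():
            if n > (1 << PARTITION_BITS):
                raise KeyError_(
                    f"population {name!r} needs {n} partitions; keys address at most "
                    f"{1 << PARTITION_BITS}"
                )

    def half_boundary(self, pop: str) -> int:
        """First partition index of the upper half."""
        return math.ceil(self.n_partitions[pop] / 2)

    def routing_id(self, pop: str, partition_index: int) -> int:
        upper = partition_index >= self.half_boundary(pop)
        return 2 * self.pop_index[pop] + int(upper)

    def routing_ids(self, pop: str) -> tuple[int, int]:
        base = 2 * self.pop_index[pop]
        return base, base + 1

    def key_for(self, pop: str, neuron_index: int) -> int:
        """AER key for a neuron given by its index within its population."""
        partition = neuron_index // NEURONS_PER_CORE
        neuron = neuron_index % NEURONS_PER_CORE
        return make_key(self.routing_id(pop, partition), partition, neuron)

    def source_of(self, key: int) -> tuple[str, int, int]:
        """(population, neuron index within population, routing id) of a key."""
        rid, partition, neuron = parse_key(key)
        pop_idx, upper = divmod(rid, 2)
        pops = self.spec.populations
        if pop_idx >= len(pops):
            raise KeyError_(f"routing id {rid} does not match any population")
        pop = pops[pop_idx].name
        if partition >= self.n_partitions[pop]:
            raise KeyError_(f"partition {partition} out of range for population {pop!r}")
        expected_upper = int(partition >= self.half_boundary(pop))
        if upper != expected_upper:
            raise KeyError_(
                f"routing id {rid} encodes {'upper' if upper else 'lower'} half but "
                f"partition {partition} of {pop!r} lies in the other half"
            )
        idx = partition * NEURONS_PER_CORE + neuron
        if idx >= self.spec.population(pop).size:
            raise KeyError_(f"neuron {idx} out of range for population {pop!r}")
        return pop, idx, rid


# ---------------------------------------------------------------------------
# Synaptic matrices and master population tables
# ---------------------------------------------------------------------------

@dataclass
class SynapticMatrix:
    """Row-indexed synapse store for one (source population → core) pathway.

    Rows are indexed by the source neuron's index within its population
    (partition_index · 64 + neuron_id); each row holds the synaptic words
    (target neuron local to the destination partition, delay steps, weight
    magnitude).  ``row_stride`` is the padded row length in words used by the
    address arithmetic — the longest row of this matrix.
    """

    source_population: str
    n_rows: int
    rows_tgt: list[np.ndarray]
    rows_delay: list[np.ndarray]
    rows_weight: list[np.ndarray]

    @property
    def row_stride(self) -> int:
        return max((len(r) for r in self.rows_tgt), default=0)

    @property
    def n_synapses(self) -> int:
        return sum(len(r) for r in self.rows_tgt)

    @classmethod
    def from_connections(
        cls,
        source_population: str,
        n_rows: int,
        src: np.ndarray,
        tgt_local: np.ndarray,
        delay: np.ndarray,
        weight: np.ndarray,
    ) -> "SynapticMatrix":
        order = np.lexsort((tgt_local, src))
        src, tgt_local = src[order], tgt_local[order]
        delay, weight = delay[order], weight[order]
        rows_t: list[np.ndarray] = []
        rows_d: list[np.ndarray] = []
        rows_w: list[np.ndarray] = []
        bounds = np.searchsorted(src, np.arange(n_rows + 1))
        for r in range(n_rows):
            sl = slice(bounds[r], bounds[r + 1])
            rows_t.append(tgt_local[sl].astype(np.int64))
            rows_d.append(delay[sl].astype(np.int64))
            rows_w.append(weight[sl].astype(np.float64))
        return cls(source_population, n_rows, rows_t, rows_d, rows_w)


@dataclass(frozen=True)
class PopulationTableEntry:
    rid_lo: int
    rid_hi: int
    population: str
    base_address: int
    row_stride: int
    n_rows: int


class MasterPopulationTable:
    """Sorted, binary-searchable key-prefix → synaptic-matrix address map.

    One entry per source population visible to the core.  ``lookup`` resolves
    a packet key to (population, row index, row address) using the partition
    jump: address = base + (partition·64 + neuron)·stride.
    """

    def __init__(self, entries: list[PopulationTableEntry]):
        self.entries = sorted(entries, key=lambda e: e.rid_lo)
        self._lows = [e.rid_lo for e in self.entries]
        for a, b in zip(self.entries, self.entries[1:]):
            if b.rid_lo <= a.rid_hi:
                raise ValueError("population table entries overlap")

    def __len__(self) -> int:
        return len(self.entries)

    def find(self, key: int) -> PopulationTableEntry | None:
        rid, _, _ = parse_key(key)
        i = bisect_right(self._lows, rid) - 1
        if i >= 0 and self.entries[i].rid_lo <= rid <= self.entries[i].rid_hi:
            return self.entries[i]
        return None

    def lookup(self, key: int) -> tuple[str, int, int]:
        entry = self.find(key)
        if entry is None:
            rid, _, _ = parse_key(key)
            raise KeyError_(f"no population table entry for routing id {rid}")
        _, partition, neuron = parse_key(key)
        row = partition * NEURONS_PER_CORE + neuron
        if row >= entry.n_rows:
            raise KeyError_(
                f"row {row} out of range for population {entry.population!r} "
                f"({entry.n_rows} rows)"
            )
        return entry.population, row, entry.base_address + row * entry.row_stride


def _core_sources(role: str, target_pop: str, spec: NetworkSpec) -> list[str]:
    """Source populations whose spikes a synapse core of ``role`` receives."""
    want_kind = "inhibitory" if role == "synapse_I" else "excitatory"
    seen: list[str] = []
    for proj in spec.projections:
        if proj.target != target_pop:
            continue
        if spec.population(proj.source).kind != want_kind:
            continue
        if proj.source not in seen:
            seen.append(proj.source)
    return seen


def build_population_table(
    role: str,
    target_pop: str,
    spec: NetworkSpec,
    routing: RoutingPlan | None = None,
    strides: dict[str, int] | None = None,
) -> MasterPopulationTable:
    """Master population table for one synapse core.

    Excitatory cores (S_L / S_U) list excitatory source populations only, and
    match only the routing id of the half they serve; the inhibitory core
    lists inhibitory sources and matches both halves.  ``strides`` gives the
    padded row length per source population (defaults to 1 word for purely
    structural use).
    """
    if routing is None:
        routing = RoutingPlan(spec)
    entries = []
    base = 0
    for pop in _core_sources(role, target_pop, spec):
        lo, hi = routing.routing_ids(pop)
        if role == "synapse_SL":
            hi = lo
        elif role == "synapse_SU":
            lo = hi
        stride = (strides or {}).get(pop, 1)
        n_rows = routing.n_partitions[pop] * NEURONS_PER_CORE
        entries.append(PopulationTableEntry(lo, hi, pop, base, stride, n_rows))
        base += n_rows * stride
    return MasterPopulationTable(entries)


def route_targets(
    key: int,
    core_map: CoreMap,
    spec: NetworkSpec,
    routing: RoutingPlan,
) -> list[CoreAssignment]:
    """Destination synapse cores of a spike key (multicast fan-out).

    Inhibitory spikes go to the inhibitory synapse core of every ensemble
    whose population receives a projection from the source; excitatory spikes
    from the lower (upper) half of the source population's partitions go to
    the S_L (S_U) cores only.  A source with no efferent projections yields
    an empty set.
    """
    pop, _, rid = routing.source_of(key)
    kind = spec.population(pop).kind
    if kind == "inhibitory":
        role = "synapse_I"
    else:
        role = "synapse_SL" if rid % 2 == 0 else "synapse_SU"
    targets = {proj.target for proj in spec.projections if proj.source == pop}
    out = []
    for ens in core_map.ensembles:
        if ens.partition.population in targets:
            out.append(
                CoreAssignment(
                    chip=ens.chip,
                    core_id=ens.cores[role],
                    role=role,
                    ensemble_index=ens.index,
                    population=ens.partition.population,
                    partition_index=ens.partition.partition_index,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Whole-network mapping
# ---------------------------------------------------------------------------

@dataclass
class NetworkMap:
    """Partitions, ensembles, placement and routing for one network."""

    spec: NetworkSpec
    mode: str
    partitions: list[SubPopulation]
    ensembles: list[Ensemble]
    core_map: CoreMap
    routing: RoutingPlan

    @property
    def n_cores(self) -> int:
        return self.core_map.n_cores

    def ensembles_of(self, pop: str) -> list[Ensemble]:
        return [e for e in self.ensembles if e.partition.population == pop]


def map_network(spec: NetworkSpec, mode: str | None = None, grid_width: int | None = None) -> NetworkMap:
    """Partition, group into ensembles and place a network spec."""
    if mode is None:
        mode = spec.background.mode
    partitions = partition_network(spec)
    ensembles = build_ensembles(partitions, mode)
    core_map = pack_chips(ensembles, mode, grid_width=grid_width)
    return NetworkMap(
        spec=spec,
        mode=mode,
        partitions=partitions,
        ensembles=ensembles,
        core_map=core_map,
        routing=RoutingPlan(spec),
    )


def synaptic_matrices_for_core(
    ens: Ensemble,
    role: str,
    network: SampledNetwork,
    routing: RoutingPlan,
) -> dict[str, SynapticMatrix]:
    """Build the per-source-population synaptic matrices held by one core.

    The core sees the synapses of afferent projections whose source kind
    matches its role, restricted to targets inside the ensemble's partition
    and — for S_L / S_U — to source neurons in the matching half of the
    source population's partitions.
    """
    spec = network.spec
    tgt_pop = ens.partition.population
    lo, hi = ens.partition.lo, ens.partition.hi
    want_kind = "inhibitory" if role == "synapse_I" else "excitatory"
    matrices: dict[str, SynapticMatrix] = {}
    for sp in network.projections:
        if sp.spec.target != tgt_pop or sp.source_kind != want_kind:
            continue
        pop = sp.spec.source
        mask = (sp.tgt >= lo) & (sp.tgt < hi)
        if role in ("synapse_SL", "synapse_SU"):
            boundary = routing.half_boundary(pop) * NEURONS_PER_CORE
            half_mask = sp.src < boundary if role == "synapse_SL" else sp.src >= boundary
            mask &= half_mask
        n_rows = routing.n_partitions[pop] * NEURONS_PER_CORE
        mat = SynapticMatrix.from_connections(
            pop,
            n_rows,
            sp.src[mask],
            (sp.tgt[mask] - lo),
            sp.delay_steps[mask],
            sp.weight[mask],
        )
        if pop in matrices:
            # multiple declared projections between the same pair merge rows
            prev = matrices[pop]
            for r in range(n_rows):
                prev.rows_tgt[r] = np.concatenate([prev.rows_tgt[r], mat.rows_tgt[r]])
                prev.rows_delay[r] = np.concatenate([prev.rows_delay[r], mat.rows_delay[r]])
                prev.rows_weight[r] = np.concatenate([prev.rows_weight[r], mat.rows_weight[r]])
        else:
            matrices[pop] = mat
    return matrices
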