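"""Partitioning, ensembles, chip packing, AER keys, tables and routing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinsim.config import Normal, ProjectionSpec
from spinsim.partition import (
    KeyError_,
    MasterPopulationTable,
    NEURONS_PER_CORE,
    PopulationTableEntry,
    RoutingPlan,
    build_ensembles,
    build_population_table,
    make_key,
    map_network,
    pack_chips,
    parse_key,
    partition_network,
    partition_population,
    route_targets,
)


class TestPartitioning:
    @pytest.mark.parametrize("size, expected", [(64, [64]), (130, [64, 64, 2]), (1, [1])])
    def test_tiling(self, size, expected, canonical_spec):
        pop = canonical_spec.populations[0].__class__(
            name="x", size=size, kind="excitatory",
            neuron=canonical_spec.populations[0].neuron,
        )
        parts = partition_population(pop)
        assert [p.size for p in parts] == expected
        assert parts[0].lo == 0 and parts[-1].hi == size
        for a, b in zip(parts, parts[1:]):
            assert a.hi == b.lo

    def test_canonical_partition_count(self, canonical_spec):
        assert len(partition_network(canonical_spec)) == 1210


class TestEnsemblesAndChips:
    def test_core_counts(self, canonical_spec):
        parts = partition_network(canonical_spec)
        assert sum(e.n_cores for e in build_ensembles(parts, "dc")) == 4840
        assert sum(e.n_cores for e in build_ensembles(parts, "poisson")) == 6050

    @pytest.mark.parametrize("mode, per_chip, density", [("dc", 4, 256), ("poisson", 3, 192)])
    def test_chip_density(self, canonical_spec, mode, per_chip, density):
        parts = partition_network(canonical_spec)[:per_chip]
        cm = pack_chips(build_ensembles(parts, mode), mode)
        assert cm.n_chips == 1
        assert cm.neurons_per_chip()[(0, 0)] == density

    def test_single_ensemble_single_chip(self, canonical_spec):
        parts = partition_network(canonical_spec)[:1]
        cm = pack_chips(build_ensembles(parts, "dc"), "dc")
        assert cm.n_chips == 1 and cm.n_cores == 4

    def test_ensemble_cores_share_chip(self, balanced_spec):
        nm = map_network(balanced_spec)
        for ens in nm.ensembles:
            chips = {a.chip for a in nm.core_map.assignments if a.ensemble_index == ens.index}
            assert chips == {ens.chip}

    def test_core_map_tsv(self, balanced_spec, tmp_path):
        nm = map_network(balanced_spec)
        out = tmp_path / "coremap.tsv"
        nm.core_map.to_tsv(out)
        lines = out.read_text().strip().split("\n")
        assert lines[0] == "chip_x\tchip_y\tcore_id\trole\tpopulation\tpartition"
        assert len(lines) == nm.n_cores + 1


class TestPacketKeys:
    def test_zero_key(self):
        assert make_key(0, 0, 0) == 0

    def test_low_fifteen_bits(self):
        assert make_key(0, 511, 63) == 32767

    def test_field_overflow_rejected(self):
        with pytest.raises(KeyError_):
            make_key(0, 512, 0)
        with pytest.raises(KeyError_):
            make_key(0, 0, 64)
        with pytest.raises(KeyError_):
            make_key(1 << 17, 0, 0)

    @settings(deadline=None, max_examples=200)
    @given(
        rid=st.integers(0, (1 << 17) - 1),
        part=st.integers(0, 511),
        neuron=st.integers(0, 63),
    )
    def test_pack_parse_identity(self, rid, part, neuron):
        assert parse_key(make_key(rid, part, neuron)) == (rid, part, neuron)


class TestPopulationTable:
    def test_partition_jump_address(self):
        """address = base + (partition*64 + neuron)*stride (spec'd arithmetic)."""
        table = MasterPopulationTable(
            [PopulationTableEntry(0, 1, "src", 1000, 10, 512 * 64)]
        )
        _pop, row, addr = table.lookup(make_key(0, 2, 3))
        assert row == 2 * 64 + 3
        assert addr == 2310

    def test_lookup_matches_per_partition_oracle(self, canonical_spec):
        """The compact table agrees with a naive one-entry-per-partition table."""
        routing = RoutingPlan(canonical_spec)
        strides = {p.name: 7 for p in canonical_spec.populations}
        table = build_population_table("synapse_SL", "L23E", canonical_spec, routing, strides)
        # oracle: address computed per (partition, neuron) directly
        for pop in ("L23E", "L4E", "L5E", "L6E"):
            entry = next(e for e in table.entries if e.population == pop)
            n_parts = routing.n_partitions[pop]
            for part in (0, 1, routing.half_boundary(pop) - 1):
                for neuron in (0, 5, 63):
                    key = make_key(routing.routing_id(pop, part), part, neuron)
                    naive = entry.base_address + (part * 64 + neuron) * 7
                    assert table.lookup(key) == (pop, part * 64 + neuron, naive)

    def test_excitatory_core_entry_count(self, canonical_spec):
        """Each excitatory synapse core resolves exactly 4 source populations."""
        for tgt in [p.name for p in canonical_spec.populations]:
            for role in ("synapse_SL", "synapse_SU"):
                table = build_population_table(role, tgt, canonical_spec)
                assert len(table) == 4
                kinds = {canonical_spec.population(e.population).kind for e in table.entries}
                assert kinds == {"excitatory"}

    def test_single_projection_toy_has_one_entry(self):
        from spinsim import generate_toy_net

        spec = generate_toy_net("single_chain", {"n": 2}, seed=0)
        table = build_population_table("synapse_SL", "link0", spec)
        assert len(table) == 1

    def test_unknown_routing_prefix_errors(self, canonical_spec):
        table = build_population_table("synapse_SL", "L23E", canonical_spec)
        with pytest.raises(KeyError_):
            table.lookup(make_key(99, 0, 0))


class TestRouting:
    def test_inhibitory_goes_to_inhibitory_cores_only(self, canonical_spec):
        nm = map_network(canonical_spec, mode="dc")
        key = nm.routing.key_for("L23I", 0)
        dests = route_targets(key, nm.core_map, canonical_spec, nm.routing)
        assert dests and all(d.role == "synapse_I" for d in dests)

    def test_excitatory_half_split(self, canonical_spec):
        nm = map_network(canonical_spec, mode="dc")
        lower_key = nm.routing.key_for("L23E", 0)
        upper_key = nm.routing.key_for("L23E", canonical_spec.population("L23E").size - 1)
        lower = route_targets(lower_key, nm.core_map, canonical_spec, nm.routing)
        upper = route_targets(upper_key, nm.core_map, canonical_spec, nm.routing)
        assert {d.role for d in lower} == {"synapse_SL"}
        assert {d.role for d in upper} == {"synapse_SU"}

    def test_no_projection_no_destinations(self):
        from spinsim import generate_toy_net

        spec = generate_toy_net("single_chain", {"n": 2}, seed=0)
        nm = map_network(spec)
        last = spec.populations[-1].name  # chain tail has no efferents
        key = nm.routing.key_for(last, 0)
        assert route_targets(key, nm.core_map, spec, nm.routing) == []

    def test_load_split_balance(self, canonical_spec):
        """Uniform spiking splits S_L vs S_U to within the boundary granularity.

        The boundary sits at ceil(P/2) whole partitions, so the halves can
        differ by one partition's share plus the last partition's shortfall
        (at most two partitions' worth when P is odd and the tail partial).
        """
        routing = RoutingPlan(canonical_spec)
        for pop in canonical_spec.populations:
            if pop.kind != "excitatory":
                continue
            n_parts = routing.n_partitions[pop.name]
            boundary = routing.half_boundary(pop.name) * NEURONS_PER_CORE
            lower = min(boundary, pop.size)
            upper = pop.size - lower
            last = pop.size - (n_parts - 1) * NEURONS_PER_CORE
            expected_gap = (n_parts % 2) * NEURONS_PER_CORE + (NEURONS_PER_CORE - last)
            assert abs(lower - upper) == expected_gap
            assert abs(lower - upper) <= 2 * NEURONS_PER_CORE
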