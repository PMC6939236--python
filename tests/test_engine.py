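"""Neuron dynamics, ring buffers, spike processing and the cost model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from spinsim.config import NeuronParams, build_network
from spinsim.engine import (
    CostModel,
    NeuronCoreState,
    PoissonCoreState,
    RingBuffer,
    Simulation,
    SynapseCoreState,
    lif_propagator,
    run,
    step_budget,
)
from spinsim.partition import (
    MasterPopulationTable,
    PopulationTableEntry,
    SubPopulation,
    SynapticMatrix,
    make_key,
    map_network,
)
from spinsim.reference import run_flat
from spinsim.toys import generate_toy_net

LIF = NeuronParams(tau_m=10.0, V_rest=-65.0, V_reset=-65.0, V_theta=-50.0,
                   R=40.0, tau_syn=0.5, I_DC=0.0, t_ref=2.0)


def _core(params=LIF, n=4, v0=-65.0, dt=0.1):
    part = SubPopulation("pop", 0, 0, n)
    return NeuronCoreState(params=params, partition=part, V=np.full(n, float(v0)), dt=dt)


class TestNeuronDynamics:
    def test_free_decay_scales_exponentially(self):
        core = _core(v0=-55.0)
        core.update(np.zeros(4))
        expected = -65.0 + (-55.0 + 65.0) * math.exp(-0.1 / 10.0)
        np.testing.assert_allclose(core.V, expected, rtol=1e-14)

    def test_dc_fixed_point(self):
        """Sub-threshold DC drives V to V_rest + I_DC * R."""
        params = NeuronParams(tau_m=10.0, V_rest=-65.0, V_reset=-65.0, V_theta=-50.0,
                              R=40.0, tau_syn=0.5, I_DC=250.0)  # +10 mV
        core = _core(params=params, n=1)
        for _ in range(3000):
            core.update(np.zeros(1))
        np.testing.assert_allclose(core.V, -55.0, atol=1e-9)

    def test_threshold_reset_and_refractory(self):
        core = _core(n=1, v0=-50.5)
        spikes = core.update(np.array([100000.0]))  # huge kick
        assert spikes.tolist() == [0]
        assert core.V[0] == LIF.V_reset
        # 2 ms refractory at 0.1 ms steps: 20 steps held at reset, no spikes
        for _ in range(20):
            assert len(core.update(np.array([100000.0]))) == 0
            assert core.V[0] == LIF.V_reset
        assert len(core.update(np.array([100000.0]))) == 1  # fires again

    def test_non_finite_state_rejected(self):
        core = _core(n=1)
        with pytest.raises(FloatingPointError):
            core.update(np.array([np.inf]))

    @pytest.mark.parametrize("params", [
        LIF,
        NeuronParams(tau_m=20.0, V_rest=-70.0, V_reset=-60.0, V_theta=-50.0,
                     R=80.0, tau_syn=2.0, I_DC=30.0),
        NeuronParams(tau_m=5.0, V_rest=-65.0, V_reset=-65.0, V_theta=-50.0,
                     R=40.0, tau_syn=5.0, I_DC=0.0),  # tau_syn == tau_m
    ], ids=["microcircuit", "generic", "equal-taus"])
    def test_propagator_matches_matrix_exponential(self, params):
        """One-step propagator equals expm of the linear system to <=1e-10."""
        dt = 0.1
        a_s, a_m, c, v_inf = lif_propagator(params, dt)
        rp = params.R * 1e-3
        A = np.array([[-1.0 / params.tau_syn, 0.0],
                      [rp / params.tau_m, -1.0 / params.tau_m]])
        P = expm(A * dt)
        b = np.array([0.0, (params.V_rest + params.I_DC * rp) / params.tau_m])
        aff = (P - np.eye(2)) @ np.linalg.solve(A, b)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i0, v0 = rng.uniform(0, 500), rng.uniform(-80, -50)
            ours = np.array([a_s * i0, v_inf + (v0 - v_inf) * a_m + c * i0])
            ref = P @ np.array([i0, v0]) + aff
            np.testing.assert_allclose(ours, ref, rtol=1e-10, atol=1e-12)


def _synapse_core(tgts, delays, weights, sign=1, fixed_scale=None):
    mat = SynapticMatrix.from_connections(
        "src", 64,
        np.zeros(len(tgts), dtype=np.int64),
        np.asarray(tgts), np.asarray(delays), np.asarray(weights, dtype=float),
    )
    table = MasterPopulationTable([PopulationTableEntry(0, 1, "src", 0, max(1, mat.row_stride), 64)])
    return SynapseCoreState(role="synapse_SL", ensemble_index=0, table=table,
                            matrices={"src": mat}, ring=RingBuffer(64, fixed_scale=fixed_scale),
                            sign=sign)


class TestSpikeProcessing:
    def test_row_word_lands_in_delay_slot(self):
        """A word (tgt=2, delay=3, w=87.8) processed at t=10 adds to slot 13."""
        core = _synapse_core([2], [3], [87.8])
        assert core.process_spike(make_key(0, 0, 0), step=10) == "processed"
        assert core.ring.peek(13)[2] == 87.8
        assert core.ring.peek(12)[2] == 0.0

    def test_same_slot_contributions_sum(self):
        core = _synapse_core([2, 2], [3, 3], [87.8, 12.2])
        core.process_spike(make_key(0, 0, 0), step=10)
        assert core.ring.peek(13)[2] == 87.8 + 12.2

    def test_inhibitory_sign(self):
        core = _synapse_core([1], [1], [351.2], sign=-1)
        core.process_spike(make_key(0, 0, 0), step=0)
        assert core.ring.peek(1)[1] == -351.2

    def test_weight_doubling_doubles_slots(self):
        w = np.array([87.8, 12.2, 3.1])
        a = _synapse_core([1, 1, 2], [1, 1, 2], w)
        b = _synapse_core([1, 1, 2], [1, 1, 2], 2 * w)
        for core in (a, b):
            core.process_spike(make_key(0, 0, 0), step=0)
        np.testing.assert_array_equal(2 * a.ring.peek(1), b.ring.peek(1))
        np.testing.assert_array_equal(2 * a.ring.peek(2), b.ring.peek(2))

    def test_zero_target_row_counted(self):
        core = _synapse_core([2], [3], [87.8])
        # source neuron 5 has an empty row on this core
        assert core.process_spike(make_key(0, 0, 5), step=0) == "zero_target"
        assert core.counters.zero_target == 1

    def test_slot_zeroed_after_drain(self):
        core = _synapse_core([2], [3], [87.8])
        core.process_spike(make_key(0, 0, 0), step=10)
        drained = core.ring.drain(13)
        assert drained[2] == 87.8
        assert core.ring.peek(13)[2] == 0.0

    def test_fixed_point_mode_saturates(self):
        core = _synapse_core([0], [1], [1.0e9], fixed_scale=2.0**-4)
        core.process_spike(make_key(0, 0, 0), step=0)
        assert core.ring.peek(1)[0] == 32767 * 2.0**-4


class TestStepBudget:
    def test_unlimited_window_flushes_nothing(self):
        arrivals = [(0.0, 1)] * 1000
        processed, _ = step_budget(CostModel.unlimited(), arrivals)
        assert processed == 1000

    def test_single_target_capacity_is_25(self):
        """90 us window / 3.55 us per single-target spike -> 25 processed."""
        cost = CostModel()
        assert cost.window_end == 90.0
        processed, kicks = step_budget(cost, [(0.0, 1)] * 40)
        assert processed == 25
        assert kicks == 1  # pipeline stays busy after the first arrival

    def test_deadline_margin_closes_window(self):
        assert CostModel(timer_period=100.0, deadline_margin=10.0).window_end == 90.0

    def test_arrival_offsets_delay_processing(self):
        cost = CostModel()
        # a spike arriving at 88 us cannot complete by 90 us
        processed, kicks = step_budget(cost, [(88.0, 1)])
        assert processed == 0
        processed, _ = step_budget(cost, [(86.0, 1)])
        assert processed == 1

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        offsets=st.lists(st.floats(0.0, 150.0), min_size=0, max_size=60),
        words=st.lists(st.integers(0, 30), min_size=60, max_size=60),
        t1=st.floats(11.0, 200.0),
        t2=st.floats(11.0, 200.0),
    )
    def test_flush_monotonicity(self, offsets, words, t1, t2):
        """A shorter timer period never flushes fewer spikes of a fixed stream."""
        lo, hi = sorted((t1, t2))
        arrivals = sorted(zip(offsets, words[:len(offsets)]))
        n = len(arrivals)
        p_lo, _ = step_budget(CostModel(timer_period=lo), arrivals)
        p_hi, _ = step_budget(CostModel(timer_period=hi), arrivals)
        assert n - p_lo >= n - p_hi


class TestPoissonCore:
    def test_zero_rate_zero_buffer(self):
        core = PoissonCoreState(rates=np.zeros(8), weight=87.8, dt=0.1,
                                rng=np.random.default_rng(0))
        assert np.all(core.update() == 0.0)

    def test_mean_counts_track_rate(self):
        """20 kHz at dt = 0.1 ms means 2 expected arrivals per step."""
        core = PoissonCoreState(rates=np.full(64, 20.0), weight=1.0, dt=0.1,
                                rng=np.random.default_rng(5))
        draws = np.array([core.update() for _ in range(2000)])
        assert abs(draws.mean() - 2.0) < 4 * math.sqrt(2.0 / draws.size)

    def test_buffer_cleared_between_steps(self):
        core = PoissonCoreState(rates=np.full(4, 50.0), weight=1.0, dt=0.1,
                                rng=np.random.default_rng(1))
        core.update()
        assert np.all(core.buffer == 0.0)


class TestEnsembleExecution:
    def test_delay_two_perturbs_at_t_plus_two(self):
        """A spike with a 2-step delay first moves the target membrane at t+2."""
        spec = generate_toy_net("single_chain",
                                {"n": 1, "delay_steps": 2, "weight": 64.0,
                                 "duration": 30.0}, seed=0)
        net = build_network(spec)
        sim = Simulation(net, map_network(spec), cost=CostModel.unlimited())
        v_hist = []
        spike_step = None
        for t in range(200):
            sim.advance()
            v_hist.append(float(sim.runtimes[1].neuron_core.V[0]))
            if spike_step is None and sim._step_rows[-1][1] > 0:
                spike_step = t
        assert spike_step is not None
        rest = -65.0
        assert all(v == rest for v in v_hist[: spike_step + 2])
        assert v_hist[spike_step + 2] != rest

    def test_no_input_pure_decay(self):
        spec = generate_toy_net("two_pop_balanced", {"rate": 1e-9, "duration": 10.0}, seed=2)
        net = build_network(spec)
        sim = Simulation(net, map_network(spec), cost=CostModel.unlimited())
        v0 = {i: rt.neuron_core.V.copy() for i, rt in enumerate(sim.runtimes)}
        n = 50
        for _ in range(n):
            sim.advance()
        decay = math.exp(-n * 0.1 / 10.0)
        for i, rt in enumerate(sim.runtimes):
            np.testing.assert_allclose(
                rt.neuron_core.V, -65.0 + (v0[i] + 65.0) * decay, rtol=1e-9, atol=1e-9)

    def test_exc_inh_counts_sum_to_total(self, balanced_spec, balanced_net, balanced_map):
        sim = Simulation(balanced_net, balanced_map, cost=CostModel.unlimited())
        res = sim.run(n_steps=500)
        assert (res.step_counts["excitatory"] + res.step_counts["inhibitory"]
                == res.step_counts["total"]).all()

    def test_zero_duration_run_is_empty(self):
        spec = generate_toy_net("two_pop_balanced", {"duration": 0.0}, seed=2)
        res = run(spec, cost=CostModel.unlimited())
        assert len(res.recording.events) == 0
        assert res.recording.n_steps == 0

    def test_run_determinism(self, balanced_spec):
        r1 = run(balanced_spec, cost=CostModel.unlimited(), seed=9, n_steps=400)
        r2 = run(balanced_spec, cost=CostModel.unlimited(), seed=9, n_steps=400)
        np.testing.assert_array_equal(r1.recording.events, r2.recording.events)
        assert r1.synaptic_events == r2.synaptic_events

    def test_matches_flat_oracle_short(self, balanced_spec, balanced_net, balanced_map):
        res = Simulation(balanced_net, balanced_map, cost=CostModel.unlimited()).run(n_steps=1000)
        ref = run_flat(balanced_net, n_steps=1000)
        assert sorted(map(tuple, res.recording.events)) == sorted(map(tuple, ref.events))
        assert len(res.recording.events) > 0


class TestCostModelArithmetic:
    def test_neuron_phase_completes_by_70us(self):
        cost = CostModel()
        assert cost.emission_offset(63) == pytest.approx(2.68 + 64 * 1.05)
        assert cost.emission_offset(63) <= 70.0

    def test_earliest_emission(self):
        assert CostModel().emission_offset(0) == pytest.approx(3.73)

    def test_single_target_cost_calibration(self):
        assert CostModel().single_target_cost == pytest.approx(3.55)

    def test_invalid_margin_rejected(self):
        with pytest.raises(ValueError):
            CostModel(timer_period=5.0, deadline_margin=10.0)
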