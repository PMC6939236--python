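"""Flat single-loop reference simulator.

A deliberately plain simulator of the same sampled network, used to validate
the ensemble engine: one dense loop over all neurons, a flat event list for
delayed synaptic input, and the one-step propagator obtained numerically as
the matrix exponential of the (I_syn, V) system — an implementation that
shares no code with the ensemble engine's analytic propagator or ring-buffer
machinery.  With an unlimited processing budget the two must agree
event-for-event.

Semantics mirrored here (the contract, not the code): inputs act as deltas
on I_syn at step boundaries; a spike emitted at step t with delay d first
perturbs its target at step t + d; background Poisson input generated during
step t (from the per-ensemble keyed stream over 64-neuron partitions in
population order) reaches its neuron at step t + 1; refractory neurons sit
at V_reset and cannot spike.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm

from .config import NetworkSpec, SampledNetwork
from .stats import SpikeRecording

__all__ = ["FlatSimulator", "run_flat"]

_SLOTS = 256


class FlatSimulator:
    """Dense event-list LIF simulator over the whole network at once."""

    def __init__(self, network: SampledNetwork, seed: int | None = None, mode: str | None = None):
        self.network = network
        spec = network.spec
        self.spec = spec
        self.seed = seed if seed is not None else spec.seed
        self.mode = mode if mode is not None else spec.background.mode
        n = spec.n_neurons
        self.n = n
        self.dt = spec.dt

        # per-neuron parameter vectors
        self.tau_m = np.empty(n)
        self.tau_syn = np.empty(n)
        self.v_rest = np.empty(n)
        self.v_reset = np.empty(n)
        self.v_theta = np.empty(n)
        self.r_mohm = np.empty(n)
        self.i_dc = np.empty(n)
        self.ref_steps = np.empty(n, dtype=np.int64)
        self.V = np.empty(n)
        bg = spec.background
        for pop in spec.populations:
            off = network.pop_offset[pop.name]
            sl = slice(off, off + pop.size)
            pr = pop.neuron
            self.tau_m[sl] = pr.tau_m
            self.tau_syn[sl] = pr.tau_syn
            self.v_rest[sl] = pr.V_rest
            self.v_reset[sl] = pr.V_reset
            self.v_theta[sl] = pr.V_theta
            self.r_mohm[sl] = pr.R
            i_dc = pr.I_DC
            if self.mode == "dc":
                i_dc = i_dc + bg.dc_current(pop.name, pr.tau_syn)
            self.i_dc[sl] = i_dc
            self.ref_steps[sl] = int(round(pr.t_ref / spec.dt))
            self.V[sl] = network.init_V[pop.name]
        self.I = np.zeros(n)
        self.ref = np.zeros(n, dtype=np.int64)

        # numeric one-step propagator per neuron via matrix exponential of
        #   d/dt [I, V] = [[-1/ts, 0], [R'/tm, -1/tm]] [I, V] + [0, (Vr + Idc R')/tm]
        self.a_ii = np.empty(n)
        self.a_vi = np.empty(n)
        self.a_vv = np.empty(n)
        self.b_v = np.empty(n)
        cache: dict[tuple, tuple] = {}
        for k in range(n):
            key = (self.tau_syn[k], self.tau_m[k], self.r_mohm[k], self.v_rest[k], self.i_dc[k])
            if key not in cache:
                ts, tm, r, vr, idc = key
                rp = r * 1e-3  # pA*MOhm -> mV
                A = np.array([[-1.0 / ts, 0.0], [rp / tm, -1.0 / tm]])
                P = expm(A * self.dt)
                # affine part: x' = P x + (P - I) A^{-1} b, b = [0, (vr + idc*rp)/tm]
                b = np.array([0.0, (vr + idc * rp) / tm])
                affine = (P - np.eye(2)) @ np.linalg.solve(A, b)
                cache[key] = (P[0, 0], P[1, 0], P[1, 1], affine[1])
            self.a_ii[k], self.a_vi[k], self.a_vv[k], self.b_v[k] = cache[key]

        # flat synapse lists grouped by presynaptic global id
        src_g, tgt_g, dly, wgt = [], [], [], []
        for sp in network.projections:
            so = network.pop_offset[sp.spec.source]
            to = network.pop_offset[sp.spec.target]
            sign = -1.0 if sp.source_kind == "inhibitory" else 1.0
            src_g.append(sp.src + so)
            tgt_g.append(sp.tgt + to)
            dly.append(sp.delay_steps)
            wgt.append(sign * sp.weight)
        if src_g:
            src_g = np.concatenate(src_g)
            tgt_g = np.concatenate(tgt_g)
            dly = np.concatenate(dly)
            wgt = np.concatenate(wgt)
        else:
            src_g = np.empty(0, dtype=np.int64)
            tgt_g = np.empty(0, dtype=np.int64)
            dly = np.empty(0, dtype=np.int64)
            wgt = np.empty(0)
        order = np.argsort(src_g, kind="stable")
        self.syn_tgt = tgt_g[order]
        self.syn_dly = dly[order]
        self.syn_wgt = wgt[order]
        self.syn_bounds = np.searchsorted(src_g[order], np.arange(n + 1))

        self.sched = np.zeros((_SLOTS, n))  # future input, slot = step % 256

        # background streams replicate the documented per-ensemble keying:
        # 64-neuron partitions in population order, stream [seed, 2, index]
        self.bg_chunks: list[tuple[slice, np.ndarray, np.random.Generator]] = []
        if self.mode == "poisson":
            idx = 0
            for pop in spec.populations:
                off = network.pop_offset[pop.name]
                n_parts = math.ceil(pop.size / 64)
                for p in range(n_parts):
                    lo = off + p * 64
                    hi = min(off + pop.size, lo + 64)
                    if pop.name in bg.rate_per_neuron:
                        rates = np.full(hi - lo, bg.rate_per_neuron[pop.name])
                        rng = np.random.default_rng([self.seed, 2, idx])
                        self.bg_chunks.append((slice(lo, hi), rates, rng))
                    idx += 1
            self.bg_weight = bg.weight
        self.pending = np.zeros(n)  # input for the upcoming step
        self.step = 0
        self.events: list[tuple[int, int]] = []

    def advance(self) -> np.ndarray:
        t = self.step
        self.I = self.I + self.pending
        v_next = self.a_vv * self.V + self.a_vi * self.I + self.b_v
        self.I = self.a_ii * self.I
        in_ref = self.ref > 0
        v_next[in_ref] = self.v_reset[in_ref]
        self.ref[in_ref] -= 1
        spikers = np.flatnonzero((v_next > self.v_theta) & ~in_ref)
        v_next[spikers] = self.v_reset[spikers]
        self.ref[spikers] = np.where(self.ref_steps[spikers] > 0, self.ref_steps[spikers], 0)
        self.V = v_next
        for g in spikers:
            self.events.append((int(g), t))
            sl = slice(self.syn_bounds[g], self.syn_bounds[g + 1])
            for tgt, d, w in zip(self.syn_tgt[sl], self.syn_dly[sl], self.syn_wgt[sl]):
                self.sched[(t + int(d)) % _SLOTS, tgt] += w
        # assemble next step's input: delayed synaptic events + background
        nxt = (t + 1) % _SLOTS
        self.pending = self.sched[nxt].copy()
        self.sched[nxt] = 0.0
        for sl, rates, rng in self.bg_chunks:
            counts = rng.poisson(rates * self.dt)
            self.pending[sl] += counts * self.bg_weight
        self.step += 1
        return spikers

    def run(self, n_steps: int | None = None) -> SpikeRecording:
        if n_steps is None:
            n_steps = self.spec.n_steps
        for _ in range(n_steps):
            self.advance()
        events = np.array(self.events, dtype=np.int64).reshape(-1, 2)
        return SpikeRecording.from_events(events, self.spec, n_steps=self.step)


def run_flat(network: SampledNetwork, seed: int | None = None,
             mode: str | None = None, n_steps: int | None = None) -> SpikeRecording:
    """Run the flat reference simulator over a sampled network."""
    return FlatSimulator(network, seed=seed, mode=mode).run(n_steps=n_steps)
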