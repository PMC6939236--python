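"""Synthetic fixture networks and scaled-down configurations.

Every generator is a pure function of (name, parameters, seed), so tests and
examples need no external data.  The toy networks have analytically
tractable behaviour: ``single_chain`` propagates one spike hop by hop at a
known cadence; ``two_pop_balanced`` is a small excitatory/inhibitory pair;
``poisson_driven`` is background-driven with zero recurrent coupling.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .config import (
    BackgroundSpec,
    ConfigError,
    NetworkSpec,
    NeuronParams,
    Normal,
    PopulationSpec,
    ProjectionSpec,
)

__all__ = ["generate_toy_net", "generate_scaled_config", "TOY_GENERATORS"]

#: Small LIF cell used by toy nets; dyadic weights elsewhere keep input sums
#: exactly representable, which the oracle-equivalence tests rely on.
_TOY_LIF = NeuronParams(
    tau_m=10.0, V_rest=-65.0, V_reset=-65.0, V_theta=-50.0,
    R=40.0, tau_syn=0.5, I_DC=0.0, t_ref=2.0,
)


def _single_chain(params: dict, seed: int) -> NetworkSpec:
    """A feed-forward chain: strong synapse neuron k → k+1 with fixed delay.

    The first neuron is driven by a supra-threshold DC current so it fires
    regularly; each spike then travels one hop per ``delay`` steps.  The
    chain weight is dyadic and large enough that one incoming spike fires
    the target on the next threshold check.
    """
    n = int(params.get("n", 5))
    delay_steps = int(params.get("delay_steps", 5))
    dt = float(params.get("dt", 0.1))
    weight = float(params.get("weight", 65536.0))  # pA, dyadic; one spike fires the target on arrival
    driver = replace(_TOY_LIF, I_DC=500.0)  # V_inf = -65 + 20 mV > threshold
    # chain links are singleton populations so each p=1 projection is one synapse
    pops = [PopulationSpec("driver", 1, "excitatory", driver, init_V=Normal(-65.0, 0.0))]
    pops += [
        PopulationSpec(f"link{k}", 1, "excitatory", _TOY_LIF, init_V=Normal(-65.0, 0.0))
        for k in range(n)
    ]
    projs = [
        ProjectionSpec("driver", "link0", 1.0, Normal(weight, 0.0), Normal(delay_steps * dt, 0.0))
    ]
    projs += [
        ProjectionSpec(f"link{k}", f"link{k + 1}", 1.0, Normal(weight, 0.0),
                       Normal(delay_steps * dt, 0.0))
        for k in range(n - 1)
    ]
    return NetworkSpec(
        populations=tuple(pops),
        projections=tuple(projs),
        background=BackgroundSpec(mode="dc"),
        dt=dt,
        duration=float(params.get("duration", 100.0)),
        discard=0.0,
        seed=seed,
        name="single_chain",
    ).validate()


def _two_pop_balanced(params: dict, seed: int) -> NetworkSpec:
    """A small recurrent excitatory/inhibitory pair with Poisson drive."""
    n_exc = int(params.get("n_exc", 16))
    n_inh = int(params.get("n_inh", 4))
    p = float(params.get("p_connect", 0.25))
    w_exc = float(params.get("w_exc", 64.0))   # dyadic defaults
    w_inh = float(params.get("w_inh", 256.0))
    sd_frac = float(params.get("sd_frac", 0.0))
    # mean background current rate*w*tau_syn = 320 pA -> 12.8 mV above rest,
    # sub-threshold on average so firing is fluctuation-driven
    rate = float(params.get("rate", 10.0))  # kHz per neuron
    dt = float(params.get("dt", 0.1))
    pops = (
        PopulationSpec("exc", n_exc, "excitatory", _TOY_LIF, init_V=Normal(-60.0, 2.0)),
        PopulationSpec("inh", n_inh, "inhibitory", _TOY_LIF, init_V=Normal(-60.0, 2.0)),
    )
    de, di = Normal(1.5, 0.75 if sd_frac else 0.0), Normal(0.75, 0.375 if sd_frac else 0.0)
    projs = tuple(
        ProjectionSpec(src, tgt, p,
                       Normal(w_exc if src == "exc" else w_inh,
                              sd_frac * (w_exc if src == "exc" else w_inh)),
                       de if src == "exc" else di)
        for src in ("exc", "inh") for tgt in ("exc", "inh")
    )
    return NetworkSpec(
        populations=pops,
        projections=projs,
        background=BackgroundSpec(mode="poisson", weight=float(params.get("bg_weight", 64.0)),
                                  rate_per_neuron={"exc": rate, "inh": rate}),
        dt=dt,
        duration=float(params.get("duration", 200.0)),
        discard=0.0,
        seed=seed,
        name="two_pop_balanced",
    ).validate()


def _poisson_driven(params: dict, seed: int) -> NetworkSpec:
    """Unconnected neurons driven only by Poisson background input."""
    n = int(params.get("n", 64))
    rate = float(params.get("rate", 15.0))
    weight = float(params.get("weight", 87.8))
    pops = (
        PopulationSpec("drive", n, "excitatory", _TOY_LIF, init_V=Normal(-62.0, 2.0)),
    )
    return NetworkSpec(
        populations=pops,
        projections=(),
        background=BackgroundSpec(mode="poisson", weight=weight,
                                  rate_per_neuron={"drive": rate}),
        dt=float(params.get("dt", 0.1)),
        duration=float(params.get("duration", 1000.0)),
        discard=0.0,
        seed=seed,
        name="poisson_driven",
    ).validate()


TOY_GENERATORS = {
    "single_chain": _single_chain,
    "two_pop_balanced": _two_pop_balanced,
    "poisson_driven": _poisson_driven,
}


def generate_toy_net(name: str, params: dict | None = None, seed: int = 0) -> NetworkSpec:
    """Build a named toy network; identical (name, params, seed) ⇒ identical spec."""
    try:
        gen = TOY_GENERATORS[name]
    except KeyError:
        raise ConfigError(
            f"unknown toy generator {name!r}; known: {sorted(TOY_GENERATORS)}"
        ) from None
    return gen(dict(params or {}), seed)


def generate_scaled_config(scale: float, base: NetworkSpec) -> NetworkSpec:
    """Shrink population sizes by ``scale`` (rounded up), keeping probabilities.

    Downscaling is a testing surrogate only: connection probabilities are kept,
    so in-degrees shrink with the populations and the dynamics of a scaled
    model are NOT equivalent to the full-scale network.
    """
    if not 0.0 < scale <= 1.0:
        raise ConfigError(f"scale must lie in (0, 1], got {scale}")
    pops = tuple(
        replace(p, size=math.ceil(p.size * scale)) for p in base.populations
    )
    for p in pops:
        if p.size < 1:
            raise ConfigError(f"scale {scale} empties population {p.name!r}")
    return replace(base, populations=pops, name=f"{base.name}@{scale:g}").validate()
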