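"""Network specification: declarative model description, validation and sampling.

A :class:`NetworkSpec` declares populations of leaky integrate-and-fire (LIF)
neurons with current-based exponential synapses, probabilistic projections
between them, background drive (direct current or Poisson spike input), and
simulation controls.  Units are fixed across the package: time in ms, voltage
in mV, current in pA, resistance in MΩ, background rates in kHz.

Connectivity is sampled as an independent Bernoulli trial per ordered
(source, target) pair; weights and delays are drawn from per-projection
normal distributions.  Delays are quantized to the simulation grid and
clipped to the [1, 255]-step window that the synaptic ring buffers can
schedule.  All sampling is reproducible: streams are keyed off the global
seed per projection/population so results do not depend on iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "Normal",
    "NeuronParams",
    "PopulationSpec",
    "ProjectionSpec",
    "BackgroundSpec",
    "NetworkSpec",
    "SampledProjection",
    "SampledNetwork",
    "load_network_spec",
    "save_network_spec",
    "spec_from_dict",
    "spec_to_dict",
    "sample_connections",
    "sample_weights",
    "sample_delays",
    "quantize_delays",
    "build_network",
    "MIN_DELAY_STEPS",
    "MAX_DELAY_STEPS",
]

#: Delay window schedulable by a 255-slot ring buffer writing one slot ahead.
MIN_DELAY_STEPS = 1
MAX_DELAY_STEPS = 255

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised when a network specification fails validation."""


@dataclass(frozen=True)
class Normal:
    """A normal distribution given as mean and standard deviation."""

    mean: float
    sd: float

    def validate(self, name: str, positive_mean: bool = True) -> None:
        if self.sd < 0:
            raise ConfigError(f"{name}: sd must be >= 0, got {self.sd}")
        if positive_mean and self.mean <= 0:
            raise ConfigError(f"{name}: mean must be > 0, got {self.mean}")


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron constants (ms / mV / pA / MΩ).

    The membrane potential V relaxes to ``V_rest`` with time constant
    ``tau_m``; synaptic current ``I_syn`` jumps on spike arrival and decays
    with ``tau_syn``; input current is converted to voltage through the
    membrane resistance ``R``.  Crossing ``V_theta`` emits a spike and resets
    to ``V_reset``, after which the neuron is held there for ``t_ref``.
    """

    tau_m: float
    V_rest: float
    V_reset: float
    V_theta: float
    R: float
    tau_syn: float
    I_DC: float = 0.0
    t_ref: float = 0.0

    def validate(self, name: str = "neuron") -> None:
        if self.tau_m <= 0:
            raise ConfigError(f"{name}.tau_m must be > 0, got {self.tau_m}")
        if self.tau_syn <= 0:
            raise ConfigError(f"{name}.tau_syn must be > 0, got {self.tau_syn}")
        if not self.V_theta > self.V_reset:
            raise ConfigError(
                f"{name}: V_theta ({self.V_theta}) must exceed V_reset ({self.V_reset})"
            )
        if self.R <= 0:
            raise ConfigError(f"{name}.R must be > 0, got {self.R}")
        if self.t_ref < 0:
            raise ConfigError(f"{name}.t_ref must be >= 0, got {self.t_ref}")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    kind: str  # "excitatory" | "inhibitory"
    neuron: NeuronParams
    init_V: Normal = Normal(-65.0, 0.0)

    def validate(self) -> None:
        if self.size < 1:
            raise ConfigError(f"population {self.name!r}: size must be >= 1, got {self.size}")
        if self.kind not in ("excitatory", "inhibitory"):
            raise ConfigError(
                f"population {self.name!r}: kind must be excitatory|inhibitory, got {self.kind!r}"
            )
        self.neuron.validate(f"population {self.name!r}.neuron")
        if self.init_V.sd < 0:
            raise ConfigError(f"population {self.name!r}: init_V.sd must be >= 0")


@dataclass(frozen=True)
class ProjectionSpec:
    """A probabilistic all-to-all projection between two populations.

    ``weight`` is a distribution of magnitudes (pA); the sign is applied at
    input accumulation according to the source population's kind (Dale's law).
    """

    source: str
    target: str
    p_connect: float
    weight: Normal
    delay: Normal

    def validate(self) -> None:
        tag = f"projection {self.source}->{self.target}"
        if not 0.0 <= self.p_connect <= 1.0:
            raise ConfigError(f"{tag}: p_connect must lie in [0, 1], got {self.p_connect}")
        self.weight.validate(f"{tag}.weight")
        self.delay.validate(f"{tag}.delay")


@dataclass(frozen=True)
class BackgroundSpec:
    """Background drive shared by all populations.

    ``mode == "poisson"``: each neuron receives an independent Poisson spike
    source of the per-population rate (kHz) through a synapse of the given
    weight.  ``mode == "dc"``: the equivalent mean current
    rate × weight × τ_syn is injected as I_DC instead.
    """

    mode: str  # "dc" | "poisson"
    weight: float = 0.0
    rate_per_neuron: dict[str, float] = field(default_factory=dict)

    def validate(self, population_names: Iterable[str]) -> None:
        if self.mode not in ("dc", "poisson"):
            raise ConfigError(f"background.mode must be dc|poisson, got {self.mode!r}")
        names = set(population_names)
        for pop, rate in self.rate_per_neuron.items():
            if pop not in names:
                raise ConfigError(f"background.rate_per_neuron references unknown population {pop!r}")
            if rate <= 0:
                raise ConfigError(f"background rate for {pop!r} must be > 0 kHz, got {rate}")
        if self.rate_per_neuron and self.weight <= 0:
            raise ConfigError(f"background.weight must be > 0 pA, got {self.weight}")

    def dc_current(self, pop: str, tau_syn: float) -> float:
        """Mean current (pA) equivalent to the Poisson drive of ``pop``."""
        rate = self.rate_per_neuron.get(pop, 0.0)
        return rate * self.weight * tau_syn  # kHz * pA * ms = pA


@dataclass(frozen=True)
class NetworkSpec:
    populations: tuple[PopulationSpec, ...]
    projections: tuple[ProjectionSpec, ...]
    background: BackgroundSpec
    dt: float = 0.1
    duration: float = 1000.0
    discard: float = 1000.0
    seed: int = 0
    name: str = "network"

    def validate(self) -> "NetworkSpec":
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.duration < 0:
            raise ConfigError(f"duration must be >= 0, got {self.duration}")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("population names must be unique")
        for pop in self.populations:
            pop.validate()
        by_name = set(names)
        for proj in self.projections:
            proj.validate()
            for end, label in ((proj.source, "source"), (proj.target, "target")):
                if end not in by_name:
                    raise ConfigError(
                        f"projection {proj.source}->{proj.target}: {label} population "
                        f"{end!r} is not declared"
                    )
        self.background.validate(by_name)
        return self

    # -- convenience lookups -------------------------------------------------
    def population(self, name: str) -> PopulationSpec:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(name)

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def expected_synapses(self) -> float:
        """Expected recurrent synapse count under the Bernoulli-pair rule."""
        sizes = {p.name: p.size for p in self.populations}
        return sum(pr.p_connect * sizes[pr.source] * sizes[pr.target] for pr in self.projections)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _normal_from(obj, field_name: str) -> Normal:
    try:
        return Normal(mean=float(obj["mean"]), sd=float(obj["sd"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{field_name}: expected {{mean, sd}} mapping, got {obj!r}") from exc


def spec_from_dict(doc: dict) -> NetworkSpec:
    """Build and validate a :class:`NetworkSpec` from a plain mapping."""
    if not isinstance(doc, dict):
        raise ConfigError(f"top-level config must be a mapping, got {type(doc).__name__}")
    try:
        pops = []
        for p in doc.get("populations", []):
            neuron_doc = dict(p.get("neuron") or doc.get("neuron_defaults") or {})
            neuron = NeuronParams(**{k: float(v) for k, v in neuron_doc.items()})
            pops.append(
                PopulationSpec(
                    name=str(p["name"]),
                    size=int(p["size"]),
                    kind=str(p["kind"]),
                    neuron=neuron,
                    init_V=_normal_from(p.get("init_V", {"mean": neuron.V_rest, "sd": 0.0}),
                                        f"population {p.get('name')}.init_V"),
                )
            )
        projs = []
        for pr in doc.get("projections", []):
            projs.append(
                ProjectionSpec(
                    source=str(pr["source"]),
                    target=str(pr["target"]),
                    p_connect=float(pr["p_connect"]),
                    weight=_normal_from(pr["weight"], "projection.weight"),
                    delay=_normal_from(pr["delay"], "projection.delay"),
                )
            )
        bg_doc = doc.get("background", {"mode": "dc"})
        background = BackgroundSpec(
            mode=str(bg_doc.get("mode", "dc")).lower(),
            weight=float(bg_doc.get("weight", 0.0)),
            rate_per_neuron={str(k): float(v) for k, v in (bg_doc.get("rate_per_neuron") or {}).items()},
        )
        spec = NetworkSpec(
            populations=tuple(pops),
            projections=tuple(projs),
            background=background,
            dt=float(doc.get("dt", 0.1)),
            duration=float(doc.get("duration", 1000.0)),
            discard=float(doc.get("discard", 1000.0)),
            seed=int(doc.get("seed", 0)),
            name=str(doc.get("name", "network")),
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed network config: {exc}") from exc
    return spec.validate()


def spec_to_dict(spec: NetworkSpec) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": spec.name,
        "dt": spec.dt,
        "duration": spec.duration,
        "discard": spec.discard,
        "seed": spec.seed,
        "populations": [
            {
                "name": p.name,
                "size": p.size,
                "kind": p.kind,
                "neuron": asdict(p.neuron),
                "init_V": asdict(p.init_V),
            }
            for p in spec.populations
        ],
        "projections": [
            {
                "source": pr.source,
                "target": pr.target,
                "p_connect": pr.p_connect,
                "weight": asdict(pr.weight),
                "delay": asdict(pr.delay),
            }
            for pr in spec.projections
        ],
        "background": {
            "mode": spec.background.mode,
            "weight": spec.background.weight,
            "rate_per_neuron": dict(spec.background.rate_per_neuron),
        },
    }
    return doc


def load_network_spec(path: str | Path) -> NetworkSpec:
    """Load a YAML (or JSON — YAML is a superset) network config file."""
    path = Path(path)
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not parseable as YAML/JSON: {exc}") from exc
    return spec_from_dict(doc)


def save_network_spec(spec: NetworkSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def canonical_microcircuit(mode: str | None = None) -> NetworkSpec:
    """The shipped full-scale microcircuit spec (8 populations, 77,169 neurons)."""
    spec = load_network_spec(Path(__file__).parent / "data" / "microcircuit.yaml")
    if mode is not None:
        spec = replace(spec, background=replace(spec.background, mode=mode)).validate()
    return spec


# ---------------------------------------------------------------------------
# Stochastic sampling
# ---------------------------------------------------------------------------

def sample_connections(
    proj: ProjectionSpec,
    n_src: int,
    n_tgt: int,
    rng: np.random.Generator,
    chunk: int = 4096,
) -> np.ndarray:
    """Independent Bernoulli(p_connect) trial per ordered (src, tgt) pair.

    Returns an (n, 2) int array of [source index, target index] rows, sorted
    by source then target.  Autapses are permitted (the connection rule draws
    every ordered pair, including self-pairs for recurrent projections).
    """
    if n_src < 1 or n_tgt < 1:
        raise ConfigError("population sizes must be >= 1")
    p = proj.p_connect
    if p == 0.0:
        return np.empty((0, 2), dtype=np.int64)
    out = []
    for lo in range(0, n_src, chunk):
        hi = min(lo + chunk, n_src)
        mask = rng.random((hi - lo, n_tgt)) < p
        src, tgt = np.nonzero(mask)
        out.append(np.column_stack([src + lo, tgt]))
    return np.concatenate(out, axis=0) if out else np.empty((0, 2), dtype=np.int64)


def sample_weights(proj: ProjectionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n weight magnitudes (pA); negative draws are clipped to 0."""
    w = rng.normal(proj.weight.mean, proj.weight.sd, size=n)
    return np.maximum(w, 0.0)


def quantize_delays(delays_ms: np.ndarray, dt: float) -> np.ndarray:
    """Quantize delays to time steps: round half away from zero, clip [1, 255]."""
    steps = delays_ms / dt
    steps = np.sign(steps) * np.floor(np.abs(steps) + 0.5)
    return np.clip(steps, MIN_DELAY_STEPS, MAX_DELAY_STEPS).astype(np.int64)


def sample_delays(proj: ProjectionSpec, n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n transmission delays and quantize them to integer steps."""
    if dt <= 0:
        raise ConfigError(f"dt must be > 0, got {dt}")
    return quantize_delays(rng.normal(proj.delay.mean, proj.delay.sd, size=n), dt)


# ---------------------------------------------------------------------------
# Network instantiation
# ---------------------------------------------------------------------------

@dataclass
class SampledProjection:
    """One projection's sampled synapses (row inputs for synaptic matrices)."""

    spec: ProjectionSpec
    source_kind: str
    src: np.ndarray      # source index within source population
    tgt: np.ndarray      # target index within target population
    weight: np.ndarray   # magnitude, pA
    delay_steps: np.ndarray

    @property
    def n_synapses(self) -> int:
        return len(self.src)


@dataclass
class SampledNetwork:
    """A fully instantiated network: sampled synapses plus initial voltages."""

    spec: NetworkSpec
    projections: list[SampledProjection]
    init_V: dict[str, np.ndarray]
    pop_offset: dict[str, int]

    @property
    def n_synapses(self) -> int:
        return sum(p.n_synapses for p in self.projections)

    def kind_of(self, pop: str) -> str:
        return self.spec.population(pop).kind


def projection_rng(seed: int, index: int) -> np.random.Generator:
    """Keyed stream for projection ``index``; independent of build order."""
    return np.random.default_rng([seed, 1, index])


def build_network(spec: NetworkSpec, seed: int | None = None) -> SampledNetwork:
    """Instantiate connectivity, weights, delays and initial state.

    Deterministic given (spec, seed): each projection and each population
    draws from its own stream keyed by the global seed, so the result is
    independent of sampling order.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    sizes = {p.name: p.size for p in spec.populations}
    projections: list[SampledProjection] = []
    for i, proj in enumerate(spec.projections):
        rng = projection_rng(seed, i)
        pairs = sample_connections(proj, sizes[proj.source], sizes[proj.target], rng)
        n = len(pairs)
        weights = sample_weights(proj, n, rng)
        delays = sample_delays(proj, n, spec.dt, rng)
        projections.append(
            SampledProjection(
                spec=proj,
                source_kind=spec.population(proj.source).kind,
                src=pairs[:, 0],
                tgt=pairs[:, 1],
                weight=weights,
                delay_steps=delays,
            )
        )
    init_V = {}
    offset = 0
    pop_offset = {}
    for j, pop in enumerate(spec.populations):
        rng = np.random.default_rng([seed, 0, j])
        v = rng.normal(pop.init_V.mean, pop.init_V.sd, size=pop.size)
        # keep the initial state sub-threshold: a draw above V_theta is clipped
        init_V[pop.name] = np.minimum(v, pop.neuron.V_theta)
        pop_offset[pop.name] = offset
        offset += pop.size
    return SampledNetwork(spec=spec, projections=projections, init_V=init_V, pop_offset=pop_offset)
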