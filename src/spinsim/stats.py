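"""Spiketrain validation statistics.

Correctness of a run is judged from its output spiketrains, not from
internal state: per-step spike decomposition into excitatory and inhibitory
counts, per-neuron firing-rate distributions by population, the coefficient
of variation of inter-spike intervals (0 for clock-regular firing, ≈1 for
Poisson firing), and Pearson correlation coefficients between binned pairs
of spiketrains, with the bin width chosen by the Freedman–Diaconis rule on
the pooled spike times.  An initial transient (default 1 s) is discarded
before computing rates/CV/correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import iqr

__all__ = [
    "SpikeRecording",
    "per_step_counts",
    "population_rates",
    "cv_isi",
    "freedman_diaconis_width",
    "bin_spiketrains",
    "correlation_coefficients",
    "histogram_overlap",
]


@dataclass
class SpikeRecording:
    """An event log of (global neuron id, time step) plus population metadata.

    ``populations`` maps each population name to (offset, size, kind) where
    offset is the first global id of the population; ids are contiguous.
    """

    events: np.ndarray  # (n, 2) int64: [neuron id, step]
    populations: dict[str, tuple[int, int, str]]
    dt: float  # ms
    n_steps: int

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if len(self.events):
            if self.events[:, 1].min() < 0 or self.events[:, 1].max() >= self.n_steps:
                raise ValueError("event steps outside the run bounds")
            if self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.n_neurons:
                raise ValueError("event neuron ids outside the network")

    @classmethod
    def from_events(cls, events: np.ndarray, spec, n_steps: int) -> "SpikeRecording":
        pops = {}
        offset = 0
        for p in spec.populations:
            pops[p.name] = (offset, p.size, p.kind)
            offset += p.size
        return cls(events=events, populations=pops, dt=spec.dt, n_steps=n_steps)

    @property
    def n_neurons(self) -> int:
        return sum(size for _off, size, _k in self.populations.values())

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def kind_of_id(self) -> np.ndarray:
        """Per-global-id excitatory flag (True = excitatory)."""
        flags = np.zeros(self.n_neurons, dtype=bool)
        for off, size, kind in self.populations.values():
            flags[off:off + size] = kind == "excitatory"
        return flags

    def neuron_ids(self, population: str) -> np.ndarray:
        off, size, _ = self.populations[population]
        return np.arange(off, off + size)

    def spikes_of(self, neuron_id: int) -> np.ndarray:
        """Spike steps of one neuron, sorted."""
        return np.sort(self.events[self.events[:, 0] == neuron_id, 1])


def per_step_counts(rec: SpikeRecording) -> pd.DataFrame:
    """Total / excitatory / inhibitory spike counts for every step."""
    exc_flag = rec.kind_of_id()
    total = np.bincount(rec.events[:, 1], minlength=rec.n_steps)
    is_exc = exc_flag[rec.events[:, 0]]
    exc = np.bincount(rec.events[is_exc, 1], minlength=rec.n_steps)
    return pd.DataFrame(
        {
            "step": np.arange(rec.n_steps),
            "total": total,
            "excitatory": exc,
            "inhibitory": total - exc,
        }
    )


def population_rates(rec: SpikeRecording, discard: float = 1000.0) -> dict[str, np.ndarray]:
    """Per-neuron firing rates (Hz) after discarding the initial transient.

    rate = spikes after ``discard`` ms / (duration − discard); silent neurons
    contribute 0 Hz.
    """
    if rec.duration <= discard:
        raise ValueError(
            f"duration {rec.duration} ms must exceed the discarded transient {discard} ms"
        )
    window_s = (rec.duration - discard) / 1000.0
    first_step = int(np.ceil(discard / rec.dt))
    kept = rec.events[rec.events[:, 1] >= first_step]
    counts = np.bincount(kept[:, 0], minlength=rec.n_neurons)
    rates = counts / window_s
    return {name: rates[off:off + size] for name, (off, size, _k) in rec.populations.items()}


def cv_isi(rec: SpikeRecording, discard: float = 1000.0, min_spikes: int = 3) -> dict[str, np.ndarray]:
    """Coefficient of variation of inter-spike intervals per neuron.

    Neurons with fewer than ``min_spikes`` spikes (after the transient) are
    excluded from the distribution rather than reported as NaN.
    """
    first_step = int(np.ceil(discard / rec.dt))
    kept = rec.events[rec.events[:, 1] >= first_step]
    order = np.lexsort((kept[:, 1], kept[:, 0]))
    kept = kept[order]
    out: dict[str, list[float]] = {name: [] for name in rec.populations}
    if len(kept):
        ids, starts = np.unique(kept[:, 0], return_index=True)
        bounds = np.append(starts, len(kept))
        for i, nid in enumerate(ids):
            train = kept[bounds[i]:bounds[i + 1], 1]
            if len(train) < min_spikes:
                continue
            isi = np.diff(train.astype(float)) * rec.dt
            m = isi.mean()
            if m > 0:
                cv = isi.std(ddof=0) / m
                for name, (off, size, _k) in rec.populations.items():
                    if off <= nid < off + size:
                        out[name].append(cv)
                        break
    return {name: np.asarray(v) for name, v in out.items()}


def freedman_diaconis_width(samples: np.ndarray, floor: float | None = None) -> float:
    """Freedman–Diaconis bin width 2·IQR·n^(−1/3), floored at ``floor``."""
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    if n == 0:
        raise ValueError("cannot choose a bin width for an empty sample")
    width = 2.0 * iqr(samples) * n ** (-1.0 / 3.0)
    if floor is not None:
        width = max(width, floor)
    if width <= 0:
        width = floor if floor else 1.0
    return float(width)


def bin_spiketrains(
    rec: SpikeRecording,
    neuron_ids: np.ndarray,
    discard: float = 1000.0,
    bin_width: float | None = None,
) -> tuple[np.ndarray, float]:
    """Bin the spiketrains of the given neurons into count series.

    The bin width, unless given, follows Freedman–Diaconis on the pooled
    spike times (ms) of the selected neurons, floored at one dt.  Returns
    (counts matrix of shape (n_neurons, n_bins), bin width ms).
    """
    first_step = int(np.ceil(discard / rec.dt))
    mask = np.isin(rec.events[:, 0], neuron_ids) & (rec.events[:, 1] >= first_step)
    ev = rec.events[mask]
    times = ev[:, 1].astype(float) * rec.dt
    if bin_width is None:
        if len(times) == 0:
            bin_width = rec.dt
        else:
            bin_width = freedman_diaconis_width(times, floor=rec.dt)
    edges = np.arange(discard, rec.duration + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([discard, rec.duration])
    id_to_row = {int(n): i for i, n in enumerate(neuron_ids)}
    counts = np.zeros((len(neuron_ids), len(edges) - 1))
    rows = np.array([id_to_row[int(n)] for n in ev[:, 0]], dtype=np.int64)
    cols = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    np.add.at(counts, (rows, cols), 1.0)
    return counts, float(bin_width)


def correlation_coefficients(
    rec: SpikeRecording,
    population: str,
    sample_size: int = 10_000,
    rng: np.random.Generator | None = None,
    discard: float = 1000.0,
    bin_width: float | None = None,
) -> np.ndarray:
    """Pairwise Pearson correlations of binned spiketrains within a population.

    Pairs are a random sample of disjoint (i ≠ j) pairs, since the full pair
    set is quadratic in population size; pairs involving a zero-variance
    binned train are skipped.
    """
    ids = rec.neuron_ids(population)
    if len(ids) < 2:
        raise ValueError(f"population {population!r} has fewer than two neurons")
    if rng is None:
        rng = np.random.default_rng()
    counts, _w = bin_spiketrains(rec, ids, discard=discard, bin_width=bin_width)
    n = len(ids)
    n_pairs = min(sample_size, n * (n - 1) // 2)
    a = rng.integers(0, n, size=2 * n_pairs)
    b = rng.integers(0, n, size=2 * n_pairs)
    keep = a != b
    pairs = np.column_stack([a[keep], b[keep]])[:n_pairs]
    sd = counts.std(axis=1)
    out = []
    for i, j in pairs:
        if sd[i] == 0 or sd[j] == 0:
            continue
        x, y = counts[i], counts[j]
        out.append(float(np.corrcoef(x, y)[0, 1]))
    return np.asarray(out)


def histogram_overlap(a: np.ndarray, b: np.ndarray, bins: int | np.ndarray = 30) -> float:
    """Overlap coefficient between two samples' normalized histograms.

    1 means identical distributions over the shared binning, 0 disjoint.
    Used to compare distributions (rates, CVs, correlations) between two
    runs of the same model on different backends or seeds.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compare empty samples")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1) if np.isscalar(bins) else np.asarray(bins)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())
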