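"""File formats: spike logs (TSV and gdf dialect), profiles, summaries.

Spike TSV columns: ``time_step<TAB>neuron_id`` with a header line.  The gdf
dialect mirrors the NEST text format: ``neuron_id<TAB>time_ms`` without a
header, time = step × dt exactly.  Core profiles are written one row per
(step, ensemble, role).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .stats import SpikeRecording

__all__ = [
    "SpikeFileError",
    "write_spikes",
    "read_spikes",
    "write_spikes_gdf",
    "read_spikes_gdf",
    "write_profiles",
    "read_profiles",
]


class SpikeFileError(ValueError):
    """Malformed spike file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def write_spikes(rec: SpikeRecording, path: str | Path) -> None:
    """Write the event log as TSV (time_step, neuron_id), one row per spike."""
    with open(path, "w") as fh:
        fh.write("time_step\tneuron_id\n")
        for nid, step in rec.events:
            fh.write(f"{step}\t{nid}\n")


def _parse_events(path: str | Path, skip_header: bool, time_first: bool,
                  scale: float | None) -> np.ndarray:
    events = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line_no == 1 and skip_header:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SpikeFileError(path, line_no, f"expected 2 tab-separated fields, got {len(parts)}")
            try:
                if time_first:
                    t, nid = parts
                else:
                    nid, t = parts
                nid = int(nid)
                step = int(t) if scale is None else int(round(float(t) / scale))
            except ValueError as exc:
                raise SpikeFileError(path, line_no, str(exc)) from None
            events.append((nid, step))
    return np.array(events, dtype=np.int64).reshape(-1, 2)


def read_spikes(path: str | Path, template: SpikeRecording) -> SpikeRecording:
    """Read a spike TSV; population metadata is taken from ``template``."""
    events = _parse_events(path, skip_header=True, time_first=True, scale=None)
    return SpikeRecording(events=events, populations=template.populations,
                          dt=template.dt, n_steps=template.n_steps)


def write_spikes_gdf(rec: SpikeRecording, path: str | Path) -> None:
    """gdf dialect: ``neuron_id<TAB>time_ms`` (time = step × dt), no header."""
    with open(path, "w") as fh:
        for nid, step in rec.events:
            fh.write(f"{nid}\t{step * rec.dt:.10g}\n")


def read_spikes_gdf(path: str | Path, template: SpikeRecording) -> SpikeRecording:
    events = _parse_events(path, skip_header=False, time_first=False, scale=template.dt)
    return SpikeRecording(events=events, populations=template.populations,
                          dt=template.dt, n_steps=template.n_steps)


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
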