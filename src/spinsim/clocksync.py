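"""Board clock drift, beacon correction and start-signal phase alignment.

Cores on one board share a crystal, so their timers tick together; crystals
on different boards differ by a small relative rate error (tens of ppm),
which accumulates into timer drift over long runs.  A master board
broadcasts a beacon every 2 s; each slave compares the master's inter-beacon
interval (in clock cycles) with the cycles elapsed on its own clock and
derives a per-timer-period correction.  Corrections are usually below one
cycle per period, so fractional parts are accumulated and applied as whole
cycles.  Phase alignment at startup uses the start signal's known transit
time — 500 ns per router hop plus 900 ns per board-to-board link — and
delays each chip by (max transit − own transit) so all chips begin in phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROUTER_HOP_NS",
    "BOARD_LINK_NS",
    "Machine",
    "DriftModel",
    "compute_correction",
    "CorrectionAccumulator",
    "start_delay",
    "simulate_alignment",
]

ROUTER_HOP_NS = 500.0
BOARD_LINK_NS = 900.0


@dataclass(frozen=True)
class Machine:
    """A rectangular chip grid tiled into boards.

    Hop counting is Manhattan on the chip grid, with wrap-around honoured
    when ``torus`` is set; board-link crossings are counted between board
    tiles of shape ``board_shape`` (48-chip boards modelled as rectangular
    8×6 tiles).
    """

    width: int
    height: int
    board_shape: tuple[int, int] = (8, 6)
    torus: bool = False

    def _axis_hops(self, a: int, b: int, span: int) -> int:
        d = abs(a - b)
        return min(d, span - d) if self.torus else d

    def hops(self, a: tuple[int, int], b: tuple[int, int]) -> int:
        return self._axis_hops(a[0], b[0], self.width) + self._axis_hops(a[1], b[1], self.height)

    def board_of(self, chip: tuple[int, int]) -> tuple[int, int]:
        return chip[0] // self.board_shape[0], chip[1] // self.board_shape[1]

    def board_links(self, a: tuple[int, int], b: tuple[int, int]) -> int:
        ba, bb = self.board_of(a), self.board_of(b)
        bw = self.width // self.board_shape[0]
        bh = self.height // self.board_shape[1]
        dx = abs(ba[0] - bb[0])
        dy = abs(ba[1] - bb[1])
        if self.torus and bw > 0 and bh > 0:
            dx = min(dx, bw - dx)
            dy = min(dy, bh - dy)
        return dx + dy

    def transit_ns(self, a: tuple[int, int], b: tuple[int, int]) -> float:
        """Packet transit time between two chips."""
        return ROUTER_HOP_NS * self.hops(a, b) + BOARD_LINK_NS * self.board_links(a, b)

    def chips(self):
        return [(x, y) for y in range(self.height) for x in range(self.width)]


@dataclass
class DriftModel:
    """Constant relative clock-rate error per board (dimensionless, e.g. 5e-5)."""

    board_errors: list[float]
    beacon_interval_s: float = 2.0
    clock_hz: float = 200e6

    def __post_init__(self):
        if any(abs(e) >= 0.01 for e in self.board_errors):
            raise ValueError("relative clock errors must be small (|e| << 1)")


def compute_correction(master_interval: float, local_elapsed: float, periods: int) -> float:
    """Clock-cycle correction per timer period from one beacon observation.

    ``master_interval`` and ``local_elapsed`` are the cycles counted between
    two beacons by the master and the local clock; the (usually fractional)
    difference is spread over the ``periods`` timer periods in the interval.
    """
    if periods < 1:
        raise ValueError("periods must be >= 1")
    return (master_interval - local_elapsed) / periods


class CorrectionAccumulator:
    """Accumulate sub-cycle corrections; release whole cycles when ready."""

    def __init__(self):
        self.residual = 0.0

    def apply(self, correction: float) -> int:
        self.residual += correction
        whole = math.trunc(self.residual)
        self.residual -= whole
        return whole


def start_delay(chip: tuple[int, int], machine: Machine, origin: tuple[int, int] = (0, 0)) -> float:
    """Start-signal phase-alignment delay (ns) for a chip.

    The start signal radiates from the origin chip; a chip waits
    max-transit − own-transit before starting, so the chip(s) farthest from
    the origin start immediately and all chips begin in phase.
    """
    transits = {c: machine.transit_ns(origin, c) for c in machine.chips()}
    return max(transits.values()) - transits[chip]


def _released(x: np.ndarray) -> np.ndarray:
    """Whole cycles released by a truncating accumulator after input total x."""
    return np.trunc(x)


def simulate_alignment(
    drift: DriftModel,
    duration_s: float,
    timer_period_us: float = 100.0,
    correct: bool = True,
    warmup_beacons: int = 1,
) -> float:
    """Simulate per-board timers under drift; return max misalignment (µs).

    Board 0 is the beacon master; all boards start in phase (the start-signal
    alignment of :func:`start_delay` is assumed).  A board whose crystal runs
    at (1 + e) × nominal rate sees its 20,000-cycle timer period shortened in
    wall-clock terms by the same factor; the beacon protocol measures the
    master interval against the locally elapsed cycles and spreads the
    difference over the interval's timer periods (:func:`compute_correction`),
    with sub-cycle amounts accumulated and applied as whole cycles.  The
    beacon protocol corrects rate only; phase comes from the start-signal
    alignment, which fires once corrections have converged — modelled by
    re-phasing all boards after ``warmup_beacons`` beacon intervals and then
    measuring.  The returned figure is the maximum wall-clock offset of any
    board's timer tick from the master's over the measured intervals.
    """
    f0 = drift.clock_hz
    c0 = round(timer_period_us * 1e-6 * f0)  # nominal cycles per period
    periods = int(round(drift.beacon_interval_s / (timer_period_us * 1e-6)))
    n_beacons = max(warmup_beacons + 1, int(round(duration_s / drift.beacon_interval_s)))
    errors = np.asarray(drift.board_errors, dtype=float)
    rates = f0 * (1.0 + errors)
    extra = np.zeros(len(errors))  # correction cycles added per period
    t0 = np.zeros(len(errors))     # wall time of each board's last tick
    carried = np.zeros(len(errors))
    worst = 0.0
    j = np.arange(1, periods + 1)
    for beacon in range(n_beacons):
        if beacon == warmup_beacons:
            t0 = np.full(len(errors), t0[0])  # start-signal phase alignment
        start_wall = t0.copy()
        # tick times within this interval: j*c0 plus whole released correction
        rel = _released(carried[:, None] + j[None, :] * extra[:, None]) - _released(carried)[:, None]
        ticks = start_wall[:, None] + (j[None, :] * c0 + rel) / rates[:, None]
        if beacon >= warmup_beacons:
            worst = max(worst, float(np.max(np.abs(ticks - ticks[0:1, :]))) * 1e6)
        carried = carried + periods * extra
        carried = carried - _released(carried)  # keep only the sub-cycle residue
        t0 = ticks[:, -1]
        if correct:
            # master interval in master cycles vs cycles elapsed locally
            wall_interval = t0[0] - start_wall[0]
            master_cycles = wall_interval * rates[0]
            local_cycles = wall_interval * rates
            extra = np.array(
                [-compute_correction(master_cycles, local_cycles[i], periods)
                 for i in range(len(errors))]
            )
    return worst
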