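"""Seeded stochastic state trajectories from a permeation cycle.

Stands in for the raw molecular-dynamics data: state-labelled time series are
drawn exactly from the continuous-time Markov chain defined by a
PermeationCycle at a given voltage, mirroring the original ensemble design of
100 independent 10 ns runs at each of 100/200/400/600/800 mV.

Sampling is event-driven (Gillespie): the dwell in each state is exponential
with the state's total exit rate, and the successor is drawn proportionally
to the outgoing rates. Unidirectional cycles take a vectorized fast path in
which the (deterministic) state sequence is tiled and dwells drawn in blocks;
cycles with backward transitions use the per-event loop. Both are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import SimulationError
from .kinetic_model import PermeationCycle, rate_at_voltage, steady_state

__all__ = ["SimulationConfig", "Trajectory", "simulate_trajectory", "simulate_ensemble",
           "resample_trajectory", "derive_seed"]

PAPER_VOLTAGES = (100.0, 200.0, 400.0, 600.0, 800.0)  # mV


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble design: which cycle, at which voltages, how much sampling.

    Defaults reproduce the reference ensemble: 100 trajectories of 10 ns at
    each of five voltages (1 microsecond of data per voltage).
    """

    cycle: PermeationCycle
    voltages: tuple[float, ...] = PAPER_VOLTAGES
    n_trajectories: int = 100
    duration: float = 10.0  # ns
    seed: int = 0
    initial_state: str = "stationary"  # state label, or "stationary"
    sampling_interval: float | None = None  # ns, for resampled output

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise SimulationError(f"n_trajectories must be >= 1, got {self.n_trajectories}")
        if not self.duration > 0:
            raise SimulationError(f"duration must be positive, got {self.duration}")
        if not self.voltages:
            raise SimulationError("at least one voltage required")
        if self.initial_state != "stationary":
            self.cycle.state_index(self.initial_state)  # raises on unknown label


@dataclass
class Trajectory:
    """A single state-labelled realization of the permeation chain.

    Segments (state, entry time, dwell) tile [0, duration]; the last dwell is
    truncated at the horizon. ``permeation_times`` are the firing times of
    the cycle's designated permeation transition.
    """

    voltage: float  # mV
    states: list[str]  # one label per segment
    entry_times: np.ndarray  # ns
    dwells: np.ndarray  # ns
    duration: float  # ns
    permeation_times: np.ndarray  # ns, strictly increasing
    seed_used: int

    def __post_init__(self) -> None:
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        self.dwells = np.asarray(self.dwells, dtype=float)
        self.permeation_times = np.asarray(self.permeation_times, dtype=float)
        n = len(self.states)
        if n == 0 or len(self.entry_times) != n or len(self.dwells) != n:
            raise SimulationError("segment arrays must be non-empty and equal length")
        if abs(self.entry_times[0]) > 1e-12:
            raise SimulationError("first segment must start at t=0")
        gaps = self.entry_times[1:] - (self.entry_times[:-1] + self.dwells[:-1])
        if n > 1 and np.max(np.abs(gaps)) > 1e-9:
            raise SimulationError("segments must tile the duration without gaps/overlaps")
        if abs(self.entry_times[-1] + self.dwells[-1] - self.duration) > 1e-9:
            raise SimulationError("segments must end exactly at the duration")
        if any(a == b for a, b in zip(self.states, self.states[1:])):
            raise SimulationError("consecutive segment states must differ")
        if len(self.permeation_times) > 1 and np.any(np.diff(self.permeation_times) <= 0):
            raise SimulationError("permeation times must be strictly increasing")

    @property
    def segments(self) -> list[tuple[str, float, float]]:
        return list(zip(self.states, self.entry_times.tolist(), self.dwells.tolist()))

    @property
    def n_permeations(self) -> int:
        return len(self.permeation_times)


def derive_seed(master_seed: int, voltage_index: int, trajectory_index: int) -> int:
    """Deterministic per-trajectory seed.

    Realized as ``SeedSequence(master, spawn_key=(voltage_index,
    trajectory_index))``; stable across runs and platforms.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(voltage_index, trajectory_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _initial_index(
    cycle: PermeationCycle,
    voltage: float,
    initial_state: str,
    rng: np.random.Generator,
    constants: PhysicalConstants,
) -> int:
    if initial_state == "stationary":
        pi = steady_state(cycle, voltage, constants)
        return int(rng.choice(len(pi), p=pi))
    return cycle.state_index(initial_state)


def _simulate_unidirectional(
    cycle: PermeationCycle,
    voltage: float,
    duration: float,
    rng: np.random.Generator,
    start: int,
    constants: PhysicalConstants,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact sampling when each state has a single successor.

    Returns (state index per segment, dwell per segment), last dwell already
    truncated at ``duration``.
    """
    n = len(cycle.states)
    k = np.array([rate_at_voltage(tr.rate, voltage, constants) for tr in cycle.transitions])
    # expected segments ~ duration / mean cycle time * n; draw in generous blocks
    mean_cycle = float(np.sum(1.0 / k))
    block = max(64, int(duration / mean_cycle * n * 1.2) + 4 * n)
    seq_chunks: list[np.ndarray] = []
    dwell_chunks: list[np.ndarray] = []
    total = 0.0
    cur = start
    while total < duration:
        seq = (cur + np.arange(block)) % n
        dw = rng.exponential(1.0, size=block) / k[seq]
        seq_chunks.append(seq)
        dwell_chunks.append(dw)
        total += float(dw.sum())
        cur = int((seq[-1] + 1) % n)
    seq = np.concatenate(seq_chunks)
    dw = np.concatenate(dwell_chunks)
    ends = np.cumsum(dw)
    last = int(np.searchsorted(ends, duration, side="left"))  # segment containing `duration`
    seq, dw, ends = seq[: last + 1], dw[: last + 1].copy(), ends[: last + 1]
    dw[-1] -= ends[-1] - duration  # truncate at the horizon
    return seq, dw


def _simulate_general(
    cycle: PermeationCycle,
    voltage: float,
    duration: float,
    rng: np.random.Generator,
    start: int,
    constants: PhysicalConstants,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-event Gillespie loop for cycles with backward transitions."""
    n = len(cycle.states)
    targets: list[list[int]] = [[] for _ in range(n)]
    rates: list[list[float]] = [[] for _ in range(n)]
    for tr in cycle.all_transitions():
        i = cycle.state_index(tr.from_state)
        targets[i].append(cycle.state_index(tr.to_state))
        rates[i].append(rate_at_voltage(tr.rate, voltage, constants))
    exit_rate = np.array([sum(r) for r in rates])
    if np.any(exit_rate <= 0):
        bad = cycle.labels[int(np.argmin(exit_rate))]
        raise SimulationError(f"state {bad!r} is absorbing (zero exit rate)")
    probs = [np.array(r) / er for r, er in zip(rates, exit_rate)]

    seq: list[int] = []
    dw: list[float] = []
    t = 0.0
    cur = start
    while t < duration:
        tau = rng.exponential(1.0 / exit_rate[cur])
        seq.append(cur)
        if t + tau >= duration:
            dw.append(duration - t)
            t = duration
        else:
            dw.append(tau)
            t += tau
            opts = targets[cur]
            if len(opts) == 1:
                cur = opts[0]
            else:
                cur = opts[int(rng.choice(len(opts), p=probs[cur]))]
    return np.array(seq), np.array(dw)


def simulate_trajectory(
    cycle: PermeationCycle,
    voltage: float,
    duration: float,
    seed: int,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    initial_state: str = "stationary",
) -> Trajectory:
    """Draw one exact CTMC trajectory of length ``duration`` ns.

    Reproducible: the same seed yields the same trajectory bit-for-bit. The
    start state is drawn from the stationary distribution by default (the
    chain analogue of equilibrating before production), or fixed by label.
    """
    if not duration > 0:
        raise SimulationError(f"duration must be positive, got {duration}")
    if not math.isfinite(voltage):
        raise SimulationError(f"voltage must be finite, got {voltage}")
    rng = np.random.default_rng(seed)
    start = _initial_index(cycle, voltage, initial_state, rng, constants)
    if cycle.is_unidirectional:
        seq, dw = _simulate_unidirectional(cycle, voltage, duration, rng, start, constants)
    else:
        seq, dw = _simulate_general(cycle, voltage, duration, rng, start, constants)

    entry = np.concatenate(([0.0], np.cumsum(dw)[:-1]))
    labels = list(cycle.labels)
    states = [labels[i] for i in seq]

    perm_from = cycle.state_index(cycle.permeation_transition[0])
    perm_to = cycle.state_index(cycle.permeation_transition[1])
    # a completed segment in perm_from whose successor is perm_to fires the event
    fired = (seq[:-1] == perm_from) & (seq[1:] == perm_to)
    perm_times = entry[1:][fired]

    return Trajectory(
        voltage=voltage,
        states=states,
        entry_times=entry,
        dwells=dw,
        duration=duration,
        permeation_times=perm_times,
        seed_used=int(seed),
    )


def simulate_ensemble(
    config: SimulationConfig, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> dict[float, list[Trajectory]]:
    """Simulate ``n_trajectories`` per voltage; per-trajectory seeds derive
    deterministically from the master seed (see :func:`derive_seed`)."""
    out: dict[float, list[Trajectory]] = {}
    for vi, v in enumerate(config.voltages):
        out[float(v)] = [
            simulate_trajectory(
                config.cycle,
                float(v),
                config.duration,
                derive_seed(config.seed, vi, ti),
                constants,
                config.initial_state,
            )
            for ti in range(config.n_trajectories)
        ]
    return out


def resample_trajectory(traj: Trajectory, interval: float):
    """Discretize a trajectory onto a fixed time grid (like saving frames).

    Grid points are 0, interval, 2*interval, ..., floor(duration/interval)
    intervals; the state at each grid time is that of the segment containing
    it. Returns a pandas DataFrame with columns time_ns, state.
    """
    import pandas as pd

    if not interval > 0:
        raise SimulationError(f"interval must be positive, got {interval}")
    if interval > traj.duration:
        raise SimulationError(
            f"interval {interval} ns exceeds trajectory duration {traj.duration} ns"
        )
    n_steps = int(math.floor(traj.duration / interval))
    grid = np.arange(n_steps + 1) * interval
    idx = np.searchsorted(traj.entry_times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(traj.states) - 1)
    return pd.DataFrame({"time_ns": grid, "state": [traj.states[i] for i in idx]})
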