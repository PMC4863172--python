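"""Rate-constant estimation from state trajectories.

The estimator is the counting relation J_ij = k_ij * P_i: the transition flux
J_ij is the number of observed i->j transitions per unit total time, and P_i
the fraction of time spent in state i. Equivalently, and exactly,
k_ij = N_ij / T_i — transitions out of i per unit dwell time in i, the
maximum-likelihood estimator for an exponential dwell process. Per-voltage
estimates are then fitted on the log scale to the exponential law
k(V) = k0 * exp(d*V/V_T) to recover the zero-voltage rate and the electrical
distance of each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import EstimationError
from .kinetic_model import PermeationCycle
from .trajectories import Trajectory

__all__ = [
    "TransitionCounts",
    "RateEstimate",
    "TransitionFit",
    "RateFit",
    "count_transitions",
    "estimate_rates",
    "current_from_events",
    "fit_voltage_dependence",
]

TransitionKey = tuple[str, str]


@dataclass(frozen=True)
class TransitionCounts:
    """Pooled transition counts and dwell times at one voltage."""

    voltage: float  # mV
    n_ij: Mapping[TransitionKey, int]  # observed transition counts
    dwell: Mapping[str, float]  # total time in each state, ns
    total_time: float  # ns
    n_permeations: int

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_ij.values()):
            raise EstimationError("transition counts must be non-negative")
        if self.total_time <= 0:
            raise EstimationError(f"total_time must be positive, got {self.total_time}")
        s = sum(self.dwell.values())
        if abs(s - self.total_time) > 1e-6 * max(1.0, self.total_time):
            raise EstimationError(
                f"dwell times sum to {s} ns but total_time is {self.total_time} ns"
            )

    @property
    def occupancy(self) -> dict[str, float]:
        """P_i = T_i / total_time; sums to 1."""
        return {s: t / self.total_time for s, t in self.dwell.items()}


@dataclass(frozen=True)
class RateEstimate:
    """Per-transition rate constants at one voltage.

    ``rates`` maps each transition to k = N_ij/T_i in ns^-1, or to None when
    the transition was never observed (an explicit missing marker — zero
    would wrongly assert an infinitely slow step). ``stderr`` carries the
    Poisson dispersion k/sqrt(N).
    """

    voltage: float
    rates: Mapping[TransitionKey, float | None]
    stderr: Mapping[TransitionKey, float | None]
    counts: TransitionCounts


@dataclass(frozen=True)
class TransitionFit:
    k0: float  # ns^-1, exp(intercept) of the ln k vs V line
    d: float  # electrical distance, slope * V_T
    r_squared: float
    n_voltages: int


@dataclass(frozen=True)
class RateFit:
    """Exponential voltage-dependence fits, one per transition."""

    fits: Mapping[TransitionKey, TransitionFit]
    missing: Mapping[TransitionKey, str] = field(default_factory=dict)
    voltages_used: tuple[float, ...] = ()


def count_transitions(
    trajectories: Trajectory | Iterable[Trajectory], cycle: PermeationCycle
) -> TransitionCounts:
    """Tally N_ij, per-state dwell T_i and permeation events from trajectories.

    Accepts one trajectory or an iterable (counts and times are pooled; the
    trajectories must share a voltage). Truncated final segments contribute
    dwell time but no transition, the correct bookkeeping for censored
    exponential dwells.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    trajectories = list(trajectories)
    if not trajectories:
        raise EstimationError("no trajectories to count")
    voltages = {t.voltage for t in trajectories}
    if len(voltages) > 1:
        raise EstimationError(
            f"cannot pool trajectories at different voltages: {sorted(voltages)}"
        )

    labels = set(cycle.labels)
    n_ij: dict[TransitionKey, int] = {tr.key: 0 for tr in cycle.all_transitions()}
    dwell: dict[str, float] = {s: 0.0 for s in cycle.labels}
    total_time = 0.0
    n_perm = 0
    for traj in trajectories:
        for pos, s in enumerate(traj.states):
            if s not in labels:
                raise EstimationError(
                    f"unknown state label {s!r} at segment {pos} "
                    f"(cycle {cycle.name!r} defines {sorted(labels)})"
                )
        for s, dw in zip(traj.states, traj.dwells):
            dwell[s] += float(dw)
        for a, b in zip(traj.states, traj.states[1:]):
            key = (a, b)
            if key not in n_ij:
                n_ij[key] = 0  # observed but not in the declared cycle; keep the count
            n_ij[key] += 1
        total_time += traj.duration
        n_perm += traj.n_permeations
    return TransitionCounts(
        voltage=trajectories[0].voltage,
        n_ij=n_ij,
        dwell=dwell,
        total_time=total_time,
        n_permeations=n_perm,
    )


def estimate_rates(counts: TransitionCounts) -> RateEstimate:
    """k_ij = N_ij / T_i, with Poisson standard error k/sqrt(N).

    Identical to J_ij / P_i with J_ij = N_ij/total_time and P_i =
    T_i/total_time — the total time cancels exactly.
    """
    rates: dict[TransitionKey, float | None] = {}
    err: dict[TransitionKey, float | None] = {}
    for (i, j), n in counts.n_ij.items():
        t_i = counts.dwell.get(i, 0.0)
        if n == 0:
            rates[(i, j)] = None
            err[(i, j)] = None
            continue
        if t_i <= 0:
            raise EstimationError(
                f"corrupt counts: {n} transitions out of {i!r} but zero dwell time"
            )
        k = n / t_i
        rates[(i, j)] = k
        err[(i, j)] = k / math.sqrt(n)
    return RateEstimate(voltage=counts.voltage, rates=rates, stderr=err, counts=counts)


def current_from_events(
    n_permeations: int,
    total_time: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Current in pA from an event count: i = e * N / T_sim."""
    if n_permeations < 0:
        raise EstimationError(f"event count must be non-negative, got {n_permeations}")
    if not total_time > 0:
        raise EstimationError(f"total_time must be positive, got {total_time}")
    return (n_permeations / total_time) * constants.current_per_rate


def fit_voltage_dependence(
    estimates: Sequence[RateEstimate],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    weighted: bool = False,
) -> RateFit:
    """Fit ln k vs V per transition; d = slope * V_T, k0 = exp(intercept).

    Ordinary least squares on the log scale by default; ``weighted=True``
    weights points by sqrt(N_ij) (inverse relative Poisson error). Voltages
    with missing estimates are dropped; transitions with fewer than two
    usable points are reported under ``missing`` with a reason.
    """
    if not estimates:
        raise EstimationError("no rate estimates to fit")
    keys: list[TransitionKey] = []
    for est in estimates:
        for key in est.rates:
            if key not in keys:
                keys.append(key)

    fits: dict[TransitionKey, TransitionFit] = {}
    missing: dict[TransitionKey, str] = {}
    for key in keys:
        volts, lnk, wts = [], [], []
        for est in estimates:
            k = est.rates.get(key)
            if k is None:
                continue
            volts.append(est.voltage)
            lnk.append(math.log(k))
            wts.append(math.sqrt(est.counts.n_ij[key]))
        if len(volts) < 2:
            missing[key] = (
                f"only {len(volts)} voltage(s) with observed transitions; need >= 2"
            )
            continue
        v = np.array(volts)
        y = np.array(lnk)
        w = np.array(wts) if weighted else None
        slope, intercept = np.polyfit(v, y, 1, w=w)
        yhat = slope * v + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        fits[key] = TransitionFit(
            k0=float(np.exp(intercept)),
            d=float(slope * constants.thermal_voltage),
            r_squared=r2,
            n_voltages=len(volts),
        )
    volts_used = tuple(sorted({e.voltage for e in estimates}))
    return RateFit(fits=fits, missing=missing, voltages_used=volts_used)
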