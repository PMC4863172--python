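"""Cyclic Markov model of single-file ion permeation.

Permeation through a narrow pore is described as a cycle of ion-occupancy
states (e.g. S2 -> S2+1 -> S3 -> S1+2 -> S2): one traversal of the cycle
transports net one ion. Each transition rate depends exponentially on the
applied transmembrane voltage,

    k_ij(V) = k_ij(0) * exp(d_ij * e * V / (k_B * T)),

where k_ij(0) is the zero-voltage rate and d_ij the electrical distance —
the fraction of the applied field sensed by the underlying motion. The
module builds the generator matrix of the chain, solves its stationary
distribution, computes the net cycle flux, and converts flux to current.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import CycleError
from .iv_analysis import IVCurve, IVPoint

__all__ = [
    "State",
    "VoltageRate",
    "Transition",
    "PermeationCycle",
    "state_from_label",
    "rate_at_voltage",
    "build_rate_matrix",
    "steady_state",
    "cycle_flux",
    "model_iv_curve",
]

DELTA_E_SIGNS = ("positive", "near-zero", "negative")

_LABEL_RE = re.compile(r"^S(\d+)(?:\+(\d+))?$")


@dataclass(frozen=True)
class State:
    """One ion-occupancy configuration of the pore.

    ``label`` follows the S{n} / S{n}+{m} convention: n ions fully inside,
    optionally m more at the entrance.
    """

    label: str
    n_inside: int = 0
    has_entrance_ion: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise CycleError("state label must be non-empty")
        if self.n_inside < 0:
            raise CycleError(f"state {self.label!r}: n_inside must be >= 0")


def state_from_label(label: str) -> State:
    """Build a State, parsing n_inside/entrance metadata from an S{n}+{m} label."""
    m = _LABEL_RE.match(label)
    if m is None:
        return State(label=label)
    return State(
        label=label,
        n_inside=int(m.group(1)),
        has_entrance_ion=m.group(2) is not None and int(m.group(2)) > 0,
    )


@dataclass(frozen=True)
class VoltageRate:
    """Exponential voltage dependence of one transition: k(V) = k0*exp(d*V/V_T)."""

    k0: float  # ns^-1 at 0 mV
    d: float  # electrical distance, dimensionless; may be negative

    def __post_init__(self) -> None:
        if not (self.k0 > 0 and math.isfinite(self.k0)):
            raise CycleError(f"k0 must be positive and finite, got {self.k0}")
        if not math.isfinite(self.d):
            raise CycleError(f"d must be finite, got {self.d}")


@dataclass(frozen=True)
class Transition:
    from_state: str
    to_state: str
    rate: VoltageRate
    delta_E_sign: str | None = None  # sign of the energy change along the step

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise CycleError(f"self-transition {self.from_state!r} not allowed")
        if self.delta_E_sign is not None and self.delta_E_sign not in DELTA_E_SIGNS:
            raise CycleError(
                f"delta_E_sign must be one of {DELTA_E_SIGNS}, got {self.delta_E_sign!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.from_state, self.to_state)


@dataclass(frozen=True)
class PermeationCycle:
    """An ordered single cycle of occupancy states with voltage-dependent rates.

    Forward transitions connect consecutive states (last back to first).
    Backward transitions, when supplied, each reverse exactly one forward
    transition. ``permeation_transition`` designates the step whose firing
    counts one net transported ion.
    """

    name: str
    states: tuple[State, ...]
    transitions: tuple[Transition, ...]
    permeation_transition: tuple[str, str]
    backward_transitions: tuple[Transition, ...] = ()

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise CycleError(f"cycle {self.name!r}: duplicate state labels {labels}")
        if len(self.states) < 2:
            raise CycleError(f"cycle {self.name!r}: needs >= 2 states")
        n = len(self.states)
        if len(self.transitions) != n:
            raise CycleError(
                f"cycle {self.name!r}: expected {n} forward transitions (one per edge), "
                f"got {len(self.transitions)}"
            )
        for i, tr in enumerate(self.transitions):
            want = (labels[i], labels[(i + 1) % n])
            if tr.key != want:
                raise CycleError(
                    f"cycle {self.name!r}: forward transition {i} is "
                    f"{tr.from_state}->{tr.to_state}, expected {want[0]}->{want[1]} "
                    "(transitions must follow the state order, closing the cycle)"
                )
        forward_keys = {tr.key for tr in self.transitions}
        if tuple(self.permeation_transition) not in forward_keys:
            raise CycleError(
                f"cycle {self.name!r}: permeation_transition "
                f"{self.permeation_transition} is not a forward transition"
            )
        seen_back: set[tuple[str, str]] = set()
        for tr in self.backward_transitions:
            if (tr.to_state, tr.from_state) not in forward_keys:
                raise CycleError(
                    f"cycle {self.name!r}: backward transition {tr.from_state}->"
                    f"{tr.to_state} does not reverse any forward transition"
                )
            if tr.key in seen_back:
                raise CycleError(
                    f"cycle {self.name!r}: duplicate backward transition "
                    f"{tr.from_state}->{tr.to_state}"
                )
            seen_back.add(tr.key)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    @property
    def is_unidirectional(self) -> bool:
        return len(self.backward_transitions) == 0

    def state_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise CycleError(f"cycle {self.name!r}: unknown state label {label!r}") from None

    def all_transitions(self) -> tuple[Transition, ...]:
        return self.transitions + self.backward_transitions


def rate_at_voltage(
    rate: VoltageRate, voltage: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Evaluate k(V) = k0 * exp(d * V / V_T), with V in mV and V_T = k_B T/e."""
    if not math.isfinite(voltage):
        raise CycleError(f"voltage must be finite, got {voltage}")
    return rate.k0 * math.exp(rate.d * voltage / constants.thermal_voltage)


def build_rate_matrix(
    cycle: PermeationCycle,
    voltage: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Generator matrix Q of the chain at one voltage.

    Q[i, j] (i != j) is the i->j rate; diagonal entries make rows sum to
    zero. Transitions absent from the cycle contribute zero.
    """
    n = len(cycle.states)
    q = np.zeros((n, n))
    seen: set[tuple[str, str]] = set()
    for tr in cycle.all_transitions():
        if tr.key in seen:
            raise CycleError(f"duplicate transition {tr.from_state}->{tr.to_state}")
        seen.add(tr.key)
        i = cycle.state_index(tr.from_state)
        j = cycle.state_index(tr.to_state)
        q[i, j] = rate_at_voltage(tr.rate, voltage, constants)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def steady_state(
    cycle: PermeationCycle,
    voltage: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-10,
) -> np.ndarray:
    """Stationary occupancy distribution, ordered as ``cycle.states``.

    Solves pi Q = 0 via the null space of Q^T, normalized to sum 1. The chain
    must be irreducible (one-dimensional null space).
    """
    q = build_rate_matrix(cycle, voltage, constants)
    ns = scipy.linalg.null_space(q.T, rcond=tol)
    if ns.shape[1] != 1:
        raise CycleError(
            f"cycle {cycle.name!r}: generator at {voltage} mV is reducible or "
            f"degenerate (null space dimension {ns.shape[1]})"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -tol):
        raise CycleError(f"cycle {cycle.name!r}: negative stationary probability {pi}")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def cycle_flux(
    cycle: PermeationCycle,
    voltage: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Net stationary flux (ions/ns) through the permeation transition.

    J = P_i k_ij - P_j k_ji; the backward term vanishes for unidirectional
    cycles, where J reduces to the harmonic form [sum_i 1/k_i]^-1.
    """
    pi = steady_state(cycle, voltage, constants)
    src, dst = cycle.permeation_transition
    i, j = cycle.state_index(src), cycle.state_index(dst)
    fwd = next(tr for tr in cycle.transitions if tr.key == (src, dst))
    flux = pi[i] * rate_at_voltage(fwd.rate, voltage, constants)
    back = next((tr for tr in cycle.backward_transitions if tr.key == (dst, src)), None)
    if back is not None:
        flux -= pi[j] * rate_at_voltage(back.rate, voltage, constants)
    return float(flux)


def model_iv_curve(
    cycle: PermeationCycle,
    voltages: "list[float] | np.ndarray",
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> IVCurve:
    """Model-predicted i-V curve: current = cycle flux x e (in pA) per voltage."""
    voltages = sorted(float(v) for v in voltages)
    if not voltages:
        raise CycleError("model_iv_curve requires at least one voltage")
    points = [
        IVPoint(voltage=v, current=cycle_flux(cycle, v, constants) * constants.current_per_rate)
        for v in voltages
    ]
    return IVCurve(points=points, source="model")
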