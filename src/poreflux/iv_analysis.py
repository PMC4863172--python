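"""Current-voltage curve construction, shape classification and bottleneck analysis.

The shape of a single-pore i-V curve carries mechanistic information: a
sublinear (saturating) curve indicates a rate-limiting step that the applied
voltage cannot accelerate (an entropy-like bottleneck, e.g. the narrow phase
space for exchanging an entrance water with an incoming ion), while a
superlinear curve indicates an energy-like barrier (e.g. ion-ion repulsion
during knock-on) that the field actively lowers. The discriminator at the
level of fitted kinetics is the electrical distance d of the slowest step:
d below a small cut (0.025 by default) or negative means voltage-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import AnalysisError

__all__ = [
    "IVPoint",
    "IVCurve",
    "AnalysisConfig",
    "FluctuatingVoltageRecord",
    "ShapeResult",
    "RateLimitingStep",
    "FluctuatingIVResult",
    "classify_shape",
    "rate_limiting_step",
    "classify_bottleneck",
    "diffusion_limit",
    "iv_from_fluctuating_voltage",
]

SHAPE_LABELS = ("sublinear", "superlinear", "linear", "mixed/undetermined")

#: d at or above this value marks a voltage-accelerated (energy-like) step.
DEFAULT_BOTTLENECK_THRESHOLD = 0.025


@dataclass(frozen=True)
class IVPoint:
    voltage: float  # mV
    current: float  # pA
    n_events: int | None = None
    total_time: float | None = None  # ns


@dataclass
class IVCurve:
    """Voltage/current pairs with provenance and optional shape label."""

    points: list[IVPoint]
    source: str = "model"  # "model" or "events"
    shape: str | None = None
    shape_statistic: float | None = None

    def __post_init__(self) -> None:
        v = self.voltages
        if len(v) == 0:
            raise AnalysisError("IVCurve requires at least one point")
        if np.any(np.diff(v) <= 0):
            raise AnalysisError("IVCurve voltages must be strictly increasing")
        if not np.all(np.isfinite(self.currents)):
            raise AnalysisError("IVCurve currents must be finite")

    @property
    def voltages(self) -> np.ndarray:
        return np.array([p.voltage for p in self.points], dtype=float)

    @property
    def currents(self) -> np.ndarray:
        return np.array([p.current for p in self.points], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voltage_mV": self.voltages,
                "current_pA": self.currents,
                "n_events": [p.n_events for p in self.points],
                "total_time_ns": [p.total_time for p in self.points],
            }
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for i-V analysis.

    n_appr is the rate (ns^-1) at which ions arrive at the pore entrance; it
    sets the diffusion-limited ceiling current e*N_appr. linearity_tolerance
    is the relative band around exact proportionality within which a curve is
    called linear.
    """

    n_appr: float | None = None
    linearity_tolerance: float = 0.05
    through_origin: bool = True

    def __post_init__(self) -> None:
        if self.n_appr is not None and not self.n_appr > 0:
            raise AnalysisError(f"n_appr must be positive, got {self.n_appr}")
        if not 0 < self.linearity_tolerance < 1:
            raise AnalysisError(
                f"linearity_tolerance must be in (0, 1), got {self.linearity_tolerance}"
            )


@dataclass(frozen=True)
class ShapeResult:
    label: str
    statistic: float  # signed mean relative deviation from the origin-anchored line


@dataclass(frozen=True)
class RateLimitingStep:
    transitions: tuple[tuple[str, str], ...]  # ties reported together
    rate: float  # ns^-1 at the queried voltage
    voltage: float  # mV
    partial: bool = False  # True when some cycle transitions lacked estimates
    missing: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class FluctuatingVoltageRecord:
    """A voltage trace paired with observed permeation-event times.

    The trace is a sampled time series (times ns, voltages mV), linearly
    interpolated between samples; every permeation time must fall inside the
    trace's time span.
    """

    times: np.ndarray  # ns, strictly increasing
    voltages: np.ndarray  # mV
    permeation_times: np.ndarray  # ns

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        ev = np.sort(np.asarray(self.permeation_times, dtype=float))
        if t.ndim != 1 or v.shape != t.shape:
            raise AnalysisError("trace times and voltages must be 1-D and equal length")
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise AnalysisError("trace times must be strictly increasing (>= 2 samples)")
        if len(ev) and (ev[0] < t[0] or ev[-1] > t[-1]):
            raise AnalysisError(
                f"permeation times [{ev[0]:g}, {ev[-1]:g}] fall outside the "
                f"voltage trace span [{t[0]:g}, {t[-1]:g}]"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "permeation_times", ev)


@dataclass(frozen=True)
class FluctuatingIVResult:
    curve: IVCurve
    mean_current: float  # pA, over all inter-event intervals
    mean_voltage: float  # mV
    intervals: pd.DataFrame  # per-interval t_start, t_end, dt_ns, voltage_mV, current_pA


def classify_shape(curve: IVCurve, config: AnalysisConfig | None = None) -> ShapeResult:
    """Classify an i-V curve as linear, sublinear, superlinear or mixed.

    Physical i-V curves pass through the origin, so the chord slope i/V is the
    natural curvature probe: a monotonically decreasing i/V means the curve
    bends below proportionality (sublinear, saturating), increasing i/V means
    it bends above (superlinear). Curves whose points all sit within
    ``linearity_tolerance`` of the best origin-anchored line are linear.

    Returns the label together with the signed mean relative deviation from
    the origin-anchored least-squares line, and stamps both onto ``curve``.
    """
    config = config or AnalysisConfig()
    v = curve.voltages
    i = curve.currents
    if len(v) < 3:
        raise AnalysisError(f"shape classification needs >= 3 points, got {len(v)}")
    if np.any(v <= 0):
        raise AnalysisError("shape classification requires positive voltages")

    slope = float(np.sum(v * i) / np.sum(v * v))  # origin-anchored least squares
    if slope == 0.0:
        raise AnalysisError("cannot classify a flat zero-current curve")
    deviations = (i - slope * v) / (slope * v)
    statistic = float(np.mean(deviations))

    ratios = i / v
    dr = np.diff(ratios)
    if np.max(np.abs(deviations)) <= config.linearity_tolerance:
        label = "linear"
    elif np.all(dr < 0):
        label = "sublinear"
    elif np.all(dr > 0):
        label = "superlinear"
    else:
        label = "mixed/undetermined"

    curve.shape = label
    curve.shape_statistic = statistic
    return ShapeResult(label=label, statistic=statistic)


def _rates_at_voltage(
    estimates, voltage: float, constants: PhysicalConstants
) -> tuple[dict[tuple[str, str], float], list[tuple[str, str]]]:
    """Extract per-transition rates at ``voltage`` from a RateEstimate or RateFit."""
    rates: dict[tuple[str, str], float] = {}
    missing: list[tuple[str, str]] = []
    if hasattr(estimates, "fits"):  # RateFit: evaluate k0*exp(d*V/V_T)
        for key, fit in estimates.fits.items():
            rates[key] = fit.k0 * math.exp(fit.d * voltage / constants.thermal_voltage)
        missing = sorted(getattr(estimates, "missing", {}))
    elif hasattr(estimates, "rates"):  # RateEstimate at a single voltage
        for key, k in estimates.rates.items():
            if k is None:
                missing.append(key)
            else:
                rates[key] = k
    else:
        raise AnalysisError(
            f"expected a RateEstimate or RateFit, got {type(estimates).__name__}"
        )
    return rates, missing


def rate_limiting_step(
    estimates,
    voltage: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    rel_tol: float = 1e-9,
) -> RateLimitingStep:
    """Identify the slowest transition at a given voltage.

    Accepts either a per-voltage ``RateEstimate`` or a fitted ``RateFit`` (in
    which case rates are evaluated from the exponential law at ``voltage``).
    Transitions tied with the minimum within ``rel_tol`` are reported as a set;
    transitions without estimates are flagged and the result marked partial.
    """
    rates, missing = _rates_at_voltage(estimates, voltage, constants)
    if not rates:
        raise AnalysisError("no transition rates available to rank")
    kmin = min(rates.values())
    ties = tuple(sorted(k for k, r in rates.items() if r <= kmin * (1 + rel_tol)))
    return RateLimitingStep(
        transitions=ties,
        rate=kmin,
        voltage=voltage,
        partial=bool(missing),
        missing=tuple(missing),
    )


def classify_bottleneck(
    fit,
    limiting: tuple[str, str] | RateLimitingStep,
    threshold: float = DEFAULT_BOTTLENECK_THRESHOLD,
) -> str:
    """Label the rate-limiting step entropy-like or energy-like from its d.

    d >= threshold: the step senses the field and is voltage-accelerated —
    an energy-like bottleneck (barrier lowered by the field, superlinear i-V).
    d < threshold (incl. negative): the step is voltage-insensitive — an
    entropy-like bottleneck (saturating, sublinear i-V). The boundary value
    itself classifies as energy-like.
    """
    if isinstance(limiting, RateLimitingStep):
        if len(limiting.transitions) != 1:
            raise AnalysisError(
                f"ambiguous rate-limiting step {limiting.transitions}; pass one transition"
            )
        key = limiting.transitions[0]
    else:
        key = tuple(limiting)
    if key not in fit.fits:
        raise AnalysisError(f"no fit available for transition {key[0]}->{key[1]}")
    d = fit.fits[key].d
    return "energy-like" if d >= threshold else "entropy-like"


def diffusion_limit(
    curve: IVCurve,
    config: AnalysisConfig,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Per-point transport efficiency relative to the diffusion-limited ceiling.

    The ceiling current is e*N_appr — every ion arriving at the entrance
    permeates. Efficiencies well below 1 mean permeation is not
    diffusion-limited (the pores studied here sit around 10%).
    """
    if config.n_appr is None:
        raise AnalysisError(
            "diffusion-limit comparison not computable: n_appr (ion approach rate) not provided"
        )
    ceiling = config.n_appr * constants.current_per_rate  # pA
    eff = curve.currents / ceiling
    return pd.DataFrame(
        {"voltage_mV": curve.voltages, "current_pA": curve.currents, "efficiency": eff}
    )


def _time_average_voltage(t: np.ndarray, v: np.ndarray, a: float, b: float) -> float:
    """Time average of the linearly interpolated trace over [a, b]."""
    if b <= a:
        raise AnalysisError(f"empty averaging interval [{a}, {b}]")
    inner = t[(t > a) & (t < b)]
    grid = np.concatenate(([a], inner, [b]))
    vals = np.interp(grid, t, v)
    return float(np.trapezoid(vals, grid) / (b - a))


def iv_from_fluctuating_voltage(
    record: FluctuatingVoltageRecord,
    bins: int | Sequence[float] = 5,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> FluctuatingIVResult:
    """Reconstruct an i-V curve from permeation events under a drifting voltage.

    Each inter-event interval yields one observation: the current is one
    elementary charge over the interval duration (e/dt, in pA) and the voltage
    is the time average of the trace over that interval. Observations are
    grouped into voltage bins (``bins`` equal-width bins over the observed
    range, or explicit edges) and per-bin means reported, together with the
    overall mean current and voltage.
    """
    ev = record.permeation_times
    if len(ev) < 2:
        raise AnalysisError(f"need >= 2 permeation events, got {len(ev)}")
    dt = np.diff(ev)
    if np.any(dt <= 0):
        raise AnalysisError("duplicate permeation times; intervals must have positive length")
    currents = constants.current_per_rate / dt  # pA
    volts = np.array(
        [
            _time_average_voltage(record.times, record.voltages, a, b)
            for a, b in zip(ev[:-1], ev[1:])
        ]
    )

    if np.isscalar(bins):
        nb = int(bins)
        lo, hi = float(volts.min()), float(volts.max())
        if hi <= lo:  # constant-voltage record: a single bin
            edges = np.array([lo - 0.5, lo + 0.5])
        else:
            edges = np.linspace(lo, hi, nb + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.clip(np.digitize(volts, edges) - 1, 0, len(edges) - 2)

    points = []
    for b in np.unique(idx):
        sel = idx == b
        points.append(
            IVPoint(
                voltage=float(volts[sel].mean()),
                current=float(currents[sel].mean()),
                n_events=int(sel.sum()),
                total_time=float(dt[sel].sum()),
            )
        )
    points.sort(key=lambda p: p.voltage)
    curve = IVCurve(points=points, source="events")
    intervals = pd.DataFrame(
        {
            "t_start_ns": ev[:-1],
            "t_end_ns": ev[1:],
            "dt_ns": dt,
            "voltage_mV": volts,
            "current_pA": currents,
        }
    )
    return FluctuatingIVResult(
        curve=curve,
        mean_current=float(currents.mean()),
        mean_voltage=float(volts.mean()),
        intervals=intervals,
    )
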