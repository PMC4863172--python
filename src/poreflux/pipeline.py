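"""End-to-end analysis chain: simulate -> count -> estimate -> fit -> classify.

Shared by the command-line ``analyze`` subcommand and by scripted use; runs
entirely in memory and is fully determined by the cycle, the ensemble design
and the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .estimation import (
    RateEstimate,
    RateFit,
    count_transitions,
    current_from_events,
    estimate_rates,
    fit_voltage_dependence,
)
from .iv_analysis import (
    DEFAULT_BOTTLENECK_THRESHOLD,
    AnalysisConfig,
    IVCurve,
    IVPoint,
    RateLimitingStep,
    ShapeResult,
    classify_bottleneck,
    classify_shape,
    rate_limiting_step,
)
from .kinetic_model import PermeationCycle
from .trajectories import SimulationConfig, simulate_ensemble

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the analysis chain produces for one cycle."""

    cycle: PermeationCycle
    sim_config: SimulationConfig
    estimates: list[RateEstimate]  # one per voltage, ascending
    fit: RateFit
    iv_curve: IVCurve  # event-derived
    shape: ShapeResult
    limiting: RateLimitingStep  # slowest step at 0 mV per the fitted law
    bottleneck: str  # "entropy-like" or "energy-like"


def run_pipeline(
    cycle: PermeationCycle,
    sim_config: SimulationConfig | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    analysis_config: AnalysisConfig | None = None,
    bottleneck_threshold: float = DEFAULT_BOTTLENECK_THRESHOLD,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full chain at the standard ensemble design.

    ``sim_config`` defaults to the reference design (100 x 10 ns at
    100/200/400/600/800 mV); ``seed`` overrides its master seed.
    """
    if sim_config is None:
        sim_config = SimulationConfig(cycle=cycle, seed=0 if seed is None else seed)
    elif seed is not None:
        sim_config = SimulationConfig(
            cycle=cycle,
            voltages=sim_config.voltages,
            n_trajectories=sim_config.n_trajectories,
            duration=sim_config.duration,
            seed=seed,
            initial_state=sim_config.initial_state,
            sampling_interval=sim_config.sampling_interval,
        )
    ensemble = simulate_ensemble(sim_config, constants)

    estimates: list[RateEstimate] = []
    points: list[IVPoint] = []
    for v in sorted(ensemble):
        trajs = ensemble[v]
        counts = count_transitions(trajs, cycle)
        estimates.append(estimate_rates(counts))
        points.append(
            IVPoint(
                voltage=v,
                current=current_from_events(counts.n_permeations, counts.total_time, constants),
                n_events=counts.n_permeations,
                total_time=counts.total_time,
            )
        )
    fit = fit_voltage_dependence(estimates, constants)
    iv_curve = IVCurve(points=points, source="events")
    shape = classify_shape(iv_curve, analysis_config)
    limiting = rate_limiting_step(fit, voltage=0.0, constants=constants)
    bottleneck = classify_bottleneck(fit, limiting.transitions[0], bottleneck_threshold)
    return PipelineResult(
        cycle=cycle,
        sim_config=sim_config,
        estimates=estimates,
        fit=fit,
        iv_curve=iv_curve,
        shape=shape,
        limiting=limiting,
        bottleneck=bottleneck,
    )
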