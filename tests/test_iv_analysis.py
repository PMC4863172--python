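"""i-V curve shape, rate-limiting step, bottleneck class, event-based reconstruction."""

import numpy as np
import pytest

import poreflux as pf
from poreflux.estimation import RateFit, TransitionFit
from poreflux.iv_analysis import FluctuatingVoltageRecord, IVPoint

from conftest import TABLE1


def curve(points):
    return pf.IVCurve(points=[IVPoint(voltage=v, current=i) for v, i in points])


def fit_from_table(name):
    return RateFit(
        fits={
            key: TransitionFit(k0=k0, d=d, r_squared=1.0, n_voltages=5)
            for key, (k0, d) in TABLE1[name].items()
        }
    )


class TestClassifyShape:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(100, 1.0), (200, 2.0), (400, 4.0)], "linear"),
            ([(100, 1.0), (200, 1.5), (400, 1.8)], "sublinear"),
            ([(100, 1.0), (200, 3.0), (400, 10.0)], "superlinear"),
            ([(100, 1.0), (200, 3.0), (300, 3.2), (400, 8.0)], "mixed/undetermined"),
        ],
    )
    def test_constructed_curves(self, points, expected):
        assert pf.classify_shape(curve(points)).label == expected

    @pytest.mark.parametrize("v_scale, i_scale", [(2.0, 1.0), (1.0, 5.0), (0.5, 3.0)])
    def test_invariant_under_axis_rescaling(self, v_scale, i_scale):
        base = [(100, 1.0), (200, 1.5), (400, 1.8)]
        scaled = [(v * v_scale, i * i_scale) for v, i in base]
        r0 = pf.classify_shape(curve(base))
        r1 = pf.classify_shape(curve(scaled))
        assert r1.label == r0.label
        assert r1.statistic == pytest.approx(r0.statistic, rel=1e-12)

    def test_needs_three_points(self):
        with pytest.raises(pf.AnalysisError, match=">= 3"):
            pf.classify_shape(curve([(100, 1.0), (200, 2.0)]))

    def test_unordered_voltages_rejected(self):
        with pytest.raises(pf.AnalysisError, match="strictly increasing"):
            pf.IVCurve(points=[IVPoint(200, 1.0), IVPoint(100, 2.0), IVPoint(300, 3.0)])

    def test_label_stamped_on_curve(self):
        c = curve([(100, 1.0), (200, 1.5), (400, 1.8)])
        pf.classify_shape(c)
        assert c.shape == "sublinear" and c.shape_statistic is not None


class TestRateLimitingStep:
    def test_ant5_slowest_at_zero_voltage(self):
        step = pf.rate_limiting_step(fit_from_table("ANT-5"), voltage=0.0)
        assert step.transitions == (("S2", "S2+1"),)
        assert step.rate == pytest.approx(8.5)

    def test_ant6_slowest_at_zero_voltage(self):
        step = pf.rate_limiting_step(fit_from_table("ANT-6"), voltage=0.0)
        assert step.transitions == (("S3+1", "S2+2"),)
        assert step.rate == pytest.approx(6.1)

    def test_ant6_bottleneck_rates_converge_at_high_voltage(self):
        """The entry step catches up with the slow knock-on step as V grows."""
        fit = fit_from_table("ANT-6")

        def ratio(v):
            rates, _ = pf.iv_analysis._rates_at_voltage(fit, v, pf.DEFAULT_CONSTANTS)
            return rates[("S3+1", "S2+2")] / rates[("S3", "S3+1")]

        assert ratio(0.0) < 0.1
        assert ratio(400.0) > ratio(0.0)
        assert 0.2 < ratio(400.0) < 1.0
        # above ~750 mV the two steps have effectively swapped roles
        assert ratio(800.0) > 1.0

    def test_single_voltage_estimates_accepted(self, ant5):
        trajs = [pf.simulate_trajectory(ant5, 100.0, 10.0, seed=s) for s in range(20)]
        est = pf.estimate_rates(pf.count_transitions(trajs, ant5))
        step = pf.rate_limiting_step(est, voltage=100.0)
        assert step.transitions == (("S2", "S2+1"),)
        assert not step.partial

    def test_missing_estimates_flag_partial_result(self):
        est = pf.RateEstimate(
            voltage=0.0,
            rates={("A", "B"): 1.0, ("B", "A"): None},
            stderr={("A", "B"): 0.1, ("B", "A"): None},
            counts=None,
        )
        step = pf.rate_limiting_step(est, voltage=0.0)
        assert step.partial and step.missing == (("B", "A"),)

    def test_ties_reported_as_set(self):
        fit = RateFit(
            fits={
                ("A", "B"): TransitionFit(2.0, 0.0, 1.0, 5),
                ("B", "A"): TransitionFit(2.0, 0.0, 1.0, 5),
            }
        )
        step = pf.rate_limiting_step(fit, voltage=0.0)
        assert set(step.transitions) == {("A", "B"), ("B", "A")}


class TestClassifyBottleneck:
    def test_ant5_limiting_step_is_entropy_like(self):
        fit = fit_from_table("ANT-5")
        assert pf.classify_bottleneck(fit, ("S2", "S2+1")) == "entropy-like"

    def test_ant6_limiting_step_is_energy_like(self):
        fit = fit_from_table("ANT-6")
        assert pf.classify_bottleneck(fit, ("S3+1", "S2+2")) == "energy-like"

    def test_threshold_boundary_is_energy_like(self):
        fit = RateFit(fits={("A", "B"): TransitionFit(1.0, 0.025, 1.0, 5)})
        assert pf.classify_bottleneck(fit, ("A", "B")) == "energy-like"

    def test_missing_fit_raises(self):
        fit = fit_from_table("ANT-5")
        with pytest.raises(pf.AnalysisError, match="no fit"):
            pf.classify_bottleneck(fit, ("X", "Y"))


class TestDiffusionLimit:
    def test_ceiling_current_efficiency_one(self):
        cfg = pf.AnalysisConfig(n_appr=4.494)
        ceiling = 4.494 * pf.DEFAULT_CONSTANTS.current_per_rate
        assert ceiling == pytest.approx(720.0, abs=0.5)
        c = curve([(100, ceiling), (200, 0.0), (400, 0.1 * ceiling)])
        eff = pf.diffusion_limit(c, cfg)
        assert eff["efficiency"].tolist() == pytest.approx([1.0, 0.0, 0.1])

    def test_missing_approach_rate_not_computable(self):
        c = curve([(100, 1.0), (200, 2.0), (400, 4.0)])
        with pytest.raises(pf.AnalysisError, match="n_appr"):
            pf.diffusion_limit(c, pf.AnalysisConfig())


class TestFluctuatingVoltage:
    def test_constant_trace_single_bin(self):
        rec = FluctuatingVoltageRecord(
            times=np.array([0.0, 20.0]),
            voltages=np.array([200.0, 200.0]),
            permeation_times=np.arange(0.0, 11.0),
        )
        res = pf.iv_from_fluctuating_voltage(rec)
        assert len(res.curve.points) == 1
        p = res.curve.points[0]
        assert p.voltage == pytest.approx(200.0)
        assert p.current == pytest.approx(160.218, abs=1e-3)
        # agrees with the event-count current over the same span
        assert res.mean_current == pytest.approx(
            pf.current_from_events(10, 10.0), rel=1e-12
        )

    def test_interval_current_is_charge_over_time(self):
        rec = FluctuatingVoltageRecord(
            times=np.array([0.0, 30.0]),
            voltages=np.array([250.0, 250.0]),
            permeation_times=np.array([1.0, 28.62]),
        )
        res = pf.iv_from_fluctuating_voltage(rec)
        assert res.mean_current == pytest.approx(5.80, abs=0.01)

    def test_event_order_irrelevant(self):
        t = np.linspace(0, 100, 101)
        v = 100 + 5 * t
        events = np.array([3.0, 11.0, 27.0, 40.0, 66.0, 90.0])
        rng = np.random.default_rng(0)
        shuffled = events.copy()
        rng.shuffle(shuffled)
        r1 = pf.iv_from_fluctuating_voltage(
            FluctuatingVoltageRecord(t, v, events), bins=3
        )
        r2 = pf.iv_from_fluctuating_voltage(
            FluctuatingVoltageRecord(t, v, shuffled), bins=3
        )
        assert r1.curve.voltages.tolist() == r2.curve.voltages.tolist()
        assert r1.curve.currents.tolist() == r2.curve.currents.tolist()

    def test_time_averaged_voltage_on_ramp(self):
        # linear ramp 0..100 mV over 0..10 ns; interval [2, 6] averages to 40 mV
        rec = FluctuatingVoltageRecord(
            times=np.array([0.0, 10.0]),
            voltages=np.array([0.0, 100.0]),
            permeation_times=np.array([2.0, 6.0]),
        )
        res = pf.iv_from_fluctuating_voltage(rec)
        assert res.mean_voltage == pytest.approx(40.0, rel=1e-12)

    def test_events_outside_trace_rejected(self):
        with pytest.raises(pf.AnalysisError, match="outside"):
            FluctuatingVoltageRecord(
                times=np.array([0.0, 10.0]),
                voltages=np.array([100.0, 100.0]),
                permeation_times=np.array([5.0, 12.0]),
            )

    def test_needs_two_events(self):
        rec = FluctuatingVoltageRecord(
            times=np.array([0.0, 10.0]),
            voltages=np.array([100.0, 100.0]),
            permeation_times=np.array([5.0]),
        )
        with pytest.raises(pf.AnalysisError, match=">= 2"):
            pf.iv_from_fluctuating_voltage(rec)
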