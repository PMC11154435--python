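"""The synthetic-data generator: determinism, closed-form expectations,
pad-retention model, traces and time courses."""

import math

import numpy as np
import pytest

from spikeval import (
    Arm,
    DesignSpec,
    SetLabel,
    ValidationStudy,
    default_design,
    pad_retained_fraction,
    paper_like_truth,
    signal_to_noise,
    simulate_experiment,
    simulate_tea_timecourse,
    simulate_trace,
)
from spikeval.nd import is_nd
from spikeval.simulate import TruthParams


def small_design(**kwargs):
    base = dict(
        analytes=("COC", "CUS", "EME", "COC-d3"),
        arms=(Arm.DROOLING,),
        sets=(SetLabel.A_NEAT, SetLabel.B_POST_SPIKE, SetLabel.C_PRE_SPIKE),
        levels=(10.0, 50.0),
        replicates=3,
        days=1,
    )
    base.update(kwargs)
    return DesignSpec(**base)


class TestPadRetention:
    def test_logistic_center_is_half(self, truth):
        assert pad_retained_fraction(truth.pad_retention_midpoint_logP, truth) == pytest.approx(0.5)

    def test_zero_steepness_is_flat_half(self, truth):
        flat = truth.with_(pad_retention_steepness=0.0)
        for logp in (-0.23, 0.72, 2.6, 2.7):
            assert pad_retained_fraction(logp, flat) == pytest.approx(0.5)

    def test_strictly_decreasing_in_logp(self, truth):
        grid = np.linspace(-1.0, 3.5, 40)
        vals = [pad_retained_fraction(x, truth) for x in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        # polar analytes retained more than hydrophobic ones
        assert pad_retained_fraction(-0.23, truth) > pad_retained_fraction(2.6, truth)

    def test_infinite_logp_rejected(self, truth):
        with pytest.raises(ValueError):
            pad_retained_fraction(math.inf, truth)


class TestSimulateExperiment:
    def test_fixed_seed_is_bitwise_deterministic(self, truth):
        t1, _ = simulate_experiment(truth, small_design(), seed=11)
        t2, _ = simulate_experiment(truth, small_design(), seed=11)
        assert [(r.analyte, r.condition.key, r.area, r.is_area) for r in t1] == [
            (r.analyte, r.condition.key, r.area, r.is_area) for r in t2
        ]

    def test_noise_free_closed_form_me_re_ra(self):
        truth = paper_like_truth().with_(
            injection_cv=0.0,
            enhancement_cv=0.0,
            buffer_interference_censor=0.0,
            matrix_enhancement_mean={"COC": 1.3, "COC-d3": 1.3},
            extraction_efficiency={"COC": 0.5, "COC-d3": 0.5},
        )
        table, _ = simulate_experiment(truth, small_design(analytes=("COC", "COC-d3")), seed=0)
        res = ValidationStudy(table).fit()
        assert res.metric("ME", "COC", "drooling", 10.0) == pytest.approx(30.0)
        assert res.metric("RE", "COC", "drooling", 10.0) == pytest.approx(50.0)
        assert res.metric("RA", "COC", "drooling", 10.0) == pytest.approx(65.0)

    def test_perfect_is_coupling_compensates_exactly(self):
        truth = paper_like_truth().with_(
            injection_cv=0.0, enhancement_cv=0.0, buffer_interference_censor=0.0, is_coupling=1.0
        )
        table, _ = simulate_experiment(truth, small_design(analytes=("COC", "COC-d3")), seed=0)
        res = ValidationStudy(table).fit()
        assert res.metric("ME_n", "COC", "drooling", 10.0) == pytest.approx(0.0, abs=1e-9)
        assert res.metric("RE_n", "COC", "drooling", 10.0) == pytest.approx(100.0)

    def test_expectation_correctness_over_many_injections(self):
        """Mean simulated area matches the closed-form expectation within
        3 standard errors for every set."""
        truth = paper_like_truth().with_(
            matrix_enhancement_mean={"COC": 1.4, "COC-d3": 1.4},
            extraction_efficiency={"COC": 0.6, "COC-d3": 0.6},
            buffer_interference_censor=0.0,
        )
        n = 2000
        design = small_design(analytes=("COC", "COC-d3"), levels=(10.0,), replicates=n)
        table, _ = simulate_experiment(truth, design, seed=3)
        rf_c = truth.response_factor["COC"] * 10.0
        expected = {
            SetLabel.A_NEAT: rf_c,
            SetLabel.B_POST_SPIKE: rf_c * 1.4,
            SetLabel.C_PRE_SPIKE: rf_c * 1.4 * 0.6,
        }
        for set_label, mean_expected in expected.items():
            areas = np.array(table.areas("COC", set_label, 10.0), dtype=float)
            se = areas.std(ddof=1) / math.sqrt(n)
            assert abs(areas.mean() - mean_expected) < 3 * se

    def test_quantisal_censoring_marks_polar_analytes_nd(self, truth):
        design = DesignSpec(
            analytes=("EME", "COC", "EME-d3", "COC-d3"),
            arms=(Arm.QUANTISAL,),
            sets=(SetLabel.A_NEAT, SetLabel.BQ_POST_SPIKE, SetLabel.CQ_PRE_SPIKE),
            levels=(10.0,),
        )
        table, _ = simulate_experiment(truth, design, seed=5)
        # polar EME is nearly fully pad-retained, so its pre-extraction
        # device-arm signal falls below the censor threshold
        assert all(is_nd(a) for a in table.areas("EME", SetLabel.CQ_PRE_SPIKE, 10.0))
        assert not any(is_nd(a) for a in table.areas("COC", SetLabel.CQ_PRE_SPIKE, 10.0))

    def test_truth_sidecar_carries_expected_statistics(self, truth):
        _, sidecar = simulate_experiment(truth, small_design(), seed=1)
        assert sidecar["expected"]["CUS"]["ME_pct"] == pytest.approx(100.0)
        assert sidecar["expected"]["COC"]["RE_pct"] == pytest.approx(45.0)
        assert sidecar["seed"] == 1


class TestParameterRecovery:
    def test_me_and_re_recovered_within_three_se_at_n6(self):
        """Full-design recovery: truth enhancement 1.5, efficiency 0.6,
        injection CV 10%, n = 6 -> ME near 50% and RE near 60%."""
        truth = paper_like_truth().with_(
            matrix_enhancement_mean={"COC": 1.5, "COC-d3": 1.5},
            extraction_efficiency={"COC": 0.6, "COC-d3": 0.6},
            injection_cv=10.0,
            enhancement_cv=10.0,
            buffer_interference_censor=0.0,
        )
        me_vals, re_vals = [], []
        for seed in range(30):
            table, _ = simulate_experiment(
                truth, small_design(analytes=("COC", "COC-d3"), replicates=6, levels=(10.0,)),
                seed=100 + seed,
            )
            res = ValidationStudy(table).fit()
            me_vals.append(res.metric("ME", "COC", "drooling", 10.0))
            re_vals.append(res.metric("RE", "COC", "drooling", 10.0))
        for vals, target in ((me_vals, 50.0), (re_vals, 60.0)):
            arr = np.array(vals)
            se = arr.std(ddof=1) / math.sqrt(len(arr))
            assert abs(arr.mean() - target) < 3 * se + 1e-9, (arr.mean(), target, se)


class TestSimulateTrace:
    def test_blank_trace_below_detection(self, truth):
        trace = simulate_trace(0.0, truth, seed=4)
        assert signal_to_noise(trace) < 3.0

    def test_linearity_of_expected_height(self, truth):
        t1 = simulate_trace(10.0, truth.with_(trace_noise_sd=1e-9), seed=4)
        t2 = simulate_trace(20.0, truth.with_(trace_noise_sd=1e-9), seed=4)
        peak1 = t1.intensities[slice(*t1.peak_window)].max() - t1.intensities[:100].mean()
        peak2 = t2.intensities[slice(*t2.peak_window)].max() - t2.intensities[:100].mean()
        assert peak2 == pytest.approx(2 * peak1, rel=1e-3)

    def test_sn_tracks_height_to_noise_ratio(self):
        """Monte-Carlo mean S/N for peak height 3x the noise SD is near 3
        (the max-over-window statistic biases it slightly upward)."""
        truth = paper_like_truth().with_(
            extraction_efficiency={}, matrix_enhancement_mean={}, trace_noise_sd=5.0,
            trace_height_per_conc=1.0,
        )
        sns = [signal_to_noise(simulate_trace(15.0, truth, seed=s)) for s in range(200)]
        assert np.mean(sns) == pytest.approx(3.0, abs=1.5)

    def test_device_arm_peak_attenuated_for_polar_analyte(self, truth):
        quiet = truth.with_(trace_noise_sd=1e-9)
        drool = simulate_trace(50.0, quiet, arm=Arm.DROOLING, analyte="EME", seed=1)
        device = simulate_trace(50.0, quiet, arm=Arm.QUANTISAL, analyte="EME", seed=1)
        assert device.intensities.max() < drool.intensities.max()


class TestTeaTimecourse:
    def test_zero_decay_rate_keeps_ratio_constant(self, truth):
        flat = truth.with_(decay_rate_per_min={"COC": 0.0}, t0_ratio={"COC": 5.0})
        points = simulate_tea_timecourse(flat, times=[60.0, 120.0])
        drool = [p.ratio for p in points if p.arm == "drooling"]
        assert drool[0] == pytest.approx(drool[1])

    def test_device_attenuation_censors_markers_before_coc(self, truth):
        points = simulate_tea_timecourse(truth, times=[60.0, 120.0], device_factor=0.10)
        at = {(p.arm, p.time_min, p.analyte): p.ratio for p in points}
        # device arm at 120 min: markers censored, COC still detected
        assert is_nd(at[("quantisal", 120.0, "HYG")])
        assert is_nd(at[("quantisal", 120.0, "CUS")])
        assert not is_nd(at[("quantisal", 120.0, "COC")])
        # drooling arm keeps the markers at 120 min
        assert not is_nd(at[("drooling", 120.0, "HYG")])

    def test_slowest_decay_is_last_to_go_nd(self, truth):
        slow = truth.with_(
            t0_ratio={"COC": 1.0, "CUS": 1.0},
            decay_rate_per_min={"COC": 0.01, "CUS": 0.05},
            detection_ratio=0.05,
        )
        points = simulate_tea_timecourse(slow, times=[0.0, 60.0, 120.0, 240.0, 300.0])
        last = {}
        for p in points:
            if p.arm == "drooling" and not is_nd(p.ratio):
                last[p.analyte] = max(last.get(p.analyte, 0.0), p.time_min)
        assert last["COC"] > last["CUS"]
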