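import numpy as np
import pytest

from csfdyn import ContractError
from csfdyn.csf_dynamics import (
    BrainWaterPair,
    DyeSeries,
    InfusionStep,
    InfusionStudy,
    brain_water_percent,
    compute_rout_step,
    compute_rout_study,
    compute_vp,
    dye_flow_rate,
    plateau_estimate,
    vp_timecourse,
)
from csfdyn.synthetic_data import (
    gen_dye_series,
    gen_infusion_study,
    gen_perfusion_run,
    gen_step_trace,
)


class TestRoutStep:
    def test_no_pressure_rise(self):
        assert compute_rout_step(3.4, 3.4, 5.0) == 0.0

    def test_printed_control_value(self):
        assert compute_rout_step(3.4, 5.6, 5.0) == pytest.approx(0.44)

    def test_rate_homogeneity(self):
        assert compute_rout_step(3.4, 5.6, 10.0) == pytest.approx(0.22)

    def test_nonpositive_rate_raises(self):
        with pytest.raises(ContractError):
            compute_rout_step(3.4, 5.6, 0.0)


class TestRoutStudy:
    def test_all_plateaus_at_baseline(self):
        study = InfusionStudy(icp_i=3.4, steps=[InfusionStep(r, 3.4) for r in (5, 10, 15, 20)])
        assert compute_rout_study(study).mean_rout == 0.0

    def test_single_step_reduces_to_step(self):
        study = InfusionStudy(icp_i=3.4, steps=[InfusionStep(5.0, 5.6)])
        res = compute_rout_study(study)
        assert res.mean_rout == pytest.approx(0.44)
        assert res.n_steps == 1

    def test_recovery_from_generator(self):
        study, true_rout = gen_infusion_study(0.67, plateau_noise_sd=0.2, seed=13)
        res = compute_rout_study(study)
        assert res.mean_rout == pytest.approx(true_rout, abs=0.05)

    def test_negative_step_flagged(self):
        study = InfusionStudy(icp_i=3.4, steps=[InfusionStep(5.0, 2.0)])
        res = compute_rout_study(study)
        assert res.per_step[0] < 0
        assert any("negative" in f for f in res.flags)

    def test_nonincreasing_rates_raise(self):
        with pytest.raises(ContractError):
            InfusionStudy(icp_i=3.4, steps=[InfusionStep(10.0, 5.0), InfusionStep(5.0, 6.0)])

    def test_empty_study_raises(self):
        with pytest.raises(ContractError):
            compute_rout_study(InfusionStudy(icp_i=3.4, steps=[]))


class TestPlateauEstimate:
    def test_settling_step(self):
        trace = gen_step_trace(start=3.4, plateau=7.0, duration=600.0, tau=40.0,
                               noise_sd=0.02, seed=5)
        est = plateau_estimate(trace, 0.0, 600.0)
        assert est.value == pytest.approx(7.0, abs=0.05)
        assert est.stable

    def test_constant_trace(self):
        trace = gen_step_trace(start=3.4, plateau=3.4, duration=600.0)
        est = plateau_estimate(trace, 0.0, 600.0)
        assert est.value == pytest.approx(3.4)
        assert est.stable

    def test_still_rising_flagged(self):
        trace = gen_step_trace(start=3.4, plateau=30.0, duration=600.0, tau=600.0)
        est = plateau_estimate(trace, 0.0, 600.0)
        assert not est.stable

    def test_window_outside_trace_raises(self):
        trace = gen_step_trace(start=3.4, plateau=7.0, duration=60.0)
        with pytest.raises(ContractError):
            plateau_estimate(trace, 0.0, 600.0)


class TestVp:
    def test_no_dilution(self):
        assert compute_vp(9.0, 1.0, 1.0) == 0.0

    def test_halving(self):
        assert compute_vp(9.0, 1.0, 0.5) == pytest.approx(9.0)

    def test_printed_hfd_value(self):
        assert compute_vp(9.0, 1.0, 0.64) == pytest.approx(5.0625)

    def test_nonpositive_co_raises(self):
        with pytest.raises(ContractError):
            compute_vp(9.0, 1.0, 0.0)

    def test_timecourse_constant(self):
        run, _ = gen_perfusion_run(9.0, ri=9.0, ci=1.0, cv=0.0, equilibration_tau_min=0.0, seed=0)
        res = vp_timecourse(run)
        assert res.vp == pytest.approx(9.0, abs=1e-9)

    def test_noisy_recovery(self):
        run, true_vp = gen_perfusion_run(5.1, cv=0.05, seed=17)
        res = vp_timecourse(run)
        assert res.vp == pytest.approx(true_vp, abs=0.4)

    def test_equilibration_window_excludes_bias(self):
        # early rising-Co samples inflate Vp; the steady window must exclude them
        run, true_vp = gen_perfusion_run(5.1, cv=0.0, equilibration_tau_min=8.0, seed=0)
        res = vp_timecourse(run)
        all_mean = float(np.mean(res.vp_per_sample))
        assert abs(res.vp - true_vp) < abs(all_mean - true_vp)
        assert res.vp == pytest.approx(true_vp, abs=0.2)

    def test_window_too_sparse_raises(self):
        run, _ = gen_perfusion_run(5.1, n_samples=3, dt_min=40.0, steady_window=30.0, seed=0)
        with pytest.raises(ContractError):
            vp_timecourse(run)


class TestDyeFlow:
    def test_exact_line(self):
        t = np.arange(0.0, 5.5, 0.5)
        series = DyeSeries(t=t, intensity_norm=1.0 + 0.24 * t)
        res = dye_flow_rate(series)
        assert res.slope == pytest.approx(0.24, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_series(self):
        t = np.arange(0.0, 5.5, 0.5)
        series = DyeSeries(t=t, intensity_norm=np.ones_like(t))
        assert dye_flow_rate(series).slope == 0.0

    def test_noisy_recovery(self):
        series, slope = gen_dye_series(0.13, noise_sd=0.02, seed=23)
        res = dye_flow_rate(series)
        assert res.slope == pytest.approx(slope, abs=0.03)

    def test_too_few_points_raises(self):
        series = DyeSeries(t=np.array([0.0, 1.0, 2.0]), intensity_norm=np.array([1.0, 1.1, 1.2]))
        with pytest.raises(ContractError):
            dye_flow_rate(series, window=(0.0, 3.0))

    def test_unnormalized_series_rejected(self):
        with pytest.raises(ContractError):
            DyeSeries(t=np.array([0.0, 1.0]), intensity_norm=np.array([2.0, 2.2]))


class TestBrainWater:
    def test_printed_hfd_value(self):
        assert brain_water_percent(BrainWaterPair(2.000, 0.448)) == pytest.approx(77.6)

    def test_half(self):
        assert brain_water_percent(BrainWaterPair(1.0, 0.5)) == pytest.approx(50.0)

    def test_printed_testosterone_value(self):
        assert brain_water_percent(BrainWaterPair(2.0, 0.430)) == pytest.approx(78.5)

    def test_dry_above_wet_raises(self):
        with pytest.raises(ContractError):
            BrainWaterPair(1.0, 1.2)


def test_rout_recovery_grid():
    # median absolute recovery error < 10% over the true-parameter grid
    errors = []
    for i, true_rout in enumerate(np.linspace(0.2, 0.8, 7)):
        for seed in range(10):
            study, _ = gen_infusion_study(true_rout, plateau_noise_sd=0.2, seed=100 * i + seed)
            errors.append(abs(compute_rout_study(study).mean_rout - true_rout) / true_rout)
    assert np.median(errors) < 0.10


def test_vp_recovery_grid():
    errors = []
    for i, true_vp in enumerate(np.linspace(2.0, 8.0, 7)):
        for seed in range(10):
            run, _ = gen_perfusion_run(true_vp, cv=0.05, seed=200 * i + seed)
            errors.append(abs(vp_timecourse(run).vp - true_vp) / true_vp)
    assert np.median(errors) < 0.10
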