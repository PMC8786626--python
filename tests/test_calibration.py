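"""Calibration objectives and the alternating three-criteria fit."""

import numpy as np
import pandas as pd
import pytest

from ampkmtor.calibration import (
    AMPK_STAGE_PARAMS,
    CalibrationTarget,
    ampk_activator_levels,
    clamped_ampk_ratio,
    evaluate_losses,
    fit,
    objective_activator,
    objective_ampk_response,
    objective_timecourse,
)
from ampkmtor.synthetic import (
    make_activator_target,
    make_dose_response_target,
    make_oscillation_target,
)


@pytest.fixture(scope="module")
def osc_target(baseline):
    return make_oscillation_target(
        baseline, times=np.arange(420.0, 500.0, 4.0), noise_sd=0.0, seed=0
    ).target


class TestTargets:
    def test_nonpositive_weight_rejected(self):
        obs = pd.DataFrame({"activation": [0.5], "value": [1.0], "weight": [0.0]})
        with pytest.raises(ValueError, match="weight"):
            CalibrationTarget("dose_response", obs)

    def test_activation_outside_range_rejected(self):
        obs = pd.DataFrame({"activation": [0.05], "value": [1.0]})
        with pytest.raises(ValueError, match="activation"):
            CalibrationTarget("dose_response", obs)

    def test_csv_round_trip(self, tmp_path):
        obs = pd.DataFrame({"activation": [0.1, 0.5], "value": [2.0, 1.0],
                            "weight": [1.0, 2.0]})
        t = CalibrationTarget("dose_response", obs)
        t.to_csv(tmp_path / "t.csv")
        back = CalibrationTarget.from_csv(tmp_path / "t.csv")
        assert back.kind == "dose_response"
        pd.testing.assert_frame_equal(back.observations, t.observations)


class TestTimecourse:
    def test_self_consistency_zero_loss(self, baseline, osc_target):
        assert objective_timecourse(baseline, osc_target) == pytest.approx(0.0, abs=1e-4)

    def test_discriminates_perturbed_rates(self, baseline, osc_target):
        worse = baseline.replace(K_mTORC1_by_pAKT=2.0 * baseline["K_mTORC1_by_pAKT"])
        assert objective_timecourse(worse, osc_target) > 1e-2

    def test_loss_equals_hand_summed_wls(self, baseline):
        """Five-point target with synthetic values: the objective equals
        sum(w * (pred - obs)^2) with predictions interpolated by hand."""
        from ampkmtor.simulate import solve

        times = np.array([410.0, 430.0, 450.0, 470.0, 490.0])
        obs = pd.DataFrame({
            "time_h": times, "species": "pmTORC1",
            "value": [0.5, 0.9, 0.4, 0.7, 0.6],
            "weight": [1.0, 2.0, 1.0, 0.5, 1.0],
        })
        target = CalibrationTarget("timecourse", obs)
        res = solve(baseline.replace(V_IR=target.v_ir), t_end=500.0,
                    rtol=1e-6, atol=1e-8, conservation_check=False)
        pred = np.interp(times, res.t, res["pmTORC1"] / res["pmTORC1"].max())
        by_hand = float(np.sum(obs["weight"] * (pred - obs["value"]) ** 2))
        assert objective_timecourse(baseline, target) == pytest.approx(by_hand, rel=1e-6)


class TestDoseResponse:
    def test_full_ampk_activation_suppresses_mtorc1_ratio(self, baseline):
        ratios = [clamped_ampk_ratio(baseline, a) for a in (0.1, 1.0)]
        assert ratios[1] < ratios[0]

    def test_matched_target_near_zero_loss(self, baseline):
        ds = make_dose_response_target(
            baseline, activations=np.array([0.2, 0.6, 1.0]), noise_sd=0.0, seed=0)
        assert objective_ampk_response(baseline, ds.target) == pytest.approx(0.0, abs=1e-6)

    def test_loss_equals_hand_summed_wls(self, baseline):
        acts = np.array([0.1, 0.5, 1.0])
        obs = pd.DataFrame({"activation": acts, "value": [3.0, 1.0, 0.3],
                            "weight": [1.0, 1.0, 2.0]})
        target = CalibrationTarget("dose_response", obs)
        pred = np.array([clamped_ampk_ratio(baseline, a) for a in acts])
        by_hand = float(np.sum(obs["weight"] * (pred - obs["value"]) ** 2))
        assert objective_ampk_response(baseline, target) == pytest.approx(by_hand, rel=1e-6)


class TestActivator:
    def test_activator_raises_pakt_and_pampk(self, baseline):
        levels = ampk_activator_levels(baseline, 4.0)
        assert levels["treated"]["pAMPK"] > levels["control"]["pAMPK"]
        assert levels["treated"]["pAKT"] > levels["control"]["pAKT"]

    def test_identity_factor_leaves_levels_unchanged(self, baseline):
        levels = ampk_activator_levels(baseline, 1.0)
        assert levels["treated"]["pAKT"] == pytest.approx(levels["control"]["pAKT"], rel=1e-6)
        assert levels["treated"]["pAMPK"] == pytest.approx(levels["control"]["pAMPK"], rel=1e-6)

    def test_loss_equals_hand_summed_wls(self, baseline):
        levels = ampk_activator_levels(baseline, 4.0)
        obs = pd.DataFrame({
            "quantity": ["pAMPK", "pAKT"], "condition": ["treated", "treated"],
            "value": [50.0, 20.0], "weight": [1.0, 3.0],
        })
        target = CalibrationTarget("activation_level", obs, activation_factor=4.0)
        pred = np.array([levels["treated"]["pAMPK"], levels["treated"]["pAKT"]])
        by_hand = float(np.sum(obs["weight"] * (pred - obs["value"]) ** 2))
        assert objective_activator(baseline, target) == pytest.approx(by_hand, rel=1e-6)


class TestFit:
    def test_satisfied_targets_return_initial_params(self, baseline):
        ds = make_dose_response_target(
            baseline, activations=np.array([0.2, 0.6, 1.0]), noise_sd=0.0, seed=0)
        report = fit(baseline, [ds.target], max_rounds=1, free_timecourse=())
        assert report.converged
        assert report.params.to_dict() == baseline.to_dict()

    def test_empty_target_list_rejected(self, baseline):
        with pytest.raises(ValueError):
            fit(baseline, [])

    def test_infeasible_bounds_rejected(self, baseline):
        ds = make_dose_response_target(
            baseline, activations=np.array([0.2, 1.0]), noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="bounds"):
            fit(baseline.replace(K_AMPK=2 * baseline["K_AMPK"]), [ds.target],
                bounds={"K_AMPK": (1.0, 0.1)}, max_rounds=1, free_timecourse=())

    def test_recovers_ampk_constants_from_synthetic_data(self, baseline):
        """Parameter recovery: targets generated at the true parameters with
        2% noise; the fit is started from 2x-perturbed AMPK activation
        constants and must come back within 10% of the truth."""
        act = make_activator_target(baseline, activation_factor=4.0,
                                    noise_sd=0.02, seed=5)
        dose = make_dose_response_target(
            baseline, activations=np.array([0.2, 0.6, 1.0]), noise_sd=0.02, seed=6)
        start = baseline.replace(
            K_AMPK=2.0 * baseline["K_AMPK"],
            K_AMPK_by_SIRT1=2.0 * baseline["K_AMPK_by_SIRT1"],
        )
        report = fit(start, [act.target, dose.target], max_rounds=2,
                     free_timecourse=(), maxiter=30)
        for name in AMPK_STAGE_PARAMS:
            assert report.params[name] == pytest.approx(baseline[name], rel=0.10)
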