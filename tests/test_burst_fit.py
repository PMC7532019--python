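import warnings

import numpy as np
import pandas as pd
import pytest

from discflow.burst_fit import (
    FlowMeasurementSet,
    UnidentifiableModelError,
    compare_variants,
    fit_report,
    fit_threshold_model,
    fit_uncertainty,
    two_point_solve,
    with_uncertainty,
)
from discflow.perfusion_model import B_from_geometry, FlowModelSpec
from discflow.rotation import rpm_to_omega
from discflow.synthetic_data import CampaignDesign, simulate_campaign
from discflow.units_geometry import M3_PER_S_TO_UL_PER_H

UL = M3_PER_S_TO_UL_PER_H


def summary_set(speeds, means, sds, n=8):
    return FlowMeasurementSet.from_summary(
        pd.DataFrame(
            {
                "speed_rpm": speeds,
                "mean_ul_per_h": means,
                "sd_ul_per_h": sds,
                "n": [n] * len(speeds),
            }
        )
    )


class TestTwoPointSolve:
    def test_reference_measurement_pair(self):
        """Hand algebra for (100 rpm, 97 μl/h), (200 rpm, 445 μl/h):
        ω₀² = (Q₂ω₁² − Q₁ω₂²)/(Q₂ − Q₁) ≈ 17.96 rad²/s² (ω₀ ≈ 40.5 rpm),
        B = Q₁/(ω₁² − ω₀²) ≈ 1.058 μl/h per (rad/s)²."""
        sol = two_point_solve((100.0, 97.0), (200.0, 445.0))
        assert sol.omega0**2 == pytest.approx(17.96, rel=1e-3)
        assert sol.B_ul_per_h == pytest.approx(1.058, rel=1e-3)

    def test_exact_interpolation_of_both_points(self):
        sol = two_point_solve((100.0, 97.0), (200.0, 445.0))
        for rpm, q in [(100.0, 97.0), (200.0, 445.0)]:
            w2 = rpm_to_omega(rpm) ** 2
            assert sol.B_ul_per_h * (w2 - sol.omega0**2) == pytest.approx(
                q, rel=1e-12
            )

    def test_symmetric_in_point_order(self):
        a = two_point_solve((100.0, 97.0), (200.0, 445.0))
        b = two_point_solve((200.0, 445.0), (100.0, 97.0))
        assert a.B == pytest.approx(b.B, rel=1e-14)
        assert a.omega0 == pytest.approx(b.omega0, rel=1e-12)

    def test_pure_quadratic_has_no_threshold(self):
        # flow ratio 4 at speed ratio 2 → ω₀ = 0
        sol = two_point_solve((100.0, 50.0), (200.0, 200.0))
        assert sol.omega0 == 0.0

    def test_equal_speeds_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            two_point_solve((100.0, 97.0), (100.0, 98.0))

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(ValueError):
            two_point_solve((100.0, 0.0), (200.0, 445.0))


class TestMeasurementSet:
    def test_summary_consistent_with_replicates(self):
        rep = pd.DataFrame(
            {
                "speed_rpm": [50.0] * 4 + [100.0] * 4,
                "flow_ul_per_h": [9.0, 10.0, 11.0, 10.0, 95.0, 99.0, 97.0, 97.0],
            }
        )
        ms = FlowMeasurementSet.from_replicates(rep)
        row = ms.summary.set_index("speed_rpm").loc[100.0]
        assert row["mean_ul_per_h"] == pytest.approx(97.0)
        assert row["sd_ul_per_h"] == pytest.approx(
            np.std([95, 99, 97, 97], ddof=1)
        )
        assert row["n"] == 4

    def test_duplicate_speeds_rejected(self):
        df = pd.DataFrame(
            {
                "speed_rpm": [100.0, 100.0],
                "mean_ul_per_h": [97.0, 98.0],
                "sd_ul_per_h": [1.0, 1.0],
                "n": [8, 8],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            FlowMeasurementSet(df)

    def test_csv_round_trip_both_dialects(self, tmp_path, truth_97, geom, water37):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=5), geom, water37)
        long_path = tmp_path / "long.csv"
        summary_path = tmp_path / "summary.csv"
        campaign.to_long_csv(long_path)
        campaign.to_summary_csv(summary_path)
        from_long = FlowMeasurementSet.read_csv(long_path)
        from_summary = FlowMeasurementSet.read_csv(summary_path)
        pd.testing.assert_frame_equal(from_long.summary, campaign.summary)
        pd.testing.assert_frame_equal(from_summary.summary, campaign.summary)

    def test_unknown_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("rpm,flow\n100,97\n")
        with pytest.raises(ValueError, match="header"):
            FlowMeasurementSet.read_csv(p)


class TestFitThresholdModel:
    def test_noiseless_exact_recovery(self, truth_97, geom, water37):
        design = CampaignDesign(
            relative_sd=0.0, floor_sd_ul_per_h=0.0, truth=truth_97, seed=1
        )
        campaign = simulate_campaign(design, geom, water37)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_threshold_model(campaign, geom, water37)
        assert fit.spec.B == pytest.approx(truth_97.B, rel=1e-6)
        assert fit.spec.omega0 == pytest.approx(truth_97.omega0, rel=1e-6)
        assert fit.p_v_estimate == pytest.approx(97.0, rel=1e-6)

    def test_two_points_match_closed_form(self, geom, water37):
        data = summary_set([100.0, 200.0], [97.0, 445.0], [0.0, 0.0], n=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_threshold_model(data, geom, water37)
        sol = two_point_solve((100.0, 97.0), (200.0, 445.0))
        assert fit.spec.B == pytest.approx(sol.B, rel=1e-9)
        assert fit.spec.omega0 == pytest.approx(sol.omega0, rel=1e-9)

    def test_closed_form_equivalence_on_parameter_grid(self, geom, water37):
        """Weighted fitter ≡ two-point closed form on a 20×20 (B, ω₀) grid."""
        w1, w2 = rpm_to_omega(100.0), rpm_to_omega(200.0)
        for b_ulh in np.geomspace(0.2, 5.0, 20):
            for omega0 in np.linspace(0.0, 0.9 * w1, 20):
                q1 = b_ulh * (w1**2 - omega0**2)
                q2 = b_ulh * (w2**2 - omega0**2)
                data = summary_set([100.0, 200.0], [q1, q2], [0.0, 0.0], n=1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_threshold_model(data, geom, water37)
                sol = two_point_solve((100.0, q1), (200.0, q2))
                assert fit.spec.B == pytest.approx(sol.B, rel=1e-9)
                assert fit.spec.omega0**2 == pytest.approx(
                    sol.omega0**2, rel=1e-9, abs=1e-9
                )

    def test_all_zero_data_unidentifiable(self, geom, water37):
        data = summary_set([0.0, 50.0, 100.0], [0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        with pytest.raises(UnidentifiableModelError):
            fit_threshold_model(data, geom, water37)

    def test_partial_zero_scatter_rejected(self, geom, water37):
        data = summary_set([50.0, 100.0, 200.0], [10.0, 97.0, 445.0], [0.0, 5.0, 20.0])
        with pytest.raises(ValueError, match="zero standard error"):
            fit_threshold_model(data, geom, water37)

    def test_all_zero_scatter_warns_and_fits_unweighted(self, geom, water37):
        data = summary_set([100.0, 200.0], [97.0, 445.0], [0.0, 0.0])
        with pytest.warns(UserWarning, match="unweighted"):
            fit = fit_threshold_model(data, geom, water37)
        assert fit.spec.B > 0

    def test_without_geometry_reports_threshold_only(self, truth_97):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=2))
        fit = fit_threshold_model(campaign)
        assert fit.p_v_estimate is None
        assert fit.spec.omega0 > 0
        with pytest.raises(ValueError, match="radii"):
            fit_uncertainty(fit, campaign, n_boot=100, seed=0)

    def test_fixed_B_mode_uses_geometry_coefficient(self, truth_97, geom, water37):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=4), geom, water37)
        fit = fit_threshold_model(campaign, geom, water37, B_mode="fixed_from_geometry")
        assert fit.spec.B == pytest.approx(B_from_geometry(geom, water37), rel=1e-12)
        assert fit.B_mode == "fixed_from_geometry"

    def test_burst_estimate_flagged_by_weakest_input(self, truth_97, geom, water37):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=4), geom, water37)
        fit = fit_threshold_model(campaign, geom, water37)
        assert fit.provenance == "assumed"  # column radii are placeholders


class TestUncertainty:
    def test_seed_determinism(self, truth_97, geom, water37):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=6), geom, water37)
        fit = fit_threshold_model(campaign, geom, water37)
        a = fit_uncertainty(fit, campaign, n_boot=150, seed=42)
        b = fit_uncertainty(fit, campaign, n_boot=150, seed=42)
        assert a.se == b.se
        assert a.ci95 == b.ci95

    def test_noiseless_data_zero_standard_error(self, geom, water37):
        data = summary_set([100.0, 200.0], [97.0, 445.0], [0.0, 0.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_threshold_model(data, geom, water37)
            boot = fit_uncertainty(fit, data, n_boot=100, seed=0)
        assert boot.se == pytest.approx(0.0, abs=1e-9)
        assert boot.ci95[0] == pytest.approx(boot.ci95[1], abs=1e-9)

    def test_small_bootstrap_rejected(self, truth_97, geom, water37):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=6), geom, water37)
        fit = fit_threshold_model(campaign, geom, water37)
        with pytest.raises(ValueError, match="n_boot"):
            fit_uncertainty(fit, campaign, n_boot=50, seed=0)

    def test_with_uncertainty_attaches_interval(self, truth_97, geom, water37):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=6), geom, water37)
        fit = with_uncertainty(
            fit_threshold_model(campaign, geom, water37), campaign, n_boot=150, seed=1
        )
        lo, hi = fit.p_v_ci95
        assert lo < fit.p_v_estimate < hi
        assert fit.p_v_se > 0


class TestCompareVariants:
    def test_pinned_truth_ranks_pinned_first(self, truth_97, geom, water37):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=7), geom, water37)
        table = compare_variants(campaign, geom, water37)
        assert table.iloc[0]["variant"] == "combined_pinned"

    def test_unpinned_truth_collapses_threshold(self, geom, water37):
        truth = FlowModelSpec("combined", B=B_from_geometry(geom, water37))
        campaign = simulate_campaign(CampaignDesign(truth=truth, seed=7), geom, water37)
        fit = fit_threshold_model(campaign, geom, water37)
        # threshold collapses: no pinning detectable above the lowest tested speed
        assert fit.spec.omega0 < rpm_to_omega(50.0) / 2
        table = compare_variants(campaign, geom, water37).set_index("variant")
        pinned = table.loc["combined_pinned", "weighted_SSR"]
        combined = table.loc["combined", "weighted_SSR"]
        assert pinned <= combined  # nested family
        assert combined - pinned < 2 * len(campaign.summary)  # agree within noise

    def test_constant_model_is_worst_on_speed_dependent_data(
        self, truth_97, geom, water37
    ):
        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=8), geom, water37)
        table = compare_variants(campaign, geom, water37).set_index("variant")
        hydro = table.loc["hydrostatic_only", "weighted_SSR"]
        assert hydro >= table.loc["combined_pinned", "weighted_SSR"]
        assert hydro >= table.loc["centrifugal_only", "weighted_SSR"]


class TestFitReport:
    def test_report_is_json_serializable_with_expected_keys(
        self, truth_97, geom, water37
    ):
        import json

        campaign = simulate_campaign(CampaignDesign(truth=truth_97, seed=9), geom, water37)
        fit = with_uncertainty(
            fit_threshold_model(campaign, geom, water37), campaign, n_boot=150, seed=2
        )
        report = fit_report(fit)
        assert {
            "variant",
            "B",
            "omega0_rad_s",
            "p_v_Pa",
            "se_Pa",
            "ci95_Pa",
            "weighted_SSR",
            "r_squared",
            "provenance",
        } <= set(report)
        json.dumps(report)
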