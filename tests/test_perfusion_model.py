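import dataclasses
import io

import numpy as np
import pytest
import yaml

from discflow.hydraulics import channel_flow, hydrostatic_pressure
from discflow.perfusion_model import (
    VARIANTS,
    B_from_geometry,
    FlowModelSpec,
    burst_from_omega0,
    omega0_from_burst,
    predict_flow,
    spec_from_dict,
    spec_to_dict,
    speed_for_flow,
    two_point_spec,
)
from discflow.rotation import SpinState, rpm_to_omega
from discflow.units_geometry import M3_PER_S_TO_UL_PER_H

UL = M3_PER_S_TO_UL_PER_H


class TestSpecValidation:
    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            FlowModelSpec("banana")

    def test_nonpositive_B(self):
        with pytest.raises(ValueError, match="B"):
            FlowModelSpec("combined_pinned", B=0.0)

    def test_negative_threshold(self):
        with pytest.raises(ValueError, match="omega0"):
            FlowModelSpec("combined_pinned", B=1e-12, omega0=-1.0)

    def test_yaml_round_trip(self, calibrated_spec):
        text = yaml.safe_dump(spec_to_dict(calibrated_spec))
        again = spec_from_dict(yaml.safe_load(io.StringIO(text)))
        assert again == calibrated_spec


class TestPinnedModel:
    def test_zero_below_threshold(self, calibrated_spec):
        assert predict_flow(calibrated_spec, calibrated_spec.omega0 * 0.5) == 0.0

    def test_continuous_at_threshold(self, calibrated_spec):
        o0 = calibrated_spec.omega0
        assert predict_flow(calibrated_spec, o0) == 0.0
        just_above = predict_flow(calibrated_spec, o0 * (1 + 1e-9))
        assert 0 <= just_above * UL < 1e-4

    def test_two_point_calibration_interpolates_exactly(self, calibrated_spec):
        """The spec solved through (100 rpm, 97 μl/h) and (200 rpm, 445 μl/h)
        must reproduce both measurements to machine precision."""
        q100 = predict_flow(calibrated_spec, rpm_to_omega(100)) * UL
        q200 = predict_flow(calibrated_spec, rpm_to_omega(200)) * UL
        assert q100 == pytest.approx(97.0, rel=1e-12)
        assert q200 == pytest.approx(445.0, rel=1e-12)

    def test_combined_dominates_pinned_at_same_B(self, calibrated_spec, geom, water37):
        combined = FlowModelSpec("combined", B=calibrated_spec.B)
        omega = np.linspace(0, rpm_to_omega(300), 500)
        q_combined = predict_flow(combined, omega, geom, water37)
        q_pinned = predict_flow(calibrated_spec, omega)
        assert np.all(q_combined >= q_pinned)

    def test_pinned_equals_backpressure_reduced_channel_flow(self, geom, water37):
        """With B from the geometry and ω₀ from a burst pressure, the pinned
        model equals the channel flow under Δp_c + Δp_h − p_v for ω ≥ ω₀."""
        from discflow.hydraulics import centrifugal_pressure

        p_v = 120.0
        p_h = hydrostatic_pressure(water37, geom.head_height)
        omega0 = omega0_from_burst(p_v, p_h, water37, geom.r_inner, geom.r_outer)
        spec = FlowModelSpec(
            "combined_pinned", B=B_from_geometry(geom, water37), omega0=omega0
        )
        for rpm in np.linspace(45, 300, 12):
            state = SpinState(rpm)
            if state.omega < omega0:
                continue
            dp = (
                centrifugal_pressure(water37, state, geom.r_inner, geom.r_outer)
                + p_h
                - p_v
            )
            assert predict_flow(spec, state.omega) == pytest.approx(
                channel_flow(geom, water37, dp), rel=1e-10
            )


class TestMonotonicity:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_nondecreasing_in_speed(self, variant, calibrated_spec, geom, water37):
        spec = (
            calibrated_spec
            if variant == "combined_pinned"
            else FlowModelSpec(variant)
        )
        omega = np.linspace(0.0, rpm_to_omega(300), 2000)
        q = np.asarray(predict_flow(spec, omega, geom, water37))
        assert np.all(np.diff(q) >= 0)


class TestThresholdAlgebra:
    def test_threshold_vanishes_when_burst_below_head(self, water37):
        assert omega0_from_burst(50.0, 78.0, water37, 0.01, 0.045) == 0.0
        assert omega0_from_burst(78.0, 78.0, water37, 0.01, 0.045) == 0.0

    def test_reference_burst_pressure_threshold(self, geom, water37):
        # √((97 − 77.93)/(½·993.3·(0.045²−0.010²))) ≈ 4.466 rad/s ≈ 42.6 rpm
        p_h = hydrostatic_pressure(water37, geom.head_height)
        o0 = omega0_from_burst(97.0, p_h, water37, geom.r_inner, geom.r_outer)
        assert o0 == pytest.approx(4.466, rel=1e-3)
        assert FlowModelSpec("combined_pinned", B=1e-12, omega0=o0).omega0_rpm == pytest.approx(42.6, abs=0.1)

    def test_burst_threshold_round_trip(self, geom, water37):
        p_h = hydrostatic_pressure(water37, geom.head_height)
        for p_v in [80.0, 97.0, 140.0, 300.0]:
            o0 = omega0_from_burst(p_v, p_h, water37, geom.r_inner, geom.r_outer)
            back = burst_from_omega0(o0, p_h, water37, geom.r_inner, geom.r_outer)
            assert back == pytest.approx(p_v, rel=1e-14)

    def test_degenerate_radii_rejected(self, water37):
        with pytest.raises(ValueError):
            omega0_from_burst(100.0, 78.0, water37, 0.045, 0.045)


class TestGeometryCoefficient:
    def test_consistency_with_channel_flow(self, geom, water37):
        """B·ω² must equal the ω-dependent part of the combined prediction."""
        b = B_from_geometry(geom, water37)
        combined = FlowModelSpec("combined")
        for omega in (1.0, 10.0, 100.0):
            delta = predict_flow(combined, omega, geom, water37) - predict_flow(
                combined, 0.0, geom, water37
            )
            assert delta == pytest.approx(b * omega**2, rel=1e-12)

    def test_doubling_length_halves_B(self, geom, water37):
        longer = dataclasses.replace(geom, channel_length=2 * geom.channel_length)
        assert B_from_geometry(longer, water37) == pytest.approx(
            B_from_geometry(geom, water37) / 2, rel=1e-14
        )

    def test_positive_for_default_geometry(self, geom, water37):
        assert B_from_geometry(geom, water37) > 0


class TestSpeedForFlow:
    def test_calibrated_inversion_of_reference_points(self, calibrated_spec):
        assert speed_for_flow(calibrated_spec, 97.0 / UL) == pytest.approx(
            100.0, rel=1e-9
        )
        assert speed_for_flow(calibrated_spec, 445.0 / UL) == pytest.approx(
            200.0, rel=1e-9
        )

    def test_zero_target_canonical_zero_speed(self, calibrated_spec):
        assert speed_for_flow(calibrated_spec, 0.0) == 0.0

    def test_round_trip_over_target_grid(self, calibrated_spec, geom, water37):
        for q_ulh in np.linspace(5.0, 800.0, 15):
            rpm = speed_for_flow(calibrated_spec, q_ulh / UL)
            back = predict_flow(calibrated_spec, rpm_to_omega(rpm)) * UL
            assert back == pytest.approx(q_ulh, rel=1e-9)

    def test_positive_target_exceeds_threshold_speed(self, calibrated_spec):
        rpm = speed_for_flow(calibrated_spec, 1e-3 / UL)
        assert rpm_to_omega(rpm) > calibrated_spec.omega0

    def test_hydrostatic_only_unreachable(self, geom, water37):
        with pytest.raises(ValueError, match="unreachable"):
            speed_for_flow(FlowModelSpec("hydrostatic_only"), 97.0 / UL, geom, water37)

    def test_combined_below_hydrostatic_floor_unreachable(self, geom, water37):
        with pytest.raises(ValueError, match="unreachable"):
            speed_for_flow(FlowModelSpec("combined"), 1.0 / UL, geom, water37)


class TestTwoPointSpecHelper:
    def test_matches_reference_calibration(self, calibrated_spec):
        assert two_point_spec((100.0, 97.0), (200.0, 445.0)) == calibrated_spec
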