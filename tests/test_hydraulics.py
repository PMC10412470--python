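import math

import pytest
from hypothesis import given, settings, strategies as st

from fontanvep.geometry import DeviceGeometry
from fontanvep.hydraulics import (CalibrationError, FluidProperties, LossModel,
                                  calibrate_nozzle_cd, calibrate_pathway_losses,
                                  ejector_throat_pressure, interp_cd, jet_state,
                                  orifice_flow, pathway_loss)

FLUID = FluidProperties()


class TestOrificeFlow:
    def test_zero_driving_pressure_gives_zero_flow(self):
        assert orifice_flow(0.0, 2.5, 0.9) == 0.0

    def test_bernoulli_closed_form(self):
        # v = sqrt(2*55*133.322/1060) = 3.7196 m/s through A(2.5 mm)
        assert orifice_flow(55.0, 2.5, 1.0) == pytest.approx(1.0955, rel=1e-3)

    @given(dp=st.floats(0.01, 100), d=st.floats(0.5, 20), cd=st.floats(0.1, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetric_in_dp(self, dp, d, cd):
        assert orifice_flow(-dp, d, cd) == -orifice_flow(dp, d, cd)

    @given(d=st.floats(0.5, 20), cd=st.floats(0.1, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_scales_as_diameter_squared(self, d, cd):
        q1 = orifice_flow(30.0, d, cd)
        q2 = orifice_flow(30.0, 2 * d, cd)
        assert q2 == pytest.approx(4 * q1, rel=1e-12)

    @given(dp1=st.floats(0.1, 50), dp2=st.floats(0.1, 50))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_driving_pressure(self, dp1, dp2):
        lo, hi = sorted((dp1, dp2))
        if hi - lo < 1e-6:
            return
        assert orifice_flow(lo, 3.0, 0.8) < orifice_flow(hi, 3.0, 0.8)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            orifice_flow(10, -1.0, 0.9)
        with pytest.raises(ValueError):
            orifice_flow(10, 2.5, 1.5)


class TestJetState:
    def test_no_flow_gives_quiescent_jet(self):
        js = jet_state(0.0, 2.5)
        assert js.v_jet == 0.0 and js.Re == 0.0 and js.momentum_flux == 0.0

    def test_hand_arithmetic_velocity_and_reynolds(self):
        js = jet_state(1.0, 2.5)
        assert js.v_jet == pytest.approx(3.395, rel=1e-3)
        assert js.Re == pytest.approx(2571, rel=1e-3)

    def test_reynolds_near_transitional_at_calibrated_assist_flow(self, results):
        """The 2.5 mm nozzle jet runs at Re ~ 2600 under full assist."""
        from fontanvep.circulation import Mode
        state = results.solve(Mode.FULL_ASSIST)
        js = jet_state(state.Q_AoG, 2.5)
        assert js.Re == pytest.approx(2600, rel=0.15)


class TestPathwayLoss:
    def test_zero_flow_zero_loss(self):
        assert pathway_loss(0.0, 6.2, 12.0) == 0.0

    def test_hand_arithmetic(self):
        # v = 0.1857 m/s, q = K * rho/2 * v^2 = 113.3 Pa = 0.85 mmHg
        assert pathway_loss(1.26, 6.2, 12.0) == pytest.approx(0.85, rel=2e-3)

    @given(q=st.floats(0.05, 5.0), k=st.floats(0.0, 30.0))
    @settings(derandomize=True, max_examples=50)
    def test_quadratic_law(self, q, k):
        assert pathway_loss(2 * q, k, 12.0) == pytest.approx(
            4 * pathway_loss(q, k, 12.0), rel=1e-12)


def _losses(cd=1.0, eta=1.0, cd_ad=0.75):
    return LossModel(cd_nozzle={2.5: cd}, cd_ad=cd_ad,
                     k_path={"1-DO": {"ivc": 0.0, "svc": 0.0}}, eta_diffuser=eta)


class TestEjectorThroatPressure:
    GEOM = DeviceGeometry(D_N=2.5, D_T=12.0, D_AD=4.0)

    def test_jet_off_reduces_to_downstream_plus_pathway_loss(self, losses):
        """No jet: throat = outlet + pathway loss, up to the tiny passive
        residual of the device body (annulus acceleration)."""
        p = ejector_throat_pressure(0.0, 1.26, self.GEOM, 10.0, losses, FLUID)
        expected = 10.0 + pathway_loss(1.26, losses.k_for("1-DO", "ivc"), 12.0)
        assert p == pytest.approx(expected, abs=0.05)
        # the throat static pressure sits at most an annulus dynamic head
        # below the no-device value (flow acceleration, not jet suction)
        assert p <= expected

    def test_momentum_balance_magnitude(self):
        """1D mixing of a 0.9 L/min jet into 1.26 L/min IVC flow in a 12 mm
        throat depresses the throat by order 3 mmHg (eta=1, K=0)."""
        p = ejector_throat_pressure(0.9, 1.26, self.GEOM, 10.0, _losses(), FLUID)
        depression = 10.0 - p
        assert 1.5 < depression < 4.5

    def test_strictly_decreasing_in_jet_flow(self, losses):
        qs = [0.2 + 0.1 * i for i in range(15)]
        ps = [ejector_throat_pressure(q, 1.26, self.GEOM, 10.0, losses, FLUID)
              for q in qs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_depression_vanishes_for_very_wide_throat(self, losses):
        wide = DeviceGeometry(D_N=2.5, D_T=200.0, D_AD=4.0)
        p = ejector_throat_pressure(1.0, 1.26, wide, 10.0, losses, FLUID)
        no_jet = 10.0 + pathway_loss(2.26, losses.k_for("1-DO", "ivc"), 12.0)
        assert p >= no_jet - 1e-6  # no suction left

    def test_all_outputs_finite(self, losses):
        for q_j in (0.0, 0.5, 1.5):
            for q_ad in (-0.5, 0.0, 0.5):
                p = ejector_throat_pressure(q_j, 1.26, self.GEOM, 10.0, losses,
                                            FLUID, Q_AD=q_ad)
                assert math.isfinite(p)

    def test_invalid_geometry_rejected(self, losses):
        with pytest.raises(ValueError):
            ejector_throat_pressure(1.0, 1.26, DeviceGeometry(2.5, 5.0, 4.0),
                                    10.0, losses, FLUID)


class TestNozzleCdCalibration:
    def test_printed_anchor_pair(self, fixtures):
        cds = calibrate_nozzle_cd(fixtures.nozzle_flow_anchors)
        assert cds[1.5] == pytest.approx(0.80, abs=0.01)
        assert cds[3.0] == pytest.approx(0.99, abs=0.01)

    def test_round_trip_recovers_known_cd(self):
        q = orifice_flow(55.0, 2.0, 0.85)
        cds = calibrate_nozzle_cd({2.0: q})
        assert cds[2.0] == pytest.approx(0.85, abs=1e-9)

    def test_impossible_anchor_raises_naming_it(self):
        with pytest.raises(CalibrationError, match="D_N=2.0"):
            calibrate_nozzle_cd({2.0: 10.0})

    def test_interpolation_linear_and_clamped(self):
        cds = {1.5: 0.8, 3.0: 0.9}
        assert interp_cd(cds, 2.25) == pytest.approx(0.85)
        assert interp_cd(cds, 1.0) == 0.8
        assert interp_cd(cds, 4.0) == 0.9


class TestPathwayLossCalibration:
    def test_positive_pair_reproduces_fixture(self, fixtures):
        k = calibrate_pathway_losses(fixtures.table1, 1.26, 0.84)
        assert k["1-DO"]["ivc"] > 0 and k["1-DO"]["svc"] > 0
        p_ivc = 10.0 + pathway_loss(1.26, k["1-DO"]["ivc"], 12.0)
        p_svc = 10.0 + pathway_loss(0.84, k["1-DO"]["svc"], 12.0)
        assert p_ivc == pytest.approx(10.850, abs=1e-9)
        assert p_svc == pytest.approx(10.868, abs=1e-9)

    def test_fixture_at_outlet_pressure_gives_zero_k(self):
        k = calibrate_pathway_losses({"1-DO": (10.0, 10.0)}, 1.26, 0.84)
        assert k["1-DO"] == {"ivc": 0.0, "svc": 0.0}

    def test_patient_specific_less_dissipative_than_zero_offset(self, fixtures):
        k = calibrate_pathway_losses(fixtures.table1, 1.26, 0.84)
        assert k["PSC1"]["ivc"] < k["0-DO"]["ivc"]
        assert k["PSC1"]["svc"] < k["0-DO"]["svc"]

    def test_fixture_below_outlet_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_pathway_losses({"1-DO": (9.5, 10.5)}, 1.26, 0.84)


def test_loss_model_yaml_round_trip(losses):
    clone = LossModel.from_yaml(losses.to_yaml())
    assert clone.cd_nozzle == losses.cd_nozzle
    assert clone.k_path == losses.k_path
    assert clone.eta_diffuser == losses.eta_diffuser
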