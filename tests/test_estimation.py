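import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trunkload as tl

Z01 = tl.section_modulus(0.01)


def cal(gauge, E, theta):
    return tl.GaugeCalibration(gauge, E=E, theta_g=theta)


class TestDirection:
    def test_equal_compression_bisects_orthogonal_gauges(self):
        d = tl.direction(-50.0, -50.0, cal("td1", 10, 0), cal("td2", 10, 90), Z01, Z01)
        assert d == pytest.approx(45.0)

    def test_equal_tension_is_the_mirror(self):
        d = tl.direction(50.0, 50.0, cal("td1", 10, 0), cal("td2", 10, 90), Z01, Z01)
        assert d == pytest.approx(225.0)

    def test_round_trip_with_misaligned_unequal_gauges(self):
        # simulate a pull from 123 deg through the beam model, then invert
        geom = tl.WOOD_POLE
        layout = tl.GaugeLayout(
            theta_g={"td1": 10.0, "td2": 103.0, "bd1": 10.0, "bd2": 103.0},
            E={"td1": 11.2, "td2": 10.5, "bd1": 11.2, "bd2": 10.5},
        )
        sc = tl.LoadScenario([(0.7, 1.5)], 123.0)
        q = tl.strains_for(sc, layout, geom)
        cals = layout.as_calibrations()
        d = tl.direction(q.eps_td1, q.eps_td2, cals["td1"], cals["td2"], geom.Z_t, geom.Z_t)
        assert d == pytest.approx(123.0, abs=1e-9)

    def test_no_load_is_an_error(self):
        with pytest.raises(tl.NoLoadError):
            tl.direction(0.0, 0.0, cal("td1", 10, 0), cal("td2", 10, 90), Z01, Z01)

    def test_parallel_gauges_rejected(self):
        with pytest.raises(tl.IllConditionedError):
            tl.direction(-50.0, -50.0, cal("td1", 10, 20), cal("td2", 10, 200), Z01, Z01)

    @given(st.floats(min_value=0, max_value=359.999))
    @settings(derandomize=True, max_examples=100)
    def test_all_quadrants_resolved(self, D):
        """The arctangent's 180-degree ambiguity is broken correctly everywhere."""
        c1, c2 = cal("td1", 11.2, 10.0), cal("td2", 10.5, 103.0)
        M = 0.5
        e1 = -M * math.cos(math.radians(D - 10.0)) / (11.2e9 * Z01) * 1e6
        e2 = -M * math.cos(math.radians(D - 103.0)) / (10.5e9 * Z01) * 1e6
        assert tl.error_deg(tl.direction(e1, e2, c1, c2, Z01, Z01), D) < 1e-7


class TestMomentAtHeight:
    def test_single_gauge_hand_inversion(self):
        # c = -1 when D == theta + 180; eps = -100 ue, E = 10 GPa
        # M = eps*E*Z = 100e-6 * 10e9 * 9.8175e-8 = 0.098175 N*m... sign folds out
        c1 = cal("td1", 10.0, 0.0)
        c2 = cal("td2", 10.0, 90.0)  # at its node for D = 180
        M = tl.moment_at_height(-100.0, 0.0, c1, c2, Z01, Z01, D=0.0)
        assert M == pytest.approx(100e-6 * 10e9 * Z01, rel=1e-6)
        assert M == pytest.approx(0.098175, rel=1e-4)

    def test_zero_strains_zero_moment(self):
        M = tl.moment_at_height(0.0, 0.0, cal("td1", 10, 0), cal("td2", 10, 90), Z01, Z01, 45.0)
        assert M == 0.0

    def test_noiseless_simulation_consistency(self, geom, layout, true_cals):
        sc = tl.LoadScenario([(0.7, 2.0)], 200.0)
        q = tl.strains_for(sc, layout, geom)
        M = tl.moment_at_height(
            q.eps_td1, q.eps_td2, true_cals["td1"], true_cals["td2"],
            geom.Z_t, geom.Z_t, D=200.0,
        )
        assert M == pytest.approx(tl.moment_at(sc, geom.h_t), rel=1e-12)

    def test_both_gauges_at_node_rejected(self):
        c1, c2 = cal("td1", 10, 0.0), cal("td2", 10, 180.0)
        with pytest.raises(tl.IllConditionedError):
            tl.moment_at_height(1.0, 1.0, c1, c2, Z01, Z01, D=90.0)


class TestForceAndCentroid:
    def test_point_load_arithmetic(self):
        # 2.5 N at 1.2 m: M_t = 2.5*0.4 = 1.0, M_b = 2.5*0.6 = 1.5
        assert tl.force_amount(1.0, 1.5, 0.8, 0.6) == pytest.approx(2.5)
        assert tl.force_centroid(1.0, 1.5, 0.8, 0.6) == pytest.approx(1.2)

    def test_equal_moments_zero_force_undefined_centroid(self):
        assert tl.force_amount(1.0, 1.0, 0.8, 0.6) == 0.0
        with pytest.raises(tl.NoLoadError):
            tl.force_centroid(1.0, 1.0, 0.8, 0.6)

    def test_zero_upper_moment_centroid_at_upper_gauge(self):
        assert tl.force_centroid(0.0, 1.5, 0.8, 0.6) == pytest.approx(0.8)

    def test_degenerate_heights_rejected(self):
        with pytest.raises(tl.InvalidGeometryError):
            tl.force_amount(1.0, 1.5, 0.6, 0.6)


class TestApplyAssignment:
    def test_full_is_identity(self, true_cals):
        assert tl.apply_assignment(true_cals, "full") == dict(true_cals)

    def test_common_E_averages(self, true_cals):
        out = tl.apply_assignment(true_cals, "common_E")
        for g in tl.GAUGE_IDS:
            assert out[g].E == pytest.approx(10.825)  # mean of 11.2, 10.5, 10.6, 11.0
            assert out[g].theta_g == true_cals[g].theta_g

    def test_right_angle_pins_d2_to_d1_plus_90(self, true_cals):
        out = tl.apply_assignment(true_cals, "right_angle")
        assert out["td2"].theta_g == pytest.approx(249.6)
        assert out["bd2"].theta_g == pytest.approx(248.3)
        assert out["td1"].theta_g == true_cals["td1"].theta_g
        assert out["td2"].E == true_cals["td2"].E

    def test_combined_mode_does_both(self, true_cals):
        out = tl.apply_assignment(true_cals, "right_angle_common_E")
        assert out["td2"].theta_g == pytest.approx(249.6)
        assert out["td2"].E == pytest.approx(10.825)


class TestEstimateState:
    def test_noiseless_single_pull_recovery(self, geom, layout, true_cals):
        for D, F in [(0.0, 0.5), (123.0, 1.0), (271.0, 2.0)]:
            sc = tl.LoadScenario([(0.7, F)], D)
            q = tl.strains_for(sc, layout, geom)
            s = tl.estimate_state(q, true_cals, geom)
            assert s.F == pytest.approx(F, rel=1e-6)
            assert s.C == pytest.approx(0.7, rel=1e-6)
            assert tl.error_deg(s.D_t, D) < 1e-6
            assert tl.error_deg(s.D_b, D) < 1e-6

    def test_all_zero_quartet_flagged_no_load(self, geom, true_cals):
        s = tl.estimate_state(tl.StrainQuartet(0, 0, 0, 0), true_cals, geom)
        assert s.F == 0.0
        assert math.isnan(s.C) and math.isnan(s.D_t)
        assert "no_load" in s.flags

    def test_missing_calibration_names_gauge(self, geom, true_cals):
        cals = {g: c for g, c in true_cals.items() if g != "bd2"}
        with pytest.raises(tl.CalibrationError, match="bd2"):
            tl.estimate_state(tl.StrainQuartet(1, 1, 1, 1), cals, geom)

    def test_rotation_invariance(self, geom, layout):
        """Rotating gauges and load together shifts D and leaves F, C fixed."""
        offset = 77.0
        rotated = tl.GaugeLayout(
            theta_g={g: layout.theta_g[g] + offset for g in tl.GAUGE_IDS},
            E=layout.E,
        )
        sc = tl.LoadScenario([(0.7, 1.5)], 40.0)
        sc_rot = tl.LoadScenario([(0.7, 1.5)], 40.0 + offset)
        s = tl.estimate_state(tl.strains_for(sc, layout, geom),
                              layout.as_calibrations(), geom)
        s_rot = tl.estimate_state(tl.strains_for(sc_rot, rotated, geom),
                                  rotated.as_calibrations(), geom)
        assert s_rot.F == pytest.approx(s.F, rel=1e-9)
        assert s_rot.C == pytest.approx(s.C, rel=1e-9)
        assert tl.error_deg(s_rot.D_t, s.D_t + offset) < 1e-7

    def test_scale_equivariance(self, geom, layout, true_cals):
        sc = tl.LoadScenario([(0.7, 1.0)], 200.0)
        q = tl.strains_for(sc, layout, geom)
        k = 3.7
        q_scaled = tl.StrainQuartet(
            k * q.eps_td1, k * q.eps_td2, k * q.eps_bd1, k * q.eps_bd2
        )
        s, s_k = (tl.estimate_state(x, true_cals, geom) for x in (q, q_scaled))
        assert s_k.F == pytest.approx(k * s.F, rel=1e-9)
        assert s_k.M_t == pytest.approx(k * s.M_t, rel=1e-9)
        assert s_k.M_b == pytest.approx(k * s.M_b, rel=1e-9)
        assert s_k.C == pytest.approx(s.C, rel=1e-9)
        assert tl.error_deg(s_k.D_t, s.D_t) < 1e-9

    def test_full_equals_degraded_when_assumptions_hold(self, geom):
        """With exactly orthogonal gauges and one E, every mode agrees."""
        layout = tl.GaugeLayout(
            theta_g={"td1": 20.0, "td2": 110.0, "bd1": 20.0, "bd2": 110.0},
            E={g: 9.0 for g in tl.GAUGE_IDS},
        )
        q = tl.strains_for(tl.LoadScenario([(0.7, 1.2)], 300.0), layout, geom)
        cals = layout.as_calibrations()
        states = {
            m: tl.estimate_state(q, cals, geom, m)
            for m in tl.AssignmentMode
        }
        ref = states[tl.AssignmentMode.FULL]
        for s in states.values():
            assert s.F == pytest.approx(ref.F, rel=1e-12)
            assert s.C == pytest.approx(ref.C, rel=1e-12)
            assert s.D_t == pytest.approx(ref.D_t, abs=1e-9)

    def test_degraded_modes_are_worse_on_misaligned_specimen(self, geom, layout, true_cals):
        """With ~10 deg misalignment and heterogeneous E, the full method wins."""
        rng = np.random.default_rng(11)
        scenarios = tl.make_pulling_protocol(geom=geom, reps=1)
        noise = tl.NoiseModel(sigma=1.0, seed=11)
        errs = {m: {"F": [], "C": [], "D": []} for m in tl.AssignmentMode}
        for sc in scenarios:
            q = tl.strains_for(sc, layout, geom, noise=noise, rng=rng)
            for m in tl.AssignmentMode:
                s = tl.estimate_state(q, true_cals, geom, m)
                errs[m]["F"].append(tl.error_pct(sc.total_force, s.F))
                errs[m]["C"].append(tl.error_pct(sc.centroid(), s.C))
                errs[m]["D"].append(tl.error_deg(sc.direction, s.D_t))
        mean = {m: {k: np.mean(v) for k, v in d.items()} for m, d in errs.items()}
        full = mean[tl.AssignmentMode.FULL]
        assert mean[tl.AssignmentMode.RIGHT_ANGLE_COMMON_E]["F"] > full["F"]
        assert mean[tl.AssignmentMode.RIGHT_ANGLE_COMMON_E]["C"] > full["C"]
        assert mean[tl.AssignmentMode.COMMON_E]["F"] > full["F"]
        assert mean[tl.AssignmentMode.COMMON_E]["C"] > full["C"]
        assert mean[tl.AssignmentMode.RIGHT_ANGLE]["D"] > full["D"]
        assert mean[tl.AssignmentMode.RIGHT_ANGLE_COMMON_E]["D"] > full["D"]


class TestEstimateSeries:
    def test_series_frame_shape_and_flags(self, geom, layout, true_cals):
        sc = tl.LoadScenario([(0.7, 1.0)], 10.0)
        good = tl.strains_for(sc, layout, geom)
        quartets = [good, tl.StrainQuartet(0, 0, 0, 0), good]
        df = tl.estimate_series(quartets, true_cals, geom)
        assert list(df["flags"]) == ["", "no_load", ""]
        assert df.loc[0, "F_N"] == pytest.approx(1.0, rel=1e-9)
        assert df.loc[0, "C_minus_ht_m"] == pytest.approx(0.7 - geom.h_t, rel=1e-9)
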