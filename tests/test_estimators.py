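"""Phase model, the four estimators, error propagation, masking."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bsmap import estimators as est
from bsmap.estimators import (
    B1Map,
    BSPhaseModel,
    bs_phase,
    b1_from_flip_angle,
    dynamic_range,
    estimate_A,
    estimate_Bdouble,
    estimate_Bprime,
    estimate_C,
    flip_angle_from_b1,
    mask_voxels,
    phase_difference,
    propagate_error,
    unwrap_phase_diff,
)
from bsmap.pulses import ParameterError

FOUR_PEAKS = (2000.0, 2300.0, 2900.0, 3950.0)  # PCr/gamma/alpha/beta-ATP
# offsets from a pulse 2 kHz above PCr


class TestBSPhase:
    def test_zero_field_zero_phase(self, model_2khz):
        assert bs_phase(0.0, model_2khz) == 0.0

    def test_known_value_at_277hz(self, model_2khz):
        # pi * 277^2 * B-tilde / 2000 ~ 0.159 rad (9.1 degrees)
        phi = bs_phase(277.0, model_2khz)
        assert phi == pytest.approx(0.159, abs=0.001)
        assert math.degrees(phi) == pytest.approx(9.1, abs=0.1)

    def test_odd_in_offset_sign(self, btilde):
        up = bs_phase(300.0, BSPhaseModel(b_tilde=btilde, omega_rf=2000.0))
        dn = bs_phase(300.0, BSPhaseModel(b_tilde=btilde, omega_rf=-2000.0))
        assert up == -dn

    def test_linearity_warning_near_offset(self, btilde):
        with pytest.warns(UserWarning, match="linear"):
            bs_phase(900.0, BSPhaseModel(b_tilde=btilde, omega_rf=2000.0))

    def test_zero_offset_rejected(self, btilde):
        with pytest.raises(ParameterError):
            BSPhaseModel(b_tilde=btilde, omega_rf=0.0)


class TestPhaseDifference:
    @pytest.mark.parametrize("p1, p2, expected", [
        (0.3, 0.3, 0.0),
        (math.radians(170), math.radians(-170), math.radians(-20)),
        (math.pi / 2, 0.0, math.pi / 2),
    ])
    def test_principal_values(self, p1, p2, expected):
        assert phase_difference(p1, p2) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_always_in_principal_interval(self, p1, p2):
        d = phase_difference(p1, p2)
        assert -math.pi <= d <= math.pi

    def test_unwrap_adds_full_turns(self):
        assert unwrap_phase_diff(0.5, 1) == pytest.approx(0.5 + 2 * math.pi)
        assert unwrap_phase_diff(0.5, 0) == 0.5

    def test_unwrap_extends_dynamic_range_by_sqrt2(self, model_2khz):
        # one extra turn doubles the usable phase span -> sqrt(2) in B1
        assert dynamic_range(model_2khz, 2 * math.pi) == pytest.approx(
            math.sqrt(2) * dynamic_range(model_2khz, math.pi), rel=1e-12)


class TestWorkedExamples:
    """The two published phase differences and the dynamic-range limits."""

    @pytest.mark.parametrize("dphi_deg, expected_hz", [
        (55.6, 484.0),   # quadriceps central voxel
        (86.9, 605.0),   # mid-septal cardiac voxel
    ])
    def test_method_a_inversion(self, model_2khz, dphi_deg, expected_hz):
        got = estimate_A(math.radians(dphi_deg), model_2khz)
        assert got.valid
        assert got.gamma_b1 == pytest.approx(expected_hz, rel=0.01)

    @pytest.mark.parametrize("max_phase, expected_hz", [
        (math.pi, 873.0),
        (2 * math.pi, 1231.0),
    ])
    def test_dynamic_range(self, model_2khz, max_phase, expected_hz):
        assert dynamic_range(model_2khz, max_phase) == pytest.approx(
            expected_hz, rel=0.01)


class TestEstimators:
    def test_zero_phase_gives_zero_field(self, model_2khz):
        assert estimate_A(0.0, model_2khz).gamma_b1 == 0.0
        assert estimate_Bprime(0.2, 0.2, model_2khz).gamma_b1 == 0.0

    def test_negative_difference_flagged(self, model_2khz):
        res = estimate_A(-0.1, model_2khz)
        assert not res.valid
        assert res.reason == "negative_phase_diff"

    @pytest.mark.parametrize("g_true", [50.0, 277.0, 605.0])
    def test_all_strategies_round_trip_noiseless_phases(self, btilde, g_true):
        """Noiseless linear-model phases invert to the generating gamma-B1
        to 1e-10 relative for every strategy."""
        model = BSPhaseModel(b_tilde=btilde, omega_rf=2000.0)
        phi = lambda w: np.pi * g_true**2 * btilde / w
        a = estimate_A(phi(2000.0) - phi(-2000.0), model)
        bp = estimate_Bprime(phi(2000.0), 0.0, model)
        omegas = np.array(FOUR_PEAKS)
        bd = estimate_Bdouble([phi(w) for w in omegas], np.zeros(4), omegas, model)
        c = estimate_C([phi(w) for w in (-975.0, 975.0)], (-975.0, 975.0), model)
        for res in (a, bp, bd, c):
            assert res.valid
            assert res.gamma_b1 == pytest.approx(g_true, rel=1e-10)

    def test_bdouble_single_peak_reduces_to_bprime(self, model_2khz):
        r1 = estimate_Bdouble([0.21], [0.02], [2000.0], model_2khz)
        r2 = estimate_Bprime(0.21, 0.02, model_2khz)
        assert r1.gamma_b1 == pytest.approx(r2.gamma_b1, rel=1e-14)

    def test_bdouble_weights_scale_with_inverse_square_offset(self, btilde):
        # a peak at twice the offset contributes 1/4 the weight: check via
        # the pooled value against an explicit weighted mean
        model = BSPhaseModel(b_tilde=btilde, omega_rf=2000.0)
        omegas = np.array([2000.0, 4000.0])
        phis = np.array([0.20, 0.16])
        pooled = estimate_Bdouble(phis, [0.0, 0.0], omegas, model).gamma_b1
        per_peak = phis * omegas / (np.pi * btilde)
        w = omegas**-2.0
        expected = math.sqrt(np.sum(per_peak * w) / np.sum(w))
        assert pooled == pytest.approx(expected, rel=1e-12)

    def test_c_equal_phases_give_zero_field(self, model_2khz):
        res = estimate_C([0.4, 0.4], (1500.0, 2500.0), model_2khz)
        assert res.valid
        assert res.gamma_b1 == 0.0

    def test_c_rejects_equal_offsets(self, model_2khz):
        with pytest.raises(ParameterError):
            estimate_C([0.1, 0.2], (2000.0, 2000.0), model_2khz)

    @given(phi0=st.floats(-2.0, 2.0))
    def test_global_phase_offset_cancels(self, btilde, phi0):
        """A coil/B0 phase common to all arms and peaks must not move any
        estimator (Methods A/B difference it out; C uses pairwise diffs)."""
        model = BSPhaseModel(b_tilde=btilde, omega_rf=2000.0)
        g = 400.0
        phi = lambda w: np.pi * g**2 * btilde / w
        a0 = estimate_A((phi(2000.0) + phi0) - (phi(-2000.0) + phi0), model)
        b0 = estimate_Bprime(phi(2000.0) + phi0, phi0, model)
        c0 = estimate_C([phi(-975.0) + phi0, phi(975.0) + phi0],
                        (-975.0, 975.0), model)
        for res in (a0, b0, c0):
            assert res.gamma_b1 == pytest.approx(g, rel=1e-9)


class TestPropagation:
    def _numeric_oracle(self, fn, phases, sds, h=1e-6):
        grads = []
        for i in range(len(phases)):
            p = np.array(phases, dtype=float)
            p[i] += h
            up = fn(p)
            p[i] -= 2 * h
            dn = fn(p)
            grads.append((up - dn) / (2 * h))
        return math.sqrt(sum((g * s) ** 2 for g, s in zip(grads, sds)))

    def test_matches_independent_finite_difference_oracle(self, model_2khz, btilde):
        phases = [0.25, -0.25]
        sds = [0.02, 0.03]
        got = propagate_error("A", phases, sds, model_2khz)
        oracle = self._numeric_oracle(
            lambda p: estimate_A(p[0] - p[1], model_2khz).gamma_b1, phases, sds)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_matches_closed_form_for_method_a(self, model_2khz):
        got = propagate_error("A", [0.3, -0.3], [0.02, 0.02], model_2khz)
        closed = est.propagate_error_A_closed_form(0.3, -0.3, 0.02, 0.02,
                                                   model_2khz)
        assert got == pytest.approx(closed, rel=1e-6)

    def test_linear_in_phase_uncertainty(self, model_2khz):
        base = propagate_error("A", [0.3, -0.3], [0.01, 0.01], model_2khz)
        doubled = propagate_error("A", [0.3, -0.3], [0.02, 0.02], model_2khz)
        assert doubled == pytest.approx(2 * base, rel=1e-9)

    def test_method_c_pairwise_expression(self, btilde):
        model = BSPhaseModel(b_tilde=btilde, omega_rf=2000.0)
        phases = [0.30, 0.26, 0.21, 0.15]
        sds = [0.02, 0.025, 0.03, 0.04]
        got = propagate_error("C", phases, sds, model, omegas=FOUR_PEAKS)
        oracle = self._numeric_oracle(
            lambda p: estimate_C(p, FOUR_PEAKS, model).gamma_b1, phases, sds)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_zero_estimate_flags_infinite_sd(self, model_2khz):
        assert propagate_error("A", [0.1, 0.1], [0.01, 0.01],
                               model_2khz) == math.inf


class TestFlipAngleConversion:
    @pytest.mark.parametrize("gamma_b1, tp, theta", [
        (500.0, 1e-3, 180.0),
        (500.0, 300e-6, 54.0),
        (0.0, 1e-3, 0.0),
    ])
    def test_hard_pulse_relation(self, gamma_b1, tp, theta):
        assert flip_angle_from_b1(gamma_b1, tp) == pytest.approx(theta)

    def test_inverse(self):
        assert b1_from_flip_angle(54.0, 300e-6) == pytest.approx(500.0)


class TestMasking:
    def _map(self):
        values = np.array([[400.0, 500.0], [600.0, 700.0]])
        dphi = np.array([[30.0, -5.0], [40.0, 50.0]])
        crlb = np.array([[5.0, 5.0], [25.0, 5.0]])
        return B1Map(values=values, delta_phi_deg=dphi, crlb_phi_deg=crlb)

    def test_clean_map_passes_unchanged(self):
        m = B1Map(values=np.full((2, 2), 300.0),
                  delta_phi_deg=np.full((2, 2), 30.0),
                  crlb_phi_deg=np.full((2, 2), 1.0))
        masked = mask_voxels(m, crlb_threshold_deg=20.0)
        assert masked.included.all()
        assert np.array_equal(masked.values, m.values)

    def test_negative_phase_and_crlb_rules(self):
        masked = mask_voxels(self._map(), crlb_threshold_deg=20.0)
        assert masked.exclusion[0, 1] == 1    # negative phase difference
        assert masked.exclusion[1, 0] == 2    # CRLB above threshold
        assert masked.included[0, 0] and masked.included[1, 1]
        # original values retained
        assert masked.values[1, 0] == 600.0

    def test_survivor_count_matches_brute_force(self):
        rng = np.random.default_rng(7)
        crlb = rng.uniform(0.0, 30.0, size=(6, 6, 6))
        dphi = rng.uniform(-10.0, 170.0, size=(6, 6, 6))
        m = B1Map(values=np.ones((6, 6, 6)), delta_phi_deg=dphi,
                  crlb_phi_deg=crlb)
        masked = mask_voxels(m, crlb_threshold_deg=10.0)
        brute = int(np.sum((crlb <= 10.0) & (dphi >= 0)))
        assert int(masked.included.sum()) == brute

    def test_geometry_mask_applies(self):
        geom = np.array([[True, True], [False, True]])
        masked = mask_voxels(self._map(), crlb_threshold_deg=100.0,
                             geometry_mask=geom)
        assert masked.exclusion[1, 0] == 3
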