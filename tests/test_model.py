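"""Forward-model behavior: the closed-form Pi relation, steady states,
eigenvalue oracle and simulated transients."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myofiber import (
    ModelError,
    Protocol,
    SchemeParams,
    calibrate_activation_rate,
    eigen_rate,
    fit_transient,
    rate_matrix,
    relaxation_rate,
    simulate_transient,
    steady_state,
)

rates = st.floats(min_value=1.0, max_value=200.0)
positive = st.floats(min_value=0.5, max_value=100.0)


def random_params(draw_k1, draw_km1, draw_K2):
    return SchemeParams(k1=draw_k1, k_minus1=draw_km1, K2=draw_K2)


class TestRelaxationRate:
    def test_zero_pi_gives_k1_exactly(self, perfused_params):
        assert relaxation_rate(perfused_params, 0.0) == perfused_params.k1

    def test_half_saturation_at_K2(self, perfused_params):
        # at [Pi] = K2 the saturating term contributes k_minus1/2
        assert relaxation_rate(perfused_params, 39.4) == pytest.approx(47.75)

    def test_saturates_below_k1_plus_kminus1(self, ischemic_params):
        limit = ischemic_params.k1 + ischemic_params.k_minus1  # 49.6
        assert limit == pytest.approx(49.6)
        near = relaxation_rate(ischemic_params, 1e9)
        assert near == pytest.approx(limit, rel=1e-6)
        assert near < limit

    def test_strictly_increasing_in_pi(self, perfused_params):
        pis = np.linspace(0.0, 60.0, 40)
        kf = [relaxation_rate(perfused_params, p) for p in pis]
        assert np.all(np.diff(kf) > 0)

    def test_negative_pi_rejected(self, perfused_params):
        with pytest.raises(ValueError):
            relaxation_rate(perfused_params, -1.0)


class TestSteadyState:
    @settings(max_examples=30, derandomize=True)
    @given(k1=rates, km1=rates, K2=positive, pi=st.floats(0, 40),
           pca=st.floats(4.0, 9.0))
    def test_occupancies_form_distribution(self, k1, km1, K2, pi, pca):
        ss = steady_state(SchemeParams(k1=k1, k_minus1=km1, K2=K2), pca, pi)
        occ = ss.occupancies()
        assert np.all(occ >= 0)
        assert occ.sum() == pytest.approx(1.0, abs=1e-9)
        assert ss.force == pytest.approx(
            (ss.AMstar_ADP_Pi + ss.AMstar_ADP)
            * SchemeParams(k1=k1, k_minus1=km1, K2=K2).f_scale
        )

    def test_gate_closed_at_relaxing_ca(self, perfused_params):
        ss = steady_state(perfused_params, 9.0, 0.0)
        assert ss.force < 1e-3 * perfused_params.f_scale

    def test_force_decreases_with_pi(self, perfused_params):
        f0 = steady_state(perfused_params, 4.5, 0.0).force
        f30 = steady_state(perfused_params, 4.5, 30.0).force
        assert f30 < f0

    def test_force_increases_with_ca(self, perfused_params):
        forces = [steady_state(perfused_params, p, 0.0).force
                  for p in (8.0, 6.0, 5.5, 5.0, 4.5)]
        assert np.all(np.diff(forces) > 0)

    def test_degenerate_all_zero_rates(self):
        dead = SchemeParams(k1=0, k_minus1=0, g_act_max=0, g_off=0)
        with pytest.raises(ModelError):
            steady_state(dead, 4.5, 0.0)


class TestEigenRate:
    def test_matches_closed_form_across_pi(self, perfused_params):
        # oracle equivalence: slowest eigenvalue vs k1 + k-1*Pi/(K2+Pi)
        for pi in np.linspace(0.0, 30.0, 7):
            kf = relaxation_rate(perfused_params, pi)
            er = eigen_rate(perfused_params, 4.5, pi)
            assert abs(er - kf) / kf < 0.05

    def test_two_state_reduction_is_exact(self, perfused_params):
        # with no recycling the cycling pair relaxes at exactly k1 + k-1*phi
        p = replace(perfused_params, g_off=0.0, g_act_max=1e5)
        for pi in (0.0, 10.0, 30.0):
            phi = pi / (p.K2 + pi)
            assert eigen_rate(p, 4.0, pi) == pytest.approx(
                p.k1 + p.k_minus1 * phi, rel=1e-9
            )

    def test_no_reverse_rates_zero_pi_gives_k1(self):
        p = SchemeParams(k1=26.6, k_minus1=0.0, g_off=0.0, g_act_max=1e5)
        assert eigen_rate(p, 4.0, 0.0) == pytest.approx(26.6, rel=1e-9)

    @settings(max_examples=30, derandomize=True)
    @given(k1=rates, km1=rates, K2=positive)
    def test_positive_for_valid_params(self, k1, km1, K2):
        assert eigen_rate(SchemeParams(k1=k1, k_minus1=km1, K2=K2), 4.5, 10.0) > 0


class TestSimulateTransient:
    def test_ca_jump_converges_to_steady_force(self, perfused_params, ca_jump):
        trace = simulate_transient(perfused_params, ca_jump)
        target = steady_state(perfused_params, 4.5, 0.0).force
        assert trace.force[-1] == pytest.approx(target, rel=0.01)

    def test_rate_matrix_conserves_probability(self, perfused_params):
        Q = rate_matrix(perfused_params, 4.5, 10.0)
        assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-12)

    def test_ca_jump_fit_recovers_slowest_eigenvalue(self, perfused_params, ca_jump):
        trace = simulate_transient(perfused_params, ca_jump)
        fit = fit_transient(trace)
        er = eigen_rate(perfused_params, 4.5, 0.0)
        assert abs(fit.rate - er) / er < 0.05

    def test_atp_jump_initial_force_and_dip(self, perfused_params):
        proto = Protocol(kind="ATP_JUMP", pCa=4.5, duration=0.5)
        trace = simulate_transient(perfused_params, proto)
        ss = steady_state(perfused_params, 4.5, 0.0)
        # rigor occupancy is scaled to one third of the steady active force
        assert trace.force[0] == pytest.approx(ss.force / 3.0, rel=1e-6)
        assert trace.force.min() < trace.force[0]
        assert trace.force[-1] > trace.force[0]

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            Protocol(kind="BAD")
        with pytest.raises(ValueError):
            Protocol(pCa=3.0)
        with pytest.raises(ValueError):
            Protocol(duration=0.0)


class TestCalibration:
    def test_calibrated_model_relaxes_at_target_rate(self, perfused_params):
        p = calibrate_activation_rate(perfused_params, 22.0, 4.5, 0.0)
        assert eigen_rate(p, 4.5, 0.0) == pytest.approx(22.0, abs=1e-6)

    def test_unreachable_target_raises(self, perfused_params):
        with pytest.raises(ModelError):
            calibrate_activation_rate(perfused_params, 1e4)
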