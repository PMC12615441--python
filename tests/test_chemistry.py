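"""Forward shift model and its closed-form inversions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from phosphoshift.chemistry import (
    BiochemState,
    ShiftConstants,
    atp_shifts_from_state,
    load_constants,
    mg_fraction_from_beta,
    ph_from_pi_shift,
    pi_shift_from_ph,
    save_constants,
)


class TestPiTitration:
    def test_midpoint_at_pka(self, constants):
        # Henderson–Hasselbalch midpoint: half-deprotonated at pH = pKa
        assert pi_shift_from_ph(constants.pka, constants) == pytest.approx(
            (constants.delta_acid_pi + constants.delta_base_pi) / 2
        )
        assert pi_shift_from_ph(constants.pka, constants) == pytest.approx(4.480)

    def test_alkaline_limit_approached_from_below(self, constants):
        val = pi_shift_from_ph(8.5, constants)
        assert val < constants.delta_base_pi
        assert constants.delta_base_pi - val < 0.05

    def test_value_at_ph7_matches_bisection_oracle(self, constants):
        delta = pi_shift_from_ph(7.00, constants)
        # independent oracle: invert the forward curve by bisection
        ph_back = brentq(
            lambda p: pi_shift_from_ph(p, constants) - delta, 5.5, 8.5, xtol=1e-12
        )
        assert ph_back == pytest.approx(7.00, abs=1e-9)
        assert ph_from_pi_shift(delta, constants) == pytest.approx(ph_back, abs=1e-9)

    def test_ion_correction_is_additive(self, constants):
        base = pi_shift_from_ph(7.0, constants)
        shifted = pi_shift_from_ph(7.0, constants, ion=constants.ion_ref + 0.1)
        assert shifted - base == pytest.approx(constants.ion_coef_pi * 0.1)

    @given(st.floats(5.5, 8.49))
    def test_strictly_increasing_in_ph(self, ph):
        c = ShiftConstants()
        assert pi_shift_from_ph(ph + 0.01, c) > pi_shift_from_ph(ph, c)

    @pytest.mark.parametrize("ph", [5.4, 8.6])
    def test_out_of_range_ph_names_bound(self, ph):
        with pytest.raises(ValueError, match="bound"):
            pi_shift_from_ph(ph)

    def test_shift_outside_titration_limits_rejected(self, constants):
        with pytest.raises(ValueError, match="titration"):
            ph_from_pi_shift(constants.delta_base_pi)
        with pytest.raises(ValueError, match="titration"):
            ph_from_pi_shift(constants.delta_acid_pi - 1e-6)

    @given(st.floats(5.6, 8.4))
    def test_round_trip(self, ph):
        c = ShiftConstants()
        assert ph_from_pi_shift(pi_shift_from_ph(ph, c), c) == pytest.approx(ph, abs=1e-10)

    def test_near_limit_monotone_and_finite(self, constants):
        # close to the deprotonated limit the inverse is large but finite
        d1 = constants.delta_base_pi - 1e-5
        d2 = constants.delta_base_pi - 1e-6
        p1, p2 = ph_from_pi_shift(d1, constants), ph_from_pi_shift(d2, constants)
        assert np.isfinite(p2) and p2 > p1
        # bisection oracle on the raw titration curve (outside the
        # physiologically valid evaluation window, so inline the formula)
        c = constants
        forward = lambda p: c.delta_acid_pi + (c.delta_base_pi - c.delta_acid_pi) / (
            1 + 10 ** (c.pka - p)
        )
        oracle = brentq(lambda p: forward(p) - d1, 5.5, 20.0, xtol=1e-13)
        assert p1 == pytest.approx(oracle, abs=1e-8)


class TestAtpShifts:
    def test_full_mg_binding_hits_mgatp_endpoints(self, constants):
        state = BiochemState(ph=constants.ph_ref, mg_fraction=1.0, ion=constants.ion_ref)
        g, a, b = atp_shifts_from_state(state, constants)
        assert (g, a, b) == (
            constants.delta_mg_gamma, constants.delta_mg_alpha, constants.delta_mg_beta
        )

    def test_half_binding_is_midpoint(self, constants):
        state = BiochemState(ph=constants.ph_ref, mg_fraction=0.5, ion=constants.ion_ref)
        g, a, b = atp_shifts_from_state(state, constants)
        assert g == pytest.approx((constants.delta_free_gamma + constants.delta_mg_gamma) / 2)
        assert a == pytest.approx((constants.delta_free_alpha + constants.delta_mg_alpha) / 2)
        assert b == pytest.approx((constants.delta_free_beta + constants.delta_mg_beta) / 2)

    def test_ion_finite_difference(self, constants):
        s0 = BiochemState(ph=7.0, mg_fraction=0.6, ion=0.15)
        s1 = BiochemState(ph=7.0, mg_fraction=0.6, ion=0.25)
        g0, a0, b0 = atp_shifts_from_state(s0, constants)
        g1, a1, b1 = atp_shifts_from_state(s1, constants)
        assert g1 - g0 == pytest.approx(constants.ion_coef_gamma * 0.1)
        assert b1 - b0 == pytest.approx(constants.ion_coef_beta * 0.1)
        assert a1 - a0 == pytest.approx(constants.ion_coef_alpha * 0.1)

    @given(st.floats(0.01, 0.99))
    def test_beta_has_steepest_mg_response(self, mg):
        c = ShiftConstants()
        eps = 0.01
        lo = BiochemState(7.0, mg, 0.15)
        hi = BiochemState(7.0, mg + eps, 0.15)
        d = np.subtract(atp_shifts_from_state(hi, c), atp_shifts_from_state(lo, c))
        assert abs(d[2]) > abs(d[0]) >= abs(d[1])
        assert d[2] > 0  # downfield with more Mg binding

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            BiochemState(ph=7.0, mg_fraction=1.2)
        with pytest.raises(ValueError):
            BiochemState(ph=4.0, mg_fraction=0.5)


class TestMgInversion:
    def test_endpoint_and_midpoint(self, constants):
        full = mg_fraction_from_beta(constants.delta_mg_beta, 7.0, 0.15, constants)
        assert full == 1.0
        mid = (constants.delta_mg_beta + constants.delta_free_beta) / 2
        assert mg_fraction_from_beta(mid, 7.0, 0.15, constants) == pytest.approx(0.5)

    @given(st.floats(0.01, 0.99), st.floats(6.0, 7.8), st.floats(0.0, 0.4))
    def test_round_trip(self, mg, ph, ion):
        c = ShiftConstants()
        _, _, beta = atp_shifts_from_state(BiochemState(ph, mg, ion), c)
        assert mg_fraction_from_beta(beta, ph, ion, c) == pytest.approx(mg, abs=1e-10)

    def test_noise_slack_clips_to_unit_interval(self, constants):
        span = constants.delta_mg_beta - constants.delta_free_beta
        slightly_over = constants.delta_mg_beta + 0.03 * span
        assert mg_fraction_from_beta(slightly_over, 7.0, 0.15, constants) == 1.0

    def test_far_outside_raises(self, constants):
        with pytest.raises(ValueError, match="inconsistent"):
            mg_fraction_from_beta(constants.delta_mg_beta + 2.0, 7.0, 0.15, constants)


class TestConstants:
    def test_sensitivity_ordering_enforced(self):
        with pytest.raises(ValueError, match="pH sensitivity"):
            ShiftConstants(ph_coef_alpha=0.5)   # would exceed gamma
        with pytest.raises(ValueError, match="Mg sensitivity"):
            ShiftConstants(delta_mg_beta=-18.94)  # beta span below gamma span
        with pytest.raises(ValueError, match="deprotonation"):
            ShiftConstants(delta_base_pi=3.0)

    def test_config_file_round_trip(self, tmp_path, constants):
        path = tmp_path / "constants.cfg"
        save_constants(constants, path)
        assert load_constants(path) == constants

    def test_fingerprint_tracks_values(self, constants):
        other = ShiftConstants(pka=6.78)
        assert constants.fingerprint() != other.fingerprint()
        assert constants.fingerprint() == ShiftConstants().fingerprint()
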