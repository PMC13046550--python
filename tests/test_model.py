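import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myofatigue import (
    CrossBridgeState, MetaboliteState, ModelParameters, effective_rates,
    h_to_ph, ph_to_h, saturation_fraction, system_rhs, xb_force,
)
from myofatigue.protocol import resting_state_vector


def resting_metabolites(p):
    r = p.resting
    return MetaboliteState(ATP=r.ATP, ADP=r.ADP, AMP=r.AMP, PCr=r.PCr,
                           Cr=r.Cr, Pi=r.Pi, H=ph_to_h(r.pH))


class TestProtonConversion:
    @pytest.mark.parametrize("ph,h", [(7.0, 0.1), (6.0, 1.0), (6.46, 0.3467)])
    def test_definition(self, ph, h):
        assert ph_to_h(ph) == pytest.approx(h, rel=1e-3)

    @given(st.floats(min_value=4.0, max_value=9.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, ph):
        assert h_to_ph(ph_to_h(ph)) == pytest.approx(ph, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 14.0, -1.0, float("nan"), float("inf")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError, match=r"pH"):
            ph_to_h(bad)


class TestSaturation:
    @pytest.mark.parametrize("conc,K,expected", [
        (5.0, 5.0, 0.5),      # half-saturation
        (0.0, 5.0, 0.0),      # empty-site limit
        (45.0, 5.0, 0.9),     # conc = 9 K
    ])
    def test_values(self, conc, K, expected):
        assert saturation_fraction(conc, K) == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=1e3),
           st.floats(min_value=0, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, c1, c2, K):
        f1, f2 = saturation_fraction(c1, K), saturation_fraction(c2, K)
        assert 0.0 <= f1 < 1.0
        if c1 <= c2:
            assert f1 <= f2

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValueError):
            saturation_fraction(1.0, 0.0)


class TestEffectiveRates:
    def test_unmodulated_limit(self, params):
        """Zero Pi/H/ADP and saturating ATP recover the published constants."""
        met = MetaboliteState(ATP=1e9, ADP=0.0, AMP=0.0, PCr=35.0, Cr=10.0,
                              Pi=0.0, H=1e-12)
        rs = effective_rates(met, (0.0, 0.0, 0.0), params)
        assert rs.ka_eff == pytest.approx(1305.6)
        assert rs.k1_eff == pytest.approx(1419.4)
        assert rs.k2_eff == pytest.approx(638.0)
        assert rs.k3_eff == pytest.approx(371.2, rel=1e-4)
        assert rs.kd_eff == pytest.approx(0.0, abs=1e-9)

    def test_proton_half_saturation_halves_k1(self, params):
        met = MetaboliteState(ATP=1e9, ADP=0.0, AMP=0.0, PCr=35.0, Cr=10.0,
                              Pi=0.0, H=params.K_H)
        rs = effective_rates(met, (0.0, 0.0, 0.0), params)
        assert rs.k1_eff == pytest.approx(1419.4 / 2)  # 709.7

    def test_monotone_in_pi_and_h(self, params):
        base = resting_metabolites(params)
        k1_prev, kd_prev = math.inf, -math.inf
        for scale in (1.0, 2.0, 5.0, 20.0):
            met = MetaboliteState(ATP=base.ATP, ADP=base.ADP, AMP=base.AMP,
                                  PCr=base.PCr, Cr=base.Cr,
                                  Pi=base.Pi * scale, H=base.H * scale)
            rs = effective_rates(met, (0.0, 0.0, 0.0), params)
            assert rs.k1_eff < k1_prev
            assert rs.kd_eff > kd_prev
            k1_prev, kd_prev = rs.k1_eff, rs.kd_eff

    def test_negative_concentration_rejected(self, params):
        met = MetaboliteState(ATP=8.2, ADP=0.01, AMP=0.0, PCr=35.0, Cr=10.0,
                              Pi=-1.0, H=0.1)
        with pytest.raises(ValueError):
            effective_rates(met, (0.0, 0.0, 0.0), params)


class TestForce:
    def test_zero_state_gives_passive_offset(self, params):
        f = xb_force(CrossBridgeState(P=0.0), params)
        assert f.friction == 0.0
        assert f.ratchet == 0.0
        assert f.total_N == params.F_pee

    def test_ratchet_term(self, params):
        xb = CrossBridgeState(P=0.5, A3_0=0.5)
        f = xb_force(xb, params)
        assert f.ratchet == pytest.approx(95115.2 * 0.008 * 0.5)  # 380.46

    def test_decomposition_identity(self, params):
        xb = CrossBridgeState(P=0.1, A2_0=0.3, A3_0=0.4,
                              A2_1=1e-4, A3_1=2e-4)
        f = xb_force(xb, params)
        expected = (f.friction + f.ratchet) * params.A_cs / 1000 + params.F_pee
        assert f.total_N == pytest.approx(expected)


@st.composite
def random_states(draw):
    occ = draw(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4))
    total = sum(occ) or 1.0
    occ = [v / max(total, 1.0) for v in occ]
    mets = [draw(st.floats(1e-6, 40.0)) for _ in range(6)]
    h = draw(st.floats(0.01, 1.0))
    return np.array(occ + [0.0, 0.0, 0.0] + mets + [h])[
        [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13]
    ]


class TestSystemRHS:
    def test_empty_pool_is_fixed_point_of_cycle(self, params):
        y = resting_state_vector(params)
        dy = system_rhs(0.0, y, params)
        assert np.allclose(dy[:7], 0.0)

    @given(random_states())
    @settings(max_examples=100, deadline=None)
    def test_conservation_laws(self, y):
        """Occupancy, adenine and creatine sums have exactly zero derivative."""
        p = ModelParameters()
        # order: P A1 A2 A3 | moments | ATP ADP AMP PCr Cr Pi H
        y = np.concatenate([y[:4], [0.0, 0.0, 0.0], y[7:]])
        dy = system_rhs(0.0, y, p)
        assert abs(dy[0] + dy[1] + dy[2] + dy[3]) < 1e-9 * max(1.0, np.abs(dy[:4]).max())
        assert abs(dy[7] + dy[8] + dy[9]) < 1e-9 * max(1.0, np.abs(dy[7:10]).max())
        assert abs(dy[10] + dy[11]) < 1e-9 * max(1.0, np.abs(dy[10:12]).max())

    def test_nonfinite_derivative_flagged(self, params):
        y = resting_state_vector(params)
        y[0] = 1.0
        y[1] = float("nan")  # corrupt A1; the failure must be surfaced
        with pytest.raises(FloatingPointError, match="non-finite derivative"):
            system_rhs(0.0, y, params)


class TestParameters:
    def test_unknown_field_rejected(self):
        with pytest.raises(KeyError):
            ModelParameters.from_dict({"not_a_rate": 1.0})

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="kstiff2"):
            ModelParameters(kstiff2=0.0)

    def test_ton_bounded_by_cycle_period(self):
        with pytest.raises(ValueError):
            ModelParameters(T_on=6.0, T_cyc=5.0)

    def test_round_trip(self, params):
        assert ModelParameters.from_dict(params.to_dict()) == params
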