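"""Transfer functions, occupancy algebra and the cascade right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxcascade.model import (
    CascadeState,
    Genotype,
    ParameterSet,
    anaerobox_occupancy,
    fnrn_active_fraction,
    genotype_from_name,
    headspace_to_dissolved,
    hfixl_active_fraction,
    promoter_rates,
    rhs,
    rhs_vector,
)

P = ParameterSet()


class TestOxygenConversion:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.01, 12e-6), (0.0001, 120e-9), (0.0, 0.0)],
    )
    def test_published_equivalences(self, fraction, expected):
        assert headspace_to_dissolved(fraction, P) == pytest.approx(expected, rel=1e-12)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            headspace_to_dissolved(-0.01, P)

    @given(st.floats(1e-8, 0.21), st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_degree_one(self, fraction, a):
        assert headspace_to_dissolved(a * fraction, P) == pytest.approx(
            a * headspace_to_dissolved(fraction, P), rel=1e-12
        )


class TestSensorTransferFunctions:
    @pytest.mark.parametrize(
        "func,half",
        [(hfixl_active_fraction, P.K_L), (fnrn_active_fraction, P.K_NO2)],
    )
    def test_anoxic_and_half_saturation_limits(self, func, half):
        assert func(0.0, P) == 1.0
        assert func(half, P) == pytest.approx(0.5, rel=1e-12)

    def test_cooperative_hfixl_at_twice_half_point(self):
        # Hill-2: 1/(1 + 2^2) = 0.2
        assert hfixl_active_fraction(2 * P.K_L, P) == pytest.approx(0.2, rel=1e-12)

    def test_fnrn_nearly_inactive_at_microaerobic_oxygen(self):
        # 120 nM half point, first-order: 1/(1 + 100) at 12 uM
        assert fnrn_active_fraction(12e-6, P) == pytest.approx(1 / 101, rel=1e-9)

    @given(st.lists(st.floats(0, 1e-3), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_non_increasing_in_oxygen(self, cs):
        cs = sorted(cs)
        for func in (hfixl_active_fraction, fnrn_active_fraction):
            vals = [func(c, P) for c in cs]
            assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_negative_oxygen_rejected(self):
        with pytest.raises(ValueError):
            hfixl_active_fraction(-1e-9, P)
        with pytest.raises(ValueError):
            fnrn_active_fraction(-1e-9, P)


class TestAnaeroboxOccupancy:
    def test_empty_and_half_saturated_operator(self):
        assert anaerobox_occupancy(0, 0, 1.0, 0.5).theta_total == 0
        occ = anaerobox_occupancy(1.0, 0, 1.0, 0.5)
        assert occ.theta_fixk == pytest.approx(0.5, rel=1e-12)

    def test_equal_drive_splits_evenly(self):
        occ = anaerobox_occupancy(2.0, 1.0, 2.0, 1.0)
        assert occ.theta_fixk == pytest.approx(1 / 3, rel=1e-12)
        assert occ.theta_fnrn == pytest.approx(1 / 3, rel=1e-12)

    @given(
        st.floats(0, 1e3),
        st.floats(0, 1e3),
        st.floats(1e-3, 1e3),
        st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_occupancies_bounded(self, k, n, ak, an):
        occ = anaerobox_occupancy(k, n, ak, an)
        assert 0.0 <= occ.theta_fixk
        assert 0.0 <= occ.theta_fnrn
        assert occ.theta_total < 1.0


class TestPromoterRatesAndRhs:
    def test_zero_state_gives_basal_rates(self):
        rates = promoter_rates(CascadeState(), 12e-6, P)
        assert rates.fixK == pytest.approx(P.alpha_K)
        assert rates.fnrN == pytest.approx(P.alpha_N)
        assert rates.fixNOQP == pytest.approx(P.alpha_F)

    def test_steric_repression_dominates_at_high_fnrn(self):
        # proximal box saturates in anoxia as N grows: rate -> alpha_N
        big = (P.alpha_N + P.beta_N) / P.delta
        rate = promoter_rates(CascadeState(N=1e6 * big), 0.0, P).fnrN
        assert rate == pytest.approx(P.alpha_N, rel=1e-3)

    def test_atmospheric_control_is_near_basal(self, defaults):
        # with the calibrated set, both sensors are off at 21% headspace
        c = headspace_to_dissolved(0.21, defaults)
        wt_ss = CascadeState(
            L=defaults.beta_L / defaults.delta, R=defaults.beta_R / defaults.delta
        )
        rates = promoter_rates(wt_ss, c, defaults)
        assert rates.fixK - defaults.alpha_K < 0.12 * defaults.beta_K
        assert rates.fnrN - defaults.alpha_N < 0.12 * defaults.beta_N

    def test_rhs_at_zero_state_is_pure_synthesis(self):
        d = rhs(CascadeState(), 12e-6, P)
        assert d == pytest.approx(
            [P.beta_L, P.beta_R, P.alpha_K, P.alpha_N, P.alpha_F]
        )

    def test_knockout_forces_pure_decay(self):
        g = Genotype.delta_fnrn()
        st_ = CascadeState(L=1, R=1, K=0.5, N=0.7, F=0.1)
        d = rhs(st_, 1e-7, P, g)
        assert d[3] == pytest.approx(-P.delta * st_.N)

    @given(
        st.integers(0, 4),
        st.lists(st.floats(0, 5), min_size=5, max_size=5),
        st.floats(0, 1e-4),
    )
    @settings(max_examples=100, deadline=None)
    def test_rhs_preserves_non_negativity(self, zero_idx, comps, c):
        comps[zero_idx] = 0.0
        d = rhs_vector(np.array(comps), c, P)
        assert d[zero_idx] >= 0.0


class TestParameterAndStateValidation:
    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            CascadeState(N=-0.1)

    @pytest.mark.parametrize(
        "kw",
        [
            {"delta": 0.0},
            {"beta_N": -1.0},
            {"A_N_dist": 5.0, "A_K_dist": 1.0},  # FnrN must bind more tightly
            {"rho_K": 0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ParameterSet(**kw)

    def test_unknown_parameter_key_rejected_by_name(self):
        with pytest.raises(ValueError, match="bogus"):
            ParameterSet.from_dict({"bogus": 1.0})

    def test_genotype_aliases_round_trip(self):
        assert genotype_from_name("dhfixl") == Genotype.delta_hfixl()
        with pytest.raises(ValueError):
            genotype_from_name("nonsense")
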