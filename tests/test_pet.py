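import math

import pytest
from hypothesis import given, settings, strategies as st

from trichodiel.params import FixedParameters
from trichodiel.pet import (
    allocate_energy,
    irradiance,
    pet_light_potential,
    pet_rate,
    required_aet_fraction,
)

P = FixedParameters()


class TestForcing:
    @pytest.mark.parametrize("frac,expected", [
        (0.0, 0.0),            # dawn
        (0.5, 1.0),            # solar noon
        (1.0, 0.0),            # dusk
        (1 / 6, 0.5),          # sin(pi/6) = 1/2
    ])
    def test_sinusoidal_light(self, frac, expected):
        assert irradiance(frac * P.t_light, P) == pytest.approx(expected * P.i_max, abs=1e-9)

    def test_outside_light_period_is_domain_error(self):
        with pytest.raises(ValueError):
            irradiance(-1.0, P)
        with pytest.raises(ValueError):
            irradiance(P.t_light + 1.0, P)

    def test_light_response_endpoints_and_half_point(self):
        assert pet_light_potential(0.0, P) == 0.0
        assert pet_light_potential(1e9, P) == pytest.approx(P.v_pet_max)
        i_half = math.log(2.0) / P.alpha_i
        assert pet_light_potential(i_half, P) == pytest.approx(0.5 * P.v_pet_max)

    def test_rp_inhibition_of_pet(self):
        v = 1e-3
        assert pet_rate(v, 0.0, P) == v
        v_rp_half = math.log(2.0) / P.beta_rp
        assert pet_rate(v, v_rp_half, P) == pytest.approx(0.5 * v)
        assert pet_rate(0.0, 1e-4, P) == 0.0


class TestRequiredAetFraction:
    def test_reference_process_ratios(self):
        # ATP:NADPH of 3:1 (N2 fixation) and 1.9:1 (C fixation + CCM)
        assert required_aet_fraction(3.0, P) == pytest.approx(0.5667, abs=5e-5)
        assert required_aet_fraction(1.9, P) == pytest.approx(0.3158, abs=5e-5)

    def test_pure_lpet_ratio_needs_no_aet(self):
        assert required_aet_fraction(1.3, P) == pytest.approx(0.0, abs=1e-12)
        assert required_aet_fraction(1.0, P) == 0.0  # unreachable ratio clips to 0

    @given(st.floats(min_value=1.3, max_value=1e3))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_demand_ratio(self, r):
        f = required_aet_fraction(r, P)
        assert 0.0 <= f <= 1.0
        assert required_aet_fraction(r + 0.1, P) >= f


class TestAllocateEnergy:
    def test_no_energy_no_rates(self):
        b = allocate_energy(0.0, 1e-5, P)
        assert b.v_nf == b.v_cf == 0.0
        assert b.limitation == "light_limited"

    def test_pure_carbon_fixation_operating_split(self):
        # no NF demand: combined ATP:NADPH ratio is 1.1*3.8/2 = 2.09,
        # giving the operating f_AET = 1 - 1.3/2.09
        b = allocate_energy(1e-3, 0.0, P)
        assert b.v_nf == 0.0
        assert b.f_aet == pytest.approx(1.0 - 1.3 / 2.09, rel=1e-12)

    def test_pure_nf_operating_split(self):
        # NF-saturated: ratio 1.1*9/3 = 3.3 -> f_AET = 1 - 1.3/3.3
        b = allocate_energy(1e-3, 1.0, P)
        assert b.v_cf == 0.0
        assert b.v_nf == pytest.approx(P.q_atp_lpet * 1e-3 / (1.1 * 9.0), rel=1e-12)
        assert b.f_aet == pytest.approx(1.0 - 1.3 / 3.3, rel=1e-9)

    def test_nf_priority_over_carbon_fixation(self):
        v_pet = 1e-3
        small = allocate_energy(v_pet, 1e-6, P)
        big = allocate_energy(v_pet, 5e-5, P)
        assert small.v_nf == pytest.approx(1e-6)
        assert big.v_nf > small.v_nf
        assert big.v_cf < small.v_cf

    def test_maintenance_is_surcharge_on_process_atp(self):
        b = allocate_energy(1e-3, 1e-5, P)
        assert b.atp_mt == pytest.approx(P.gamma_mt * (b.atp_nf + b.atp_cf + b.atp_ccm))

    def test_o2_evolution_tracks_lpet_share(self):
        b = allocate_energy(1e-3, 1e-5, P)
        assert b.o2_evolution == pytest.approx(0.25 * (1.0 - b.f_aet) * 1e-3)

    def test_ablate_aet_pins_split_and_wastes_surplus(self):
        b = allocate_energy(1e-3, 0.0, P, ablate_aet=True)
        assert b.f_aet == 0.0
        assert b.o2_evolution == pytest.approx(0.25 * 1e-3)
        # ATP binds first for CF at ratio 2.09 > 1.3, so NADPH is in surplus
        assert b.nadph_surplus > 0.0
        assert b.atp_surplus == pytest.approx(0.0, abs=1e-18)

    @given(
        v_pet=st.floats(min_value=0.0, max_value=2e-3),
        v_nf_req=st.floats(min_value=0.0, max_value=1e-4),
    )
    @settings(derandomize=True, max_examples=200)
    def test_currency_closure_and_caps(self, v_pet, v_nf_req):
        """Both currencies close exactly; realized rates respect supply."""
        b = allocate_energy(v_pet, v_nf_req, P)
        assert 0.0 <= b.f_aet <= 1.0
        assert 0.0 <= b.v_nf <= v_nf_req + 1e-18
        assert b.v_cf >= 0.0
        assert b.atp_supply == pytest.approx(0.65 * v_pet, rel=1e-12)
        assert b.nadph_supply == pytest.approx(0.5 * (1 - b.f_aet) * v_pet, rel=1e-12)
        # closure: no storage of either currency (absolute floor far below
        # any physical rate guards denormal-magnitude inputs)
        assert abs(b.atp_surplus) <= max(1e-12 * b.atp_supply, 1e-24)
        assert abs(b.nadph_surplus) <= max(1e-12 * b.nadph_supply, 1e-24)

    @given(st.floats(min_value=1e-8, max_value=1e-4))
    @settings(derandomize=True, max_examples=50)
    def test_f_aet_continuous_between_process_endpoints(self, v_nf_req):
        b = allocate_energy(1e-3, v_nf_req, P)
        lo = 1.0 - 1.3 / 2.09   # pure CF with surcharge
        hi = 1.0 - 1.3 / 3.3    # pure NF with surcharge
        assert lo - 1e-12 <= b.f_aet <= hi + 1e-12
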