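import math

import numpy as np
import pytest

from trichodiel import metabolism, pet
from trichodiel.oxygen import DiffusionGeometry, o2_exchange_unified
from trichodiel.params import FixedParameters, FreeParameters, RunConfig
from trichodiel.simulator import (
    biosynthesis,
    compute_fluxes,
    derivatives,
    growth_rate,
    integrate_diel,
)

P = FixedParameters()
F = FreeParameters()


class TestDerivatives:
    def test_dark_limit_only_o2_relaxes(self):
        """At dawn (I=0, empty C pools) every biological rate is zero and O2
        relaxes diffusively toward ambient."""
        state = np.array([0.0, 0.0, 0.01, 0.5 * P.o2_ambient, 0, 0, 0, 0])
        d = derivatives(0.0, state, P, F, RunConfig())
        geom = DiffusionGeometry.from_params(P)
        assert d[:3] == pytest.approx([0.0, 0.0, 0.0], abs=1e-18)
        assert d[3] == pytest.approx(geom.g_unified * 0.5 * P.o2_ambient, rel=1e-12)
        assert d[4:] == pytest.approx(np.zeros(4), abs=1e-18)

    def test_zero_state_grows_only_through_carbon_fixation(self):
        d = derivatives(P.t_light / 2, np.zeros(8), P, F, RunConfig())
        assert d[0] > 0.0          # CH2O builds from CF
        assert d[1] == 0.0         # no CS without CH2O
        assert d[2] == 0.0         # no NF without CS
        assert d[4] == d[0]        # gross C quadrature = CF when nothing consumes

    def test_assembly_matches_independent_composition(self):
        """One hand-stepped assembly from the module operations."""
        t, ch2o, cs, n, o2 = 10_000.0, 0.3, 0.05, 0.01, 0.05
        cfg = RunConfig()
        d = derivatives(t, np.array([ch2o, cs, n, o2, 0, 0, 0, 0]), P, F, cfg)

        i = pet.irradiance(t, P)
        v_rp = metabolism.rp_rate(o2, i, cs, n, P, F, ch2o=ch2o)
        v_pet = pet.pet_rate(pet.pet_light_potential(i, P), v_rp, P)
        v_nf_req = metabolism.nf_rate(metabolism.nf_max(v_pet, P), cs, n, o2, P, F)
        budget = pet.allocate_energy(v_pet, v_nf_req, P)
        v_cs = metabolism.cs_rate(ch2o, cs, P, F)
        t_o2 = o2_exchange_unified(o2, P)
        expected = [
            budget.v_cf - v_cs - v_rp,
            v_cs,
            budget.v_nf,
            (budget.o2_evolution - P.q_o2_rp * v_rp) * P.c_density + t_o2,
        ]
        assert d[:4] == pytest.approx(expected, rel=1e-12)


class TestBiosynthesis:
    def test_closed_form(self):
        # Bio_C = (CH2O + CS) / 1.44 at the default stoichiometry
        bs = biosynthesis(0.2, 0.088, 1.0, P)
        assert bs.bio_c == pytest.approx(0.2, rel=1e-12)
        assert bs.ch2o_resp == pytest.approx(0.2 * 2.0 * 1.1 / 5.0, rel=1e-12)
        assert not bs.energy_capped

    def test_cross_checked_against_numeric_solve(self):
        ch2o, cs = 0.31, 0.12
        bs = biosynthesis(ch2o, cs, 1.0, P)
        # independent 2x2 solve of the mass and energy balance
        a = np.array([[P.q_atp_bio * (1 + P.gamma_mt), -P.q_atp_resp], [1.0, 1.0]])
        bio_c, resp = np.linalg.solve(a, np.array([0.0, ch2o + cs]))
        assert bs.bio_c == pytest.approx(bio_c, rel=1e-12)
        assert bs.ch2o_resp == pytest.approx(resp, rel=1e-12)

    def test_nitrogen_limitation(self):
        assert biosynthesis(0.2, 0.1, 0.0, P).bio == 0.0
        bs = biosynthesis(0.2, 0.1, 0.01, P)
        assert bs.bio == pytest.approx(0.01 / P.nc_ratio)
        assert bs.bio < bs.bio_c

    def test_empty_pools(self):
        bs = biosynthesis(0.0, 0.0, 0.0, P)
        assert bs.bio == bs.bio_c == bs.ch2o_resp == 0.0

    def test_energy_cap_when_carbohydrate_scarce(self):
        # CS >> CH2O: respiration demand exceeds the carbohydrate pool
        bs = biosynthesis(0.1, 1.0, 1.0, P)
        assert bs.energy_capped
        assert bs.ch2o_resp == pytest.approx(0.1)
        assert bs.bio_c == pytest.approx(0.1 * P.q_atp_resp / (P.q_atp_bio * 1.1), rel=1e-12)


class TestGrowthRate:
    @pytest.mark.parametrize("bio,g", [
        (0.0, 0.0),
        (math.e - 1.0, 1.0),
        (math.exp(0.25) - 1.0, 0.25),
    ])
    def test_log_growth(self, bio, g):
        assert growth_rate(bio) == pytest.approx(g, abs=1e-12)


class TestIntegration:
    def test_temporal_segregation_peak_ordering(self, unified_run):
        """C fixation peaks in the first quarter, N2 fixation mid/late day."""
        s = unified_run.summary
        assert s["t_peak_cf"] < 0.25 * P.t_light
        assert 0.25 * P.t_light < s["t_peak_nf"] < P.t_light
        assert s["t_peak_cf"] < s["t_peak_nf"]

    def test_low_o2_window_forms_during_n2_fixation(self, unified_run):
        ts = unified_run.timeseries
        at_nf_peak = ts.loc[ts["v_nf"].idxmax()]
        assert at_nf_peak["o2"] < P.o2_ambient
        assert unified_run.summary["o2_min"] < 0.5 * P.o2_ambient

    def test_carbon_conservation(self, unified_run):
        """Gross fixed C = end pools + RP carbon (unified: no losses)."""
        s = unified_run.summary
        recon = s["ch2o_end"] + s["cs_end"] + s["rp_carbon"]
        assert recon == pytest.approx(s["gross_c_fixation"], rel=1e-5)
        assert s["transfer_c_loss"] == pytest.approx(0.0, abs=1e-12)
        # and the reported fractions close exactly by construction
        total = (s["frac_c_biomass"] + s["frac_c_rp"] + s["frac_c_night_respiration"]
                 + s["frac_c_transfer_loss"] + s["frac_c_residual"])
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_nitrogen_conservation(self, unified_run):
        s = unified_run.summary
        assert s["n_end"] == pytest.approx(s["gross_n_fixation"], rel=1e-6)

    def test_currency_closure_every_output_step(self, unified_run):
        ts = unified_run.timeseries
        tol = 1e-9 * max(ts["atp_supply"].max(), 1e-30)
        assert (ts["atp_surplus"].abs() <= tol).all()
        assert (ts["nadph_surplus"].abs() <= 1e-9 * max(ts["nadph_supply"].max(), 1e-30)).all()

    def test_energy_fraction_sets_sum_to_one(self, unified_run):
        s = unified_run.summary
        assert (s["frac_atp_cf_ccm"] + s["frac_atp_nf"] + s["frac_atp_mt"]
                + s["frac_atp_bio"]) == pytest.approx(1.0, abs=1e-6)
        assert s["frac_nadph_cf"] + s["frac_nadph_nf"] == pytest.approx(1.0, abs=1e-6)
        assert s["frac_atp_from_lpet"] + s["frac_atp_from_aet"] == pytest.approx(1.0, abs=1e-6)

    def test_solver_tolerance_stability(self, fixed, free_unified, unified_run):
        tight = integrate_diel(fixed, free_unified,
                               RunConfig(rtol=1e-7, atol_pool=1e-11, atol_o2=1e-10))
        assert tight.growth == pytest.approx(unified_run.growth, rel=1e-3)

    def test_no_rp_collapses_n2_fixation(self, fixed, free_unified, unified_run):
        res = integrate_diel(fixed, free_unified.replace(v_rp_max=0.0), RunConfig())
        assert res.summary["gross_n_fixation"] < 0.1 * unified_run.summary["gross_n_fixation"]
        assert res.summary["o2_min"] >= P.o2_ambient - 1e-9  # never below ambient

    def test_higher_membrane_permeability_costs_more_rp_carbon(self, fixed, free_unified, unified_run):
        leaky = integrate_diel(fixed.replace(epsilon=1e-3), free_unified, RunConfig())
        assert leaky.summary["rp_carbon"] > unified_run.summary["rp_carbon"]

    def test_timeseries_export_columns(self, unified_run, tmp_path):
        path = tmp_path / "ts.csv"
        unified_run.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        for col in ("t", "ch2o", "cs", "n", "o2", "v_pet", "v_nf", "v_cf",
                    "v_rp", "f_aet", "atp_supply", "nadph_supply"):
            assert col in header
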