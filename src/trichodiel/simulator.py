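"""Diel ODE assembly, integration, end-of-day biosynthesis, and budgets.

State layout (all normalized to trichome carbon unless noted):

unified:     [CH2O, CS, N, O2,             cumCF, cumNF, cumRP, cumLoss]
segregated:  [CH2O, CS, N, O2_diaz, O2_photo, cumCF, cumNF, cumRP, cumLoss]

The last four entries are quadrature states accumulating gross C fixation,
gross N2 fixation, carbon respired in respiratory protection, and carbon
lost during intercellular transfer; carrying them inside the integrator
makes the daily carbon balance close at solver tolerance instead of
quadrature-grid tolerance.

The light period covers [0, T_light]; the night contributes no fluxes
except a single algebraic biosynthesis solve that converts the end-of-day
carbohydrate, carbon-skeleton, and fixed-N pools into new biomass, from
which the daily growth rate follows as G = ln(1 + Bio) / 1 day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import metabolism, pet, segregation
from .oxygen import DiffusionGeometry, o2_exchange_unified
from .params import FixedParameters, FreeParameters, RunConfig

__all__ = [
    "FluxRecord",
    "DielResult",
    "BiosynthesisResult",
    "derivatives",
    "compute_fluxes",
    "integrate_diel",
    "biosynthesis",
    "growth_rate",
    "daily_budgets",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class FluxRecord:
    """All instantaneous rates and supply/demand terms at one time point.

    Rates are mol (mol C)^-1 s^-1 normalized to whole-trichome carbon;
    ``t_o2*`` diffusion terms are mol O2 m^-3 s^-1 (positive = gain by the
    compartment).  Compartment-resolved fields are NaN for the unified
    variant.
    """

    t: float
    irradiance: float
    v_pet_i: float          # light-limited PET potential before RP inhibition
    v_pet: float
    f_aet: float
    v_nf: float             # gross N2 fixation (before transfer loss)
    v_cf: float
    v_cs: float
    v_rp: float             # trichome-mean carbon respired in RP
    ch2o_use_rp: float      # carbohydrate drawn for RP incl. transfer loss
    n_gain: float           # net fixed-N gain after transfer loss
    o2_production: float    # mol O2 (mol C)^-1 s^-1 from LPET water splitting
    o2_rp: float            # mol O2 (mol C)^-1 s^-1 consumed by RP
    t_o2: float             # net trichome <-> environment diffusion, mol m^-3 s^-1
    atp_supply: float
    atp_nf: float
    atp_cf: float
    atp_ccm: float
    atp_mt: float
    atp_lpet: float
    atp_aet: float
    atp_surplus: float
    nadph_supply: float
    nadph_nf: float
    nadph_cf: float
    nadph_surplus: float
    limitation: str
    # segregated-variant extras (per own compartment biomass/volume)
    v_rp_photo: float = math.nan
    v_rp_diaz: float = math.nan
    o2_mixed: float = math.nan
    t_o2_diaz: float = math.nan
    t_o2_photo: float = math.nan


def compute_fluxes(
    t: float,
    state: np.ndarray,
    fixed: FixedParameters,
    free: FreeParameters,
    config: RunConfig,
    geometry: DiffusionGeometry | None = None,
) -> FluxRecord:
    """Evaluate every instantaneous flux from the (pool) state at time t."""
    geom = geometry or DiffusionGeometry.from_params(fixed)
    if config.variant == "segregated":
        return segregation.segregated_fluxes(t, state, fixed, free, config, geom)

    ch2o, cs, n, o2 = (max(float(x), 0.0) for x in state[:4])
    # stiff steppers probe marginally outside the light period
    i = pet.irradiance(min(max(t, 0.0), fixed.t_light), fixed)
    v_pet_i = pet.pet_light_potential(i, fixed)
    v_rp = metabolism.rp_rate(o2, i, cs, n, fixed, free,
                              ablate_rp=config.ablate_rp, ch2o=ch2o)
    v_pet = pet.pet_rate(v_pet_i, v_rp, fixed)
    v_nf_req = metabolism.nf_rate(metabolism.nf_max(v_pet, fixed), cs, n, o2, fixed, free)
    budget = pet.allocate_energy(v_pet, v_nf_req, fixed, ablate_aet=config.ablate_aet)
    v_cs = metabolism.cs_rate(ch2o, cs, fixed, free)
    t_o2 = o2_exchange_unified(o2, fixed, geom)
    return FluxRecord(
        t=t,
        irradiance=i,
        v_pet_i=v_pet_i,
        v_pet=v_pet,
        f_aet=budget.f_aet,
        v_nf=budget.v_nf,
        v_cf=budget.v_cf,
        v_cs=v_cs,
        v_rp=v_rp,
        ch2o_use_rp=v_rp,
        n_gain=budget.v_nf,
        o2_production=budget.o2_evolution,
        o2_rp=fixed.q_o2_rp * v_rp,
        t_o2=t_o2,
        atp_supply=budget.atp_supply,
        atp_nf=budget.atp_nf,
        atp_cf=budget.atp_cf,
        atp_ccm=budget.atp_ccm,
        atp_mt=budget.atp_mt,
        atp_lpet=fixed.q_atp_lpet * (1.0 - budget.f_aet) * v_pet,
        atp_aet=fixed.q_atp_aet * budget.f_aet * v_pet,
        atp_surplus=budget.atp_surplus,
        nadph_supply=budget.nadph_supply,
        nadph_nf=budget.nadph_nf,
        nadph_cf=budget.nadph_cf,
        nadph_surplus=budget.nadph_surplus,
        limitation=budget.limitation,
    )


def derivatives(
    t: float,
    state: np.ndarray,
    fixed: FixedParameters,
    free: FreeParameters,
    config: RunConfig,
    geometry: DiffusionGeometry | None = None,
) -> np.ndarray:
    """Right-hand side of the diel ODE system (pools + quadrature states)."""
    geom = geometry or DiffusionGeometry.from_params(fixed)
    fx = compute_fluxes(t, state, fixed, free, config, geom)
    dch2o = fx.v_cf - fx.v_cs - fx.ch2o_use_rp
    dcs = fx.v_cs
    dn = fx.n_gain
    quad = (fx.v_cf, fx.v_nf, fx.v_rp, fx.ch2o_use_rp - fx.v_rp)
    if config.variant == "segregated":
        f_d = fixed.f_diazocyte
        do2_d = (-fixed.q_o2_rp * fx.v_rp_diaz) * fixed.c_density + fx.t_o2_diaz
        do2_p = (
            fx.o2_production / (1.0 - f_d) - fixed.q_o2_rp * fx.v_rp_photo
        ) * fixed.c_density + fx.t_o2_photo
        out = np.array([dch2o, dcs, dn, do2_d, do2_p, *quad])
    else:
        do2 = (fx.o2_production - fx.o2_rp) * fixed.c_density + fx.t_o2
        out = np.array([dch2o, dcs, dn, do2, *quad])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"non-finite derivative at t={t:.1f}s, state={np.asarray(state).tolist()}"
        )
    return out


@dataclass(frozen=True)
class BiosynthesisResult:
    bio: float          # realized biomass increment, mol C (mol C)^-1
    bio_c: float        # carbon-limited biomass potential
    bio_n: float        # nitrogen-limited biomass potential
    ch2o_resp: float    # carbohydrate respired to power the realized biosynthesis
    energy_capped: bool  # True if respiration demand exceeded the CH2O pool


def biosynthesis(
    ch2o_end: float, cs_end: float, n_end: float, params: FixedParameters
) -> BiosynthesisResult:
    """End-of-day biosynthesis from the accumulated pools.

    The ATP for night biosynthesis comes from respiring part of the
    carbohydrate pool; the remainder plus all carbon skeletons become
    biomass.  Solving

        Bio_C * q_atp_bio * (1 + gamma_mt) = CH2O_resp * q_atp_resp
        Bio_C = CH2O - CH2O_resp + CS

    gives Bio_C = (CH2O + CS) / (1 + q_atp_bio*(1+gamma_mt)/q_atp_resp),
    i.e. (CH2O+CS)/1.44 at the default stoichiometry.  If the implied
    respiration exceeds the carbohydrate pool, all carbohydrate is respired
    and the carbon skeleton is only usable up to the energy that affords
    (flagged).  Bio is the smaller of the C- and N-limited potentials.
    """
    if min(ch2o_end, cs_end, n_end) < 0:
        raise ValueError("end-of-day pools must be non-negative")
    p = params
    bio_n = n_end / p.nc_ratio
    energy_per_bio = p.q_atp_bio * (1.0 + p.gamma_mt) / p.q_atp_resp  # CH2O per Bio_C
    bio_c = (ch2o_end + cs_end) / (1.0 + energy_per_bio)
    capped = False
    if bio_c * energy_per_bio > ch2o_end:
        capped = True
        bio_c = min(cs_end, ch2o_end / energy_per_bio)
    bio = min(bio_c, bio_n)
    ch2o_resp = min(bio * energy_per_bio, ch2o_end)
    return BiosynthesisResult(bio=bio, bio_c=bio_c, bio_n=bio_n,
                              ch2o_resp=ch2o_resp, energy_capped=capped)


def growth_rate(bio: float) -> float:
    """Specific growth rate G = ln(1 + Bio) per day, day^-1."""
    if bio < 0:
        raise ValueError("Bio must be non-negative")
    return math.log1p(bio)


@dataclass
class DielResult:
    """One diel cycle: time series, daily integrals, biosynthesis, growth."""

    fixed: FixedParameters
    free: FreeParameters
    config: RunConfig
    timeseries: pd.DataFrame
    summary: dict[str, Any] = field(default_factory=dict)

    @property
    def growth(self) -> float:
        return self.summary["growth_rate"]

    def to_csv(self, path) -> None:
        self.timeseries.to_csv(path, index=False)

    def summary_json(self) -> str:
        import json

        return json.dumps(self.summary, indent=2, sort_keys=True)


def _trapz(y: np.ndarray, t: np.ndarray) -> float:
    return float(np.trapezoid(y, t))


def integrate_diel(
    fixed: FixedParameters,
    free: FreeParameters,
    config: RunConfig | None = None,
) -> DielResult:
    """Integrate the diel cycle and assemble all daily diagnostics.

    Starts from empty pools at dawn (yesterday's stores went into biomass)
    with intracellular O2 equilibrated to the ambient concentration, and
    integrates the stiff system with LSODA over the 12-h light period.
    """
    config = config or RunConfig()
    geom = DiffusionGeometry.from_params(fixed)
    segregated = config.variant == "segregated"
    n_o2 = 2 if segregated else 1
    y0 = np.zeros(3 + n_o2 + 4)
    y0[3:3 + n_o2] = fixed.o2_ambient
    atol = np.full_like(y0, config.atol_pool)
    atol[3:3 + n_o2] = config.atol_o2

    sol = solve_ivp(
        derivatives,
        (0.0, fixed.t_light),
        y0,
        args=(fixed, free, config, geom),
        method="LSODA",
        t_eval=np.arange(0.0, fixed.t_light + 0.5 * config.output_dt, config.output_dt),
        rtol=config.rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"diel integration failed: {sol.message}; last state {sol.y[:, -1]}")
    if np.min(sol.y[:3 + n_o2]) < -1e-6:
        raise RuntimeError(f"negative pool in solution: min={np.min(sol.y[:3 + n_o2]):.3e}")

    records = [
        compute_fluxes(tk, sol.y[:, k], fixed, free, config, geom)
        for k, tk in enumerate(sol.t)
    ]
    ts = pd.DataFrame([asdict(r) for r in records])
    ts.insert(1, "ch2o", np.maximum(sol.y[0], 0.0))
    ts.insert(2, "cs", np.maximum(sol.y[1], 0.0))
    ts.insert(3, "n", np.maximum(sol.y[2], 0.0))
    if segregated:
        ts.insert(4, "o2_diaz", np.maximum(sol.y[3], 0.0))
        ts.insert(5, "o2_photo", np.maximum(sol.y[4], 0.0))
    else:
        ts.insert(4, "o2", np.maximum(sol.y[3], 0.0))

    yend = sol.y[:, -1]
    ch2o_end, cs_end, n_end = (max(float(v), 0.0) for v in yend[:3])
    gross_c, gross_n, rp_carbon, transfer_c_loss = (float(v) for v in yend[3 + n_o2:])
    bs = biosynthesis(ch2o_end, cs_end, n_end, fixed)
    g = growth_rate(bs.bio)

    tgrid = sol.t
    pet_int = _trapz(ts["v_pet"].to_numpy(), tgrid)
    atp_terms = {k: _trapz(ts[k].to_numpy(), tgrid)
                 for k in ("atp_supply", "atp_nf", "atp_cf", "atp_ccm", "atp_mt",
                           "atp_lpet", "atp_aet", "atp_surplus",
                           "nadph_supply", "nadph_nf", "nadph_cf", "nadph_surplus")}
    o2_prod = _trapz(ts["o2_production"].to_numpy(), tgrid)
    o2_rp = _trapz(ts["o2_rp"].to_numpy(), tgrid)
    o2_diff = _trapz(ts["t_o2"].to_numpy(), tgrid) / fixed.c_density

    # one diel cycle spans one day, so light-period integrals are per-day rates
    summary: dict[str, Any] = {
        "variant": config.variant,
        "transfer_loss": config.transfer_loss,
        "gross_c_fixation": gross_c,
        "gross_n_fixation": gross_n,
        "net_n_gain": n_end,
        "rp_carbon": rp_carbon,
        "transfer_c_loss": transfer_c_loss,
        "transfer_n_loss": gross_n - n_end,
        "c_to_n_ratio": gross_c / gross_n if gross_n > 0 else math.inf,
        "ch2o_end": ch2o_end,
        "cs_end": cs_end,
        "n_end": n_end,
        "bio": bs.bio,
        "bio_c": bs.bio_c,
        "bio_n": bs.bio_n,
        "ch2o_resp_night": bs.ch2o_resp,
        "biosynthesis_energy_capped": bs.energy_capped,
        "growth_rate": g,
        "f_aet_daily": (_trapz((ts["f_aet"] * ts["v_pet"]).to_numpy(), tgrid) / pet_int
                        if pet_int > 0 else 0.0),
        "pet_electrons": pet_int,
        "o2_production": o2_prod,
        "o2_rp_consumption": o2_rp,
        "o2_net_diffusion": o2_diff,
        "t_peak_cf": float(tgrid[int(np.argmax(ts["v_cf"].to_numpy()))]),
        "t_peak_nf": float(tgrid[int(np.argmax(ts["v_nf"].to_numpy()))]),
        **atp_terms,
    }
    if segregated:
        summary["o2_min_diaz"] = float(ts["o2_diaz"].min())
        summary["o2_max_photo"] = float(ts["o2_photo"].max())
    else:
        summary["o2_min"] = float(ts["o2"].min())
        summary["o2_max"] = float(ts["o2"].max())
    result = DielResult(fixed=fixed, free=free, config=config, timeseries=ts, summary=summary)
    result.summary.update(daily_budgets(result))
    return result


def daily_budgets(result: DielResult) -> dict[str, Any]:
    """Daily allocation fractions for carbon, ATP, NADPH, and O2.

    Every fraction set sums to one by construction; the carbon residual
    (pool carbon left unsynthesized at the end of the night) is checked
    elsewhere to be non-negative within integration tolerance.
    """
    s = result.summary
    gross_c = s["gross_c_fixation"]
    out: dict[str, Any] = {}
    if gross_c > 0:
        resp = s["ch2o_resp_night"]
        out["frac_c_biomass"] = s["bio"] / gross_c
        out["frac_c_rp"] = s["rp_carbon"] / gross_c
        out["frac_c_night_respiration"] = resp / gross_c
        out["frac_c_transfer_loss"] = s["transfer_c_loss"] / gross_c
        out["frac_c_residual"] = 1.0 - (
            out["frac_c_biomass"] + out["frac_c_rp"]
            + out["frac_c_night_respiration"] + out["frac_c_transfer_loss"]
        )
    # the ATP ledger covers the whole diel cycle: daytime process ATP plus the
    # night biosynthesis ATP (from respired carbohydrate) and its maintenance
    atp_bio = result.fixed.q_atp_bio * s["bio"]
    atp_mt_night = result.fixed.gamma_mt * atp_bio
    atp_used = s["atp_nf"] + s["atp_cf"] + s["atp_ccm"] + s["atp_mt"] + atp_bio + atp_mt_night
    if atp_used > 0:
        out["atp_bio_night"] = atp_bio
        out["frac_atp_cf_ccm"] = (s["atp_cf"] + s["atp_ccm"]) / atp_used
        out["frac_atp_nf"] = s["atp_nf"] / atp_used
        out["frac_atp_bio"] = atp_bio / atp_used
        out["frac_atp_mt"] = (s["atp_mt"] + atp_mt_night) / atp_used
    atp_prod = s["atp_lpet"] + s["atp_aet"]
    if atp_prod > 0:
        out["frac_atp_from_lpet"] = s["atp_lpet"] / atp_prod
        out["frac_atp_from_aet"] = s["atp_aet"] / atp_prod
    nadph_used = s["nadph_nf"] + s["nadph_cf"]
    if nadph_used > 0:
        out["frac_nadph_cf"] = s["nadph_cf"] / nadph_used
        out["frac_nadph_nf"] = s["nadph_nf"] / nadph_used
    return out
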