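"""Diel light forcing, photosynthetic electron transport, and the LPET/AET split.

Total photosynthetic electron transport (PET) is driven by a sinusoidal
12-h light cycle through a saturating light response, and is inhibited by
respiratory protection (RP) via plastoquinone-pool feedback:

    V_PET = v_pet_max * (1 - exp(-alpha_i * I)) * exp(-beta_rp * V_RP)

Electrons split between linear PET (LPET: 0.65 ATP, 0.5 NADPH, 0.25 O2 per
electron) and a Mehler-type alternative route (AET: 0.65 ATP, no net NADPH
or O2).  The AET fraction f_AET is adjusted instantaneously so that the
ATP:NADPH supply ratio matches demand — ATP and NADPH are never stored.
N2 fixation has first claim on both currencies; carbon fixation takes the
remainder; maintenance is a multiplicative surcharge ``gamma_mt`` on all
process ATP.  ATP produced by RP is wasted as heat and never enters the
budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import FixedParameters

__all__ = [
    "irradiance",
    "pet_light_potential",
    "pet_rate",
    "required_aet_fraction",
    "allocate_energy",
    "EnergyBudget",
]


def irradiance(t: float, params: FixedParameters) -> float:
    """Irradiance I(t) = I_max * sin(pi * t / T_light) during the light period.

    ``t`` is seconds since dawn; values outside [0, T_light] are a domain
    error (the model's night contributes no fluxes).
    """
    if not 0.0 <= t <= params.t_light:
        raise ValueError(f"t={t!r} outside the light period [0, {params.t_light}]")
    # rounding in pi*t/T can push sin a few ulp below zero at the endpoints
    return params.i_max * max(0.0, math.sin(math.pi * t / params.t_light))


def pet_light_potential(i: float, params: FixedParameters) -> float:
    """Light-dependent PET rate: v_pet_max * (1 - exp(-alpha_i * I))."""
    if i < 0:
        raise ValueError("irradiance must be non-negative")
    return params.v_pet_max * (-math.expm1(-params.alpha_i * i))


def pet_rate(v_pet_i: float, v_rp: float, params: FixedParameters) -> float:
    """Realized PET after respiratory-protection inhibition: V_PETI * exp(-beta*V_RP)."""
    return v_pet_i * math.exp(-params.beta_rp * v_rp)


def required_aet_fraction(
    atp_nadph_demand_ratio: float, params: FixedParameters | None = None
) -> float:
    """AET electron fraction needed to supply ATP:NADPH at a given demand ratio.

    Pure LPET supplies ATP:NADPH at 0.65/0.5 = 1.3.  Routing a fraction f of
    electrons through AET leaves NADPH = 0.5*(1-f) while ATP stays 0.65 per
    electron, so matching a demand ratio r requires

        f = 1 - q_atp_lpet / (q_nadph_lpet * r)

    For the pure-process demand ratios this gives 56.7% (N2 fixation, 3:1)
    and 31.6% (carbon fixation incl. CCM, 1.9:1).  Ratios below 1.3 cannot
    be reached without discarding NADPH; 0 is returned (pure LPET).
    """
    p = params or FixedParameters()
    if atp_nadph_demand_ratio <= 0:
        raise ValueError("demand ratio must be positive")
    f = 1.0 - p.q_atp_lpet / (p.q_nadph_lpet * atp_nadph_demand_ratio)
    return min(1.0, max(0.0, f))


@dataclass(frozen=True)
class EnergyBudget:
    """Instantaneous two-currency energy balance at one time point.

    All rates are mol (mol C)^-1 s^-1, normalized to whole-trichome carbon.
    ``atp_supply`` always closes against the four ATP demand terms; NADPH
    closes except when AET is ablated (f_aet pinned at 0), in which case the
    surplus of one currency is recorded in ``atp_surplus``/``nadph_surplus``.
    """

    v_pet: float
    f_aet: float
    v_nf: float                 # realized N2 fixation, mol N (mol C)^-1 s^-1
    v_cf: float                 # realized C fixation, mol C (mol C)^-1 s^-1
    atp_supply: float
    nadph_supply: float
    atp_nf: float
    atp_cf: float               # Calvin-Benson ATP
    atp_ccm: float              # carbon-concentrating-mechanism ATP
    atp_mt: float               # maintenance surcharge ATP
    nadph_nf: float
    nadph_cf: float
    o2_evolution: float         # mol O2 (mol C)^-1 s^-1, LPET water splitting
    atp_surplus: float
    nadph_surplus: float
    limitation: str             # 'ATP_limited' | 'NADPH_limited' | 'light_limited' | 'none'


def allocate_energy(
    v_pet: float,
    v_nf_requested: float,
    params: FixedParameters,
    *,
    ablate_aet: bool = False,
    nf_transfer_loss_factor: float = 1.0,
) -> EnergyBudget:
    """Split PET energy between N2 fixation and carbon fixation.

    N2 fixation is served first: the requested rate is capped by the full
    ATP budget (with maintenance surcharge) and by the NADPH available at
    the N2-fixation reference split (f_AET = 56.7%).  Carbon fixation then
    takes the entire ATP residual, and f_AET is solved in closed form so
    NADPH supply exactly meets the combined demand.  With the maintenance
    surcharge the combined ATP:NADPH demand ratio always exceeds the pure
    LPET ratio of 1.3, so the closed-form f_AET lies strictly inside (0, 1)
    whenever any demand exists.

    ``nf_transfer_loss_factor`` > 1 inflates the effective ATP/NADPH cost of
    N2 fixation when the currencies must be transferred into diazocytes with
    loss (segregated variant); it is 1 for the unified trichome.
    """
    p = params
    if v_pet < 0 or v_nf_requested < 0:
        raise ValueError("rates must be non-negative")
    mult = nf_transfer_loss_factor
    surcharge = 1.0 + p.gamma_mt
    atp_supply = p.q_atp_lpet * v_pet  # AET and LPET yield equal ATP per electron

    limitation = "none"
    if v_pet <= 1e-30:  # no meaningful electron flux (guards subnormal division)
        limitation = "light_limited"
        v_nf = v_cf = 0.0
        f_aet = 0.0
    else:
        # (1) N2-fixation priority caps
        cap_atp = atp_supply / (surcharge * p.q_atp_nf * mult)
        f_nf = required_aet_fraction(p.q_atp_nf / p.q_nadph_nf, p)
        cap_nadph = p.q_nadph_lpet * v_pet * (1.0 - f_nf) / (p.q_nadph_nf * mult)
        if ablate_aet:
            cap_nadph = p.q_nadph_lpet * v_pet / (p.q_nadph_nf * mult)
        v_nf = min(v_nf_requested, cap_atp, cap_nadph)
        if v_nf < v_nf_requested:
            limitation = "ATP_limited" if cap_atp <= cap_nadph else "NADPH_limited"
        # (2) carbon fixation takes the ATP residual
        atp_residual = atp_supply / surcharge - p.q_atp_nf * mult * v_nf
        v_cf = max(0.0, atp_residual / (p.q_atp_cf + p.q_atp_ccm))
        # (3) f_AET closes the NADPH balance
        nadph_demand = p.q_nadph_nf * mult * v_nf + p.q_nadph_cf * v_cf
        if ablate_aet:
            f_aet = 0.0
            # both currencies now bind independently; CF takes the tighter one
            nadph_residual = p.q_nadph_lpet * v_pet - p.q_nadph_nf * mult * v_nf
            v_cf_nadph = max(0.0, nadph_residual / p.q_nadph_cf)
            if v_cf_nadph < v_cf:
                v_cf = v_cf_nadph
                limitation = "NADPH_limited"
        else:
            f_aet = 1.0 - nadph_demand / (p.q_nadph_lpet * v_pet)
            f_aet = min(1.0, max(0.0, f_aet))

    atp_nf = p.q_atp_nf * mult * v_nf
    atp_cf = p.q_atp_cf * v_cf
    atp_ccm = p.q_atp_ccm * v_cf
    atp_mt = p.gamma_mt * (atp_nf + atp_cf + atp_ccm)
    nadph_nf = p.q_nadph_nf * mult * v_nf
    nadph_cf = p.q_nadph_cf * v_cf
    nadph_supply = p.q_nadph_lpet * (1.0 - f_aet) * v_pet
    return EnergyBudget(
        v_pet=v_pet,
        f_aet=f_aet,
        v_nf=v_nf,
        v_cf=v_cf,
        atp_supply=atp_supply,
        nadph_supply=nadph_supply,
        atp_nf=atp_nf,
        atp_cf=atp_cf,
        atp_ccm=atp_ccm,
        atp_mt=atp_mt,
        nadph_nf=nadph_nf,
        nadph_cf=nadph_cf,
        o2_evolution=p.q_o2_lpet * (1.0 - f_aet) * v_pet,
        atp_surplus=atp_supply - (atp_nf + atp_cf + atp_ccm + atp_mt),
        nadph_surplus=nadph_supply - (nadph_nf + nadph_cf),
        limitation=limitation,
    )
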