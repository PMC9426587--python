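"""Spatially segregated variant: diazocytes vs. photosynthetic cells.

N2 fixation is confined to diazocytes (a fraction ``f_diazocyte`` of the
cells); PET, carbon fixation, and carbon-skeleton synthesis run in the
remaining photosynthetic cells.  Carbohydrate, carbon skeleton, and fixed N
are shared trichome-wide pools; ATP and NADPH are produced only in
photosynthetic cells and used instantaneously.  Each cell type keeps its
own intracellular O2, exchanged through a common mixed layer (oxygen
module).

Intercellular transfer can be lossy (loss fraction ``transfer_loss`` of the
run configuration, 0–0.8).  The loss applies to the *transferred* share of
a material:

* fixed N produced in diazocytes — the diazocyte-retained share (f_D of it)
  is loss-free, the share transferred to the rest of the trichome loses the
  fraction, so the net gain per mol fixed is f_D + (1-f_D)(1-loss);
* carbohydrate respired in diazocytes — the f_D share of the shared pool
  already resides there, the remainder must be transferred in, so one mol
  respired draws f_D + (1-f_D)/(1-loss) from the pool;
* ATP and NADPH consumed by N2 fixation — produced exclusively in
  photosynthetic cells and never stored, so the whole demand is transferred
  and costs 1/(1-loss) per mol delivered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metabolism, pet
from .oxygen import DiffusionGeometry, o2_exchange_segregated
from .params import FixedParameters, FreeParameters, ParameterError, RunConfig

__all__ = ["SegregationConfig", "segregated_fluxes", "transfer_loss_sweep"]


@dataclass(frozen=True)
class SegregationConfig:
    """Diazocyte fraction and transfer-loss fraction of the segregated variant."""

    f_diazocyte: float = 0.15
    transfer_loss: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_diazocyte < 1.0:
            raise ParameterError("f_diazocyte must lie in (0, 1)")
        if not 0.0 <= self.transfer_loss <= 0.8:
            raise ParameterError("transfer_loss must lie in [0, 0.8]")


def segregated_fluxes(
    t: float,
    state: np.ndarray,
    fixed: FixedParameters,
    free: FreeParameters,
    config: RunConfig,
    geometry: DiffusionGeometry | None = None,
):
    """All instantaneous fluxes of the segregated trichome at time t.

    Rates named per-compartment (``v_rp_photo``, ``v_rp_diaz``) are
    normalized to that compartment's own carbon; everything else is
    normalized to whole-trichome carbon.
    """
    from .simulator import FluxRecord  # local import to avoid a cycle

    geom = geometry or DiffusionGeometry.from_params(fixed)
    ch2o, cs, n, o2_d, o2_p = (max(float(x), 0.0) for x in state[:5])
    f_d = fixed.f_diazocyte
    lam = config.transfer_loss
    retain = 1.0 - lam
    # effective pool/currency cost multipliers of diazocyte consumption
    mult_energy = 1.0 / retain
    mult_ch2o = f_d + (1.0 - f_d) / retain
    n_gain_mult = f_d + (1.0 - f_d) * retain
    if config.nf_in_photo:
        # reduction check: nitrogenase co-located with photosynthesis
        mult_energy = 1.0
        mult_ch2o = 1.0
        n_gain_mult = (1.0 - f_d) + f_d * retain

    i = pet.irradiance(min(max(t, 0.0), fixed.t_light), fixed)
    v_pet_i = pet.pet_light_potential(i, fixed)
    v_rp_p = metabolism.rp_rate(o2_p, i, cs, n, fixed, free,
                                ablate_rp=config.ablate_rp, ch2o=ch2o)
    v_rp_d = metabolism.rp_rate(o2_d, i, cs, n, fixed, free,
                                ablate_rp=config.ablate_rp, ch2o=ch2o)
    v_pet_photo = pet.pet_rate(v_pet_i, v_rp_p, fixed)  # RP feedback is cell-local
    v_pet = (1.0 - f_d) * v_pet_photo                   # per trichome carbon

    o2_nf = o2_p if config.nf_in_photo else o2_d
    v_nf_max = metabolism.nf_max(v_pet, fixed) / mult_energy
    v_nf_req = metabolism.nf_rate(v_nf_max, cs, n, o2_nf, fixed, free)
    budget = pet.allocate_energy(v_pet, v_nf_req, fixed,
                                 ablate_aet=config.ablate_aet,
                                 nf_transfer_loss_factor=mult_energy)
    v_cs = (1.0 - f_d) * metabolism.cs_rate(ch2o, cs, fixed, free)
    v_rp = (1.0 - f_d) * v_rp_p + f_d * v_rp_d
    ch2o_use = (1.0 - f_d) * v_rp_p + f_d * v_rp_d * mult_ch2o

    seg = o2_exchange_segregated(o2_d, o2_p, fixed, geom)
    # net trichome <-> environment exchange, volume-weighted to trichome units
    t_o2 = f_d * seg.flux_diazocyte + (1.0 - f_d) * seg.flux_photosynthetic

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
        ch2o_use_rp=ch2o_use,
        n_gain=budget.v_nf * n_gain_mult,
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
        v_rp_photo=v_rp_p,
        v_rp_diaz=v_rp_d,
        o2_mixed=seg.o2_mixed,
        t_o2_diaz=seg.flux_diazocyte,
        t_o2_photo=seg.flux_photosynthetic,
    )


def transfer_loss_sweep(
    loss_grid,
    fixed: FixedParameters | None = None,
    free: FreeParameters | None = None,
    config: RunConfig | None = None,
):
    """Run the segregated model across a grid of transfer-loss fractions.

    Returns a DataFrame with the absolute growth rate, gross C and N2
    fixation, and net N gain at each loss fraction, plus their ratios to
    the unified model run at its own optimized parameters.
    """
    import pandas as pd

    from .params import default_optimized_parameters
    from .simulator import integrate_diel

    fixed = fixed or FixedParameters()
    free = free or default_optimized_parameters("segregated")
    config = config or RunConfig(variant="segregated")
    uni = integrate_diel(fixed, default_optimized_parameters("unified"),
                         config.replace(variant="unified", transfer_loss=0.0))
    rows = []
    for lam in loss_grid:
        res = integrate_diel(fixed, free, config.replace(transfer_loss=float(lam)))
        s = res.summary
        rows.append({
            "transfer_loss": float(lam),
            "growth_rate": s["growth_rate"],
            "gross_c_fixation": s["gross_c_fixation"],
            "gross_n_fixation": s["gross_n_fixation"],
            "net_n_gain": s["net_n_gain"],
            "growth_ratio_vs_unified": s["growth_rate"] / uni.summary["growth_rate"],
            "gross_c_ratio_vs_unified": s["gross_c_fixation"] / uni.summary["gross_c_fixation"],
            "gross_n_ratio_vs_unified": s["gross_n_fixation"] / uni.summary["gross_n_fixation"],
            "net_n_ratio_vs_unified": s["net_n_gain"] / uni.summary["net_n_gain"],
        })
    return pd.DataFrame(rows)
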