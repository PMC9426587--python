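"""Instantaneous metabolic rates: N2 fixation, carbon-skeleton synthesis, RP.

All rates follow Michaelis-Menten / saturating-product forms and are
normalized to the carbon biomass of the compartment they run in.  The
carbon skeleton (CS) acts purely as a regulator during the day — it is
consumed only by the end-of-day biosynthesis step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import FixedParameters, FreeParameters

__all__ = ["TrichomeState", "nf_max", "nf_rate", "cs_rate", "rp_rate"]

#: Carbohydrate availability scale used to shut respiratory protection off
#: smoothly as the carbohydrate pool empties (keeps pools non-negative
#: without introducing a hard switch into the stiff integrator).
CH2O_AVAILABILITY_SCALE = 1.0e-6


@dataclass
class TrichomeState:
    """Instantaneous pools of one trichome, normalized to carbon biomass.

    ``o2`` is the single intracellular O2 concentration of the unified
    trichome; the segregated variant carries separate diazocyte and
    photosynthetic-cell concentrations instead.
    """

    ch2o: float = 0.0   # carbohydrate, mol C (mol C)^-1
    cs: float = 0.0     # carbon skeleton, mol C (mol C)^-1
    n: float = 0.0      # fixed nitrogen, mol N (mol C)^-1
    o2: float = 0.0     # intracellular O2, mol m^-3


def nf_max(v_pet: float, params: FixedParameters) -> float:
    """Maximal N2-fixation potential when all PET serves N2 fixation.

    At the N2-fixation reference split (f_AET = 56.7%) every mol of
    electrons yields q_nadph_lpet*(1-f_AET) NADPH, which supports
    that amount / q_nadph_nf of fixed N:

        V_NF_max = V_PET * (1 - f_AET_NF) * q_nadph_lpet / q_nadph_nf
    """
    if v_pet < 0:
        raise ValueError("v_pet must be non-negative")
    from .pet import required_aet_fraction

    f_nf = required_aet_fraction(params.q_atp_nf / params.q_nadph_nf, params)
    return v_pet * (1.0 - f_nf) * params.q_nadph_lpet / params.q_nadph_nf


def _sat(x: float, k: float) -> float:
    """Michaelis factor x/(x+k), clamped for non-negative substrate."""
    x = max(x, 0.0)
    if x == 0.0:
        return 0.0
    return x / (x + k)


def _storage(x: float, x_max: float) -> float:
    """Linear storage-inhibition factor (x_max - x)/x_max, clamped to [0, 1]."""
    return min(1.0, max(0.0, (x_max - x) / x_max))


def nf_rate(
    v_nf_max: float, cs: float, n: float, o2: float,
    params: FixedParameters, free: FreeParameters,
) -> float:
    """Regulated N2-fixation demand.

    The potential is throttled by carbon-skeleton availability (half
    saturation ``k_cs_nf``), by the approach of fixed N to its storage
    ceiling, and by Michaelis-Menten O2 inhibition: the O2 factor
    1 - O2/(O2+k_o2_nf) = k_o2_nf/(O2+k_o2_nf) vanishes at high O2.
    """
    return (
        v_nf_max
        * _sat(cs, free.k_cs_nf)
        * _storage(n, params.n_max)
        * (1.0 - _sat(o2, params.k_o2_nf))
    )


def cs_rate(ch2o: float, cs: float, params: FixedParameters, free: FreeParameters) -> float:
    """Carbon-skeleton synthesis from carbohydrate, self-inhibited by its own store."""
    return free.v_cs_max * _sat(ch2o, free.k_ch2o_cs) * _storage(cs, params.cs_max)


def rp_rate(
    o2: float, i: float, cs: float, n: float,
    params: FixedParameters, free: FreeParameters,
    *,
    ablate_rp: bool = False,
    ch2o: float | None = None,
) -> float:
    """Respiratory protection: carbohydrate combustion that draws down O2.

    Stimulated by intracellular O2 and by the same N2-fixation demand
    signals (light, carbon skeleton, unfilled N storage) that elevate
    nitrogenase activity:

        V_RP = v_rp_max * O2/(O2+k_o2_nf) * (1-exp(-alpha_i*I))
                        * CS/(CS+k_cs_nf) * (N_max-N)/N_max

    If ``ch2o`` is given, the rate is additionally scaled by a steep
    carbohydrate-availability factor so RP cannot respire carbon that is
    not there.
    """
    if ablate_rp:
        return 0.0
    v = (
        free.v_rp_max
        * _sat(o2, params.k_o2_nf)
        * (-math.expm1(-params.alpha_i * max(i, 0.0)))
        * _sat(cs, free.k_cs_nf)
        * _storage(n, params.n_max)
    )
    if ch2o is not None:
        v *= _sat(ch2o, CH2O_AVAILABILITY_SCALE)
    return v
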