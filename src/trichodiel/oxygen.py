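"""Cross-membrane O2 exchange for a cylindrical trichome.

Radial diffusion through concentric layers around an infinite cylinder gives
a flux proportional to the concentration difference divided by a sum of
log-resistances, one per layer; the cell membrane's resistance is inflated
by 1/epsilon because its O2 diffusivity is a small fraction epsilon of the
seawater value.  For the unified trichome the membrane and the diffusive
boundary layer act in series:

    T_O2 = g * (O2_ambient - O2_in),
    g = (2 pi d_O2 L / V) / [ (1/eps) ln((R+Lg)/R) + ln((R+Lg+Lb)/(R+Lg)) ]

with V = pi R^2 L, so g = 2 d_O2 / (R^2 * sum-of-resistances), in s^-1.
Positive T_O2 is an O2 gain by the cell.

The segregated variant inserts a well-mixed O2 layer between the cell
membranes and the boundary layer.  Diazocytes and photosynthetic cells each
exchange with that mixed layer through their own membranes (interface area
partitioned by cell fraction), and the mixed layer exchanges with the far
field through the boundary layer.  The mixed layer is treated as
quasi-steady (no storage): its concentration is the conductance-weighted
mean that closes the instantaneous O2 balance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import FixedParameters, ParameterError

__all__ = [
    "DiffusionGeometry",
    "o2_exchange_unified",
    "o2_exchange_segregated",
    "SegregatedO2Fluxes",
]


@dataclass(frozen=True)
class DiffusionGeometry:
    """Pre-computed interface conductances, s^-1 (per compartment volume)."""

    g_unified: float    # cell <-> far field, membrane + boundary layer in series
    g_membrane: float   # cell <-> mixed layer, membrane only (segregated variant)
    g_boundary: float   # mixed layer <-> far field, per trichome volume

    @classmethod
    def from_params(cls, p: FixedParameters) -> "DiffusionGeometry":
        import math

        r, lg, lb, lm = p.radius, p.l_membrane, p.l_boundary, p.l_mixed
        if min(r, lg, lb, lm, p.epsilon, p.d_o2) <= 0:
            raise ParameterError("diffusion geometry requires positive lengths, epsilon, d_o2")
        res_membrane = math.log((r + lg) / r) / p.epsilon
        res_boundary = math.log((r + lg + lb) / (r + lg))
        res_boundary_seg = math.log((r + lg + lm + lb) / (r + lg + lm))
        scale = 2.0 * p.d_o2 / r**2  # = 2 pi d L / (pi R^2 L)
        return cls(
            g_unified=scale / (res_membrane + res_boundary),
            g_membrane=scale / res_membrane,
            g_boundary=scale / res_boundary_seg,
        )


def o2_exchange_unified(o2_in: float, params: FixedParameters,
                        geometry: DiffusionGeometry | None = None) -> float:
    """Net diffusive O2 flux into the unified trichome, mol O2 m^-3 s^-1."""
    if o2_in < 0:
        raise ValueError("O2 concentration must be non-negative")
    g = (geometry or DiffusionGeometry.from_params(params)).g_unified
    return g * (params.o2_ambient - o2_in)


@dataclass(frozen=True)
class SegregatedO2Fluxes:
    """Per-compartment diffusive O2 fluxes, each per its own volume."""

    o2_mixed: float       # quasi-steady mixed-layer concentration, mol m^-3
    flux_diazocyte: float       # into diazocytes, per diazocyte volume
    flux_photosynthetic: float  # into photosynthetic cells, per their volume
    flux_environment: float     # far field -> mixed layer, per trichome volume


def o2_exchange_segregated(
    o2_d: float, o2_p: float, params: FixedParameters,
    geometry: DiffusionGeometry | None = None,
    o2_mixed: float | None = None,
) -> SegregatedO2Fluxes:
    """Three-compartment O2 exchange of the segregated trichome.

    With the quasi-steady mixed layer (``o2_mixed=None``) the returned
    fluxes conserve O2 exactly: the volume-weighted sum of the two cell
    fluxes equals the environment flux.
    """
    if min(o2_d, o2_p) < 0:
        raise ValueError("O2 concentrations must be non-negative")
    geom = geometry or DiffusionGeometry.from_params(params)
    f_d = params.f_diazocyte
    g_m, g_b = geom.g_membrane, geom.g_boundary
    if o2_mixed is None:
        # g_m*(f_d*(o2_d - m) + (1-f_d)*(o2_p - m)) + g_b*(o2_ambient - m) = 0
        o2_mixed = (
            g_m * (f_d * o2_d + (1.0 - f_d) * o2_p) + g_b * params.o2_ambient
        ) / (g_m + g_b)
    return SegregatedO2Fluxes(
        o2_mixed=o2_mixed,
        flux_diazocyte=g_m * (o2_mixed - o2_d),
        flux_photosynthetic=g_m * (o2_mixed - o2_p),
        flux_environment=g_b * (params.o2_ambient - o2_mixed),
    )
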