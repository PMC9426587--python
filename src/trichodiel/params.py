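"""Model constants, optimizable parameters, and run configuration.

Every symbol used by the rate equations lives here, in SI units (seconds for
all internal rates; "per day" quantities are produced only by the simulator's
reporting layer).  Three groups:

``FixedParameters``
    Stoichiometric quotas, kinetic constants, trichome geometry, and
    environmental boundary conditions.  Quotas and boundary conditions are
    literature-constrained biochemistry; the light-curve, PET-capacity,
    storage-ceiling, and geometry constants are *calibrated* defaults (see
    the ``CALIBRATED`` set below and docs/methods.md) obtained by matching
    the model's daily outputs to published rates for this organism.

``FreeParameters``
    The four parameters that the growth-maximizing optimizer is allowed to
    move, with their documented bounds.

``RunConfig``
    Experiment plumbing: model variant, ablation switches, transfer-loss
    fraction, solver tolerances, output grid, and optimizer settings.

Values outside a documented bound are rejected at construction/load time,
never silently clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict, replace as _dc_replace
from typing import Any

import yaml

__all__ = [
    "FixedParameters",
    "FreeParameters",
    "RunConfig",
    "ParameterError",
    "load_config",
    "LoadedConfig",
    "default_optimized_parameters",
    "FREE_PARAMETER_BOUNDS",
]


class ParameterError(ValueError):
    """A parameter violated its documented range or the config schema."""


#: Bounds of the optimizable parameters (the optimizer's search box and the
#: validation range).  Half-saturation constants are bounded by the maximal
#: carbon that can be fixed over a diurnal cycle (1 mol C per mol C); the two
#: maximal rates by the maximal potential O2-production rate of PSII.
FREE_PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "k_cs_nf": (0.0, 1.0),
    "v_cs_max": (0.0, 5.0e-4),
    "k_ch2o_cs": (0.0, 1.0),
    "v_rp_max": (0.0, 5.0e-4),
}

#: Fixed-parameter names whose defaults are calibrated rather than taken from
#: primary literature.  ``experiments.calibrate_unknowns`` re-derives them.
CALIBRATED = {
    "v_pet_max", "alpha_i", "i_max", "beta_rp",
    "n_max", "cs_max", "d_o2", "radius", "l_membrane",
    "l_mixed", "length", "k_boundary",
}


@dataclass(frozen=True)
class FixedParameters:
    """Fixed stoichiometric, kinetic, geometric, and boundary constants.

    Units follow the coarse-grained convention of normalizing every cellular
    quantity to carbon biomass: pools are mol (mol C)^-1, rates are
    mol (mol C)^-1 s^-1, intracellular O2 is mol O2 m^-3.
    """

    # --- per-electron yields of the two photosynthetic electron routes ---
    q_atp_lpet: float = 0.65     # mol ATP per mol e- through linear PET
    q_nadph_lpet: float = 0.5    # mol NADPH per mol e- through linear PET
    q_o2_lpet: float = 0.25      # mol O2 per mol e- through linear PET
    q_atp_aet: float = 0.65      # mol ATP per mol e- through Mehler-type AET

    # --- process stoichiometries ---
    q_atp_nf: float = 9.0        # mol ATP per mol N fixed (N2 -> glutamate)
    q_nadph_nf: float = 3.0      # mol NADPH per mol N fixed
    q_atp_cf: float = 3.0        # mol ATP per mol C fixed (Calvin-Benson)
    q_nadph_cf: float = 2.0      # mol NADPH per mol C fixed
    # CCM surcharge: 50% Ci leakage doubles gross uptake, 80% of Ci enters as
    # HCO3- at 0.5 ATP per ion -> (1/0.5)*0.8*0.5 = 0.8 ATP per net fixed C.
    q_atp_ccm: float = 0.8
    q_atp_bio: float = 2.0       # mol ATP per mol C of biomass synthesized
    q_atp_resp: float = 5.0      # mol ATP per mol C of carbohydrate respired
    q_o2_rp: float = 1.0         # mol O2 per mol C respired (CH2O + O2 -> CO2 + H2O)
    gamma_mt: float = 0.10       # maintenance surcharge on process ATP

    # --- elemental composition and environment ---
    nc_ratio: float = 0.159      # mol N per mol C of biomass (Redfield-type)
    c_density: float = 18333.0   # cellular carbon density Q_C, mol C m^-3
    o2_ambient: float = 0.213    # far-field O2, mol m^-3 (34 PSU, 25 degC)

    # --- O2 regulation ---
    k_o2_nf: float = 1.0e-2      # half-saturation of O2 inhibition on NF, mol m^-3
    epsilon: float = 1.0e-4      # membrane/seawater O2 diffusivity ratio

    # --- light and PET capacity (calibrated) ---
    i_max: float = 2000.0        # peak irradiance, umol photons m^-2 s^-1
    alpha_i: float = 4.99e-4     # initial slope of the P-I curve, (umol m^-2 s^-1)^-1
    v_pet_max: float = 2.0e-3    # light-saturated PET capacity, mol e- (mol C)^-1 s^-1
    beta_rp: float = 2.0e4       # PET-inhibition strength of RP, s

    # --- storage ceilings (calibrated) ---
    n_max: float = 0.1536        # maximal fixed-N storage, mol N (mol C)^-1
    cs_max: float = 0.739        # maximal carbon-skeleton storage, mol C (mol C)^-1

    # --- trichome geometry and diffusion (calibrated) ---
    d_o2: float = 2.1e-9         # O2 diffusivity in seawater, m^2 s^-1
    radius: float = 6.90e-6      # cytoplasm radius R, m
    l_membrane: float = 5.0e-8   # cell membrane/envelope thickness L_g, m
    k_boundary: float = 1024.0   # boundary-layer rule L_b = k_boundary*(R+L_g)
    l_mixed: float = 1.0e-7      # mixed-layer thickness L_m (segregated variant), m
    length: float = 1.0e-3       # trichome length L, m
    volume: float | None = None  # trichome volume V, m^3; default pi R^2 L

    # --- diel forcing and diazocyte fraction ---
    t_light: float = 43200.0     # light-period duration, s (12 h)
    f_diazocyte: float = 0.15    # diazocyte fraction of cells (segregated variant)

    def __post_init__(self) -> None:
        for name in (
            "q_atp_lpet", "q_nadph_lpet", "q_o2_lpet", "q_atp_aet",
            "q_atp_nf", "q_nadph_nf", "q_atp_cf", "q_nadph_cf", "q_atp_ccm",
            "q_atp_bio", "q_atp_resp", "q_o2_rp", "nc_ratio", "c_density",
            "o2_ambient", "k_o2_nf", "i_max", "alpha_i", "v_pet_max",
            "beta_rp", "n_max", "cs_max", "d_o2", "radius", "l_membrane",
            "k_boundary", "l_mixed", "length", "t_light",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be a positive finite number, got {v!r}")
        for name in ("gamma_mt", "epsilon", "f_diazocyte"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        if not (0.0 < self.f_diazocyte < 1.0):
            raise ParameterError("f_diazocyte must lie strictly in (0, 1)")
        cyl = math.pi * self.radius**2 * self.length
        if self.volume is None:
            object.__setattr__(self, "volume", cyl)
        elif abs(self.volume - cyl) > 1e-3 * cyl:
            raise ParameterError(
                f"volume={self.volume!r} inconsistent with cylinder pi*R^2*L={cyl:.4e}"
            )

    @property
    def l_boundary(self) -> float:
        """Boundary-layer thickness L_b = k_boundary * (R + L_g), m."""
        return self.k_boundary * (self.radius + self.l_membrane)

    @property
    def lpet_atp_nadph_ratio(self) -> float:
        """ATP:NADPH yield ratio of pure linear PET (0.65/0.5 = 1.3)."""
        return self.q_atp_lpet / self.q_nadph_lpet

    def replace(self, **kw: Any) -> "FixedParameters":
        # re-derive the cylinder volume unless the caller pins it explicitly
        if ("radius" in kw or "length" in kw) and "volume" not in kw:
            kw["volume"] = None
        return _dc_replace(self, **kw)


@dataclass(frozen=True)
class FreeParameters:
    """The four growth-optimizable parameters with their documented bounds."""

    k_cs_nf: float = 0.06       # half-saturation of carbon skeleton for NF, mol C (mol C)^-1
    v_cs_max: float = 3.7e-6    # maximal carbon-skeleton synthesis rate, s^-1
    k_ch2o_cs: float = 0.58     # half-saturation of carbohydrate for CS synthesis
    v_rp_max: float = 4.5e-4    # maximal respiratory-protection rate, s^-1

    def __post_init__(self) -> None:
        for name, (lo, hi) in FREE_PARAMETER_BOUNDS.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ParameterError(f"{name} must be finite, got {v!r}")
            if not (lo <= v <= hi):
                raise ParameterError(f"{name}={v!r} outside documented bounds [{lo}, {hi}]")

    def replace(self, **kw: Any) -> "FreeParameters":
        return _dc_replace(self, **kw)

    def as_array(self):
        import numpy as np

        return np.array([self.k_cs_nf, self.v_cs_max, self.k_ch2o_cs, self.v_rp_max])

    @classmethod
    def from_array(cls, x) -> "FreeParameters":
        return cls(k_cs_nf=float(x[0]), v_cs_max=float(x[1]),
                   k_ch2o_cs=float(x[2]), v_rp_max=float(x[3]))


def default_optimized_parameters(variant: str) -> FreeParameters:
    """Growth-maximizing parameter set for a model variant.

    The maximal respiratory-protection rate is the only parameter that
    differs between the unified trichome (4.5e-4 s^-1) and the spatially
    segregated one (4.0e-4 s^-1): confining nitrogenase to diazocytes lowers
    the respiratory protection the trichome needs.
    """
    if variant == "unified":
        return FreeParameters(v_rp_max=4.5e-4)
    if variant == "segregated":
        return FreeParameters(v_rp_max=4.0e-4)
    raise ParameterError(f"unknown variant {variant!r}; expected 'unified' or 'segregated'")


@dataclass(frozen=True)
class RunConfig:
    """Switches and numerics for one simulation/experiment run."""

    variant: str = "unified"          # 'unified' | 'segregated'
    transfer_loss: float = 0.0        # loss fraction of intercellularly transferred materials
    ablate_rp: bool = False           # no respiratory protection
    ablate_aet: bool = False          # force all electrons through linear PET
    nf_in_photo: bool = False         # allow NF in photosynthetic cells (reduction check)
    rtol: float = 1.0e-6              # ODE relative tolerance
    atol_pool: float = 1.0e-10        # ODE absolute tolerance for C/N pools
    atol_o2: float = 1.0e-9           # ODE absolute tolerance for O2, mol m^-3
    output_dt: float = 60.0           # output grid spacing, s
    seed: int = 42
    n_starts: int = 64                # multistart optimizer start count

    def __post_init__(self) -> None:
        if self.variant not in ("unified", "segregated"):
            raise ParameterError(f"unknown variant {self.variant!r}")
        if not (0.0 <= self.transfer_loss <= 0.8):
            raise ParameterError(
                f"transfer_loss={self.transfer_loss!r} outside documented range [0, 0.8]"
            )
        if self.transfer_loss > 0.0 and self.variant != "segregated":
            raise ParameterError("transfer_loss is only meaningful for the segregated variant")
        for name in ("rtol", "atol_pool", "atol_o2", "output_dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_starts < 1:
            raise ParameterError("n_starts must be >= 1")

    def replace(self, **kw: Any) -> "RunConfig":
        return _dc_replace(self, **kw)


@dataclass(frozen=True)
class LoadedConfig:
    fixed: FixedParameters
    free: FreeParameters
    run: RunConfig
    #: provenance of every field: 'file' if supplied, 'default' otherwise
    provenance: dict[str, str] = field(default_factory=dict)


def _field_names(cls) -> list[str]:
    return [f.name for f in fields(cls)]


def load_config(path: str | Any) -> LoadedConfig:
    """Load a flat YAML/JSON mapping into validated parameter objects.

    The namespace is flat: any key matching a ``FixedParameters``,
    ``FreeParameters``, or ``RunConfig`` field is routed to that object;
    unknown keys raise.  Omitted fields take the documented defaults and are
    recorded as such in ``LoadedConfig.provenance``.
    """
    if hasattr(path, "read"):
        raw = yaml.safe_load(path.read())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config must be a mapping, got {type(raw).__name__}")
    return config_from_mapping(raw)


def config_from_mapping(raw: dict[str, Any]) -> LoadedConfig:
    groups = {
        FixedParameters: _field_names(FixedParameters),
        FreeParameters: _field_names(FreeParameters),
        RunConfig: _field_names(RunConfig),
    }
    kwargs: dict[type, dict[str, Any]] = {cls: {} for cls in groups}
    provenance: dict[str, str] = {}
    for key, value in raw.items():
        for cls, names in groups.items():
            if key in names:
                kwargs[cls][key] = value
                provenance[key] = "file"
                break
        else:
            raise ParameterError(f"unknown config key {key!r}")
    for cls, names in groups.items():
        for name in names:
            provenance.setdefault(name, "default")
    if "variant" in kwargs[RunConfig] and "v_rp_max" not in kwargs[FreeParameters]:
        # the variant-dependent optimized default for v_rp_max
        variant = kwargs[RunConfig]["variant"]
        kwargs[FreeParameters]["v_rp_max"] = default_optimized_parameters(variant).v_rp_max
    return LoadedConfig(
        fixed=FixedParameters(**kwargs[FixedParameters]),
        free=FreeParameters(**kwargs[FreeParameters]),
        run=RunConfig(**kwargs[RunConfig]),
        provenance=provenance,
    )


def serialize_config(cfg: LoadedConfig) -> str:
    """Flat-YAML dump such that ``load_config`` round-trips every field."""
    flat: dict[str, Any] = {}
    flat.update(asdict(cfg.fixed))
    flat.update(asdict(cfg.free))
    flat.update(asdict(cfg.run))
    return yaml.safe_dump(flat, sort_keys=True)
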