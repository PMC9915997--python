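"""Versioned YAML configuration schema for the simulator.

Inputs use SI-flavoured units (N/m, N*m, Pa, Pa*s, um, s, pN) and are
converted to internal pN-um-s units exactly once, here.  Validation
errors name the offending field.  ``schema_version`` must match
:data:`SCHEMA_VERSION` exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import units

SCHEMA_VERSION = 1

__all__ = [
    "SCHEMA_VERSION",
    "SimConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "reduced_preset",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class DomainConfig(BaseModel):
    extents_um: tuple[float, float, float] = (120.0, 120.0, 60.0)
    youngs_modulus_pa: float = 100.0  # .inf -> rigid box
    elastic_thickness_um: float = 10.0
    relax_rate_per_s: float = 1.0
    wall_strength_pn_per_um: float = 100.0
    anchor_tolerance_um: float = 0.5

    @field_validator("extents_um")
    @classmethod
    def _positive_extents(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("domain extents must be positive")
        return v


class ConstantsConfig(BaseModel):
    kBT_pn_um: float = units.KBT_300K
    viscosity_pa_s: float = 0.86  # cytoplasm-like placeholder; not printed
    dt_s: Optional[float] = None  # None -> dt_safety * min(zeta / k_s)
    dt_safety: float = 0.1
    thermal: bool = True


class FiberConfig(BaseModel):
    ks_n_per_m: float = 0.277
    kb_n_m: float = 8.12e-20
    rest_length_um: float = 1.0
    diameter_um: float = 0.060
    count: int = 300
    segments_per_fiber: int = 3


class CrosslinkerConfig(BaseModel):
    ks_n_per_m: float = 2.0e-3
    kb_n_m: float = 1.04e-19
    rest_length_um: float = 0.230
    max_distance_um: Optional[float] = None  # None -> 1.5 * rest length
    max_count: Optional[int] = None


class MembraneConfig(BaseModel):
    ks_n_per_m: float = 0.001
    kb_n_m: float = 10e-19
    edge_length_um: float = 1.0
    thickness_um: float = 0.2
    z_um: float = 30.0


class RepulsionConfig(BaseModel):
    fiber_fiber_n_per_m: float = 1.69e-4
    fiber_membrane_n_per_m: float = 4.0e-4


class CellsConfig(BaseModel):
    enabled: bool = True
    radius_um: float = 2.0
    interaction_distance_um: float = 4.0
    force_pn: float = 100.0
    k_on_per_s: float = 0.03
    # zero-force off-rate and Bell force sensitivity are not printed in the
    # source model: they are required whenever cells are enabled
    k_off0_per_s: float = Field(...)
    x_bell_um: float = Field(...)
    drag_pn_s_per_um: Optional[float] = None  # None -> Stokes 6 pi mu R
    d_c_um: float = 40.0
    z_um: Optional[float] = None  # None -> membrane z / 2


class ProtocolConfig(BaseModel):
    assembly_duration_s: float = 100.0
    interaction_duration_s: float = 200.0
    snapshot_stride_s: float = 1.0


class SimConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    domain: DomainConfig = DomainConfig()
    constants: ConstantsConfig = ConstantsConfig()
    fiber: FiberConfig = FiberConfig()
    crosslinker: CrosslinkerConfig = CrosslinkerConfig()
    membrane: MembraneConfig = MembraneConfig()
    repulsion: RepulsionConfig = RepulsionConfig()
    coupling_radius_um: float = 0.380
    cells: CellsConfig = CellsConfig(k_off0_per_s=0.1, x_bell_um=1.0e-4)
    protocol: ProtocolConfig = ProtocolConfig()

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v):
        if v != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {v}; this build reads version {SCHEMA_VERSION}"
            )
        return v

    # -- converted (internal-unit) views -----------------------------------
    @property
    def fiber_ks(self) -> float:
        return self.fiber.ks_n_per_m * units.N_PER_M

    @property
    def fiber_kb(self) -> float:
        return self.fiber.kb_n_m * units.N_M

    @property
    def crosslinker_ks(self) -> float:
        return self.crosslinker.ks_n_per_m * units.N_PER_M

    @property
    def crosslinker_kb(self) -> float:
        return self.crosslinker.kb_n_m * units.N_M

    @property
    def membrane_ks(self) -> float:
        return self.membrane.ks_n_per_m * units.N_PER_M

    @property
    def membrane_kb(self) -> float:
        return self.membrane.kb_n_m * units.N_M

    @property
    def kr_fiber_fiber(self) -> float:
        return self.repulsion.fiber_fiber_n_per_m * units.N_PER_M

    @property
    def kr_fiber_membrane(self) -> float:
        return self.repulsion.fiber_membrane_n_per_m * units.N_PER_M


def load_config(source: str | Path | dict) -> SimConfig:
    """Parse and validate a YAML file, YAML string, or mapping."""
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    try:
        return SimConfig.model_validate(raw)
    except ValidationError as exc:
        names = ", ".join(
            ".".join(str(loc) for loc in err["loc"]) for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration field(s): {names}\n{exc}") from exc


def dump_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))


def reduced_preset(
    d_c_um: float = 12.0,
    seed: int = 0,
    extents: Sequence[float] = (40.0, 40.0, 20.0),
    cells_enabled: bool = True,
) -> SimConfig:
    """Desk-scale two-cell preset.

    Runs the full protocol on one CPU in minutes by (a) shrinking the
    domain, (b) softening all extensional stiffnesses by a common factor so
    the explicit-Euler stability bound allows a millisecond-scale timestep,
    and (c) shortening both protocol phases.  Contractile force, thermal
    energy, binding kinetics and all bending stiffnesses keep their
    full-scale values, so network strains are larger than at full stiffness
    but the contraction/remodeling phenomenology is preserved.  The
    cross-link search distance is widened so the sparse desk-scale matrix
    percolates.
    """
    soft = 1.0 / 3000.0  # extensional softening factor
    extents = tuple(float(x) for x in extents)
    z_mem = extents[2] / 2.0
    return SimConfig(
        seed=seed,
        domain=DomainConfig(
            extents_um=extents,
            youngs_modulus_pa=100.0,
            elastic_thickness_um=5.0,
            wall_strength_pn_per_um=20.0,
            anchor_tolerance_um=0.5,
        ),
        constants=ConstantsConfig(),
        fiber=FiberConfig(
            ks_n_per_m=0.277 * soft,
            count=250,
            segments_per_fiber=4,
        ),
        crosslinker=CrosslinkerConfig(
            # softened only 100x (not 3000x) so desk-scale links stay
            # force-bearing; stability is set by the softer membrane springs
            ks_n_per_m=2.0e-3 / 100.0,
            max_distance_um=2.0,
        ),
        membrane=MembraneConfig(
            ks_n_per_m=0.001 / 100.0,
            edge_length_um=2.0,
            z_um=z_mem,
        ),
        repulsion=RepulsionConfig(
            fiber_fiber_n_per_m=1.69e-4 / 30.0,
            fiber_membrane_n_per_m=4.0e-4 / 30.0,
        ),
        # cells sit at 0.7 z_mem so their interaction shell reaches the
        # membrane-coupled fiber layer; coupling radius widened with the
        # coarser (2 um) membrane mesh
        coupling_radius_um=0.8,
        cells=CellsConfig(
            enabled=cells_enabled,
            d_c_um=d_c_um,
            k_off0_per_s=0.1,
            x_bell_um=1.0e-4,
            # adhesion-dominated effective drag (a free Stokes sphere would
            # crawl at ~1 um/s under a single 100 pN link, far faster than
            # a real cell); slows migration so matrix tension is sustained
            drag_pn_s_per_um=160.0,
            z_um=0.7 * z_mem,
        ),
        protocol=ProtocolConfig(
            assembly_duration_s=15.0,
            interaction_duration_s=60.0,
            snapshot_stride_s=1.0,
        ),
    )
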