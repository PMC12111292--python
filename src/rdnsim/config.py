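"""Scenario definition and validation.

Every input of the simulation is a parameter: material properties of the
media involved (blood, abdominal soft tissue, agar gel, gold electrodes),
the vessel/domain geometry, the electrode layout, the flow condition, and
the generator's temperature-control settings.  This module collects those
parameters into validated, serializable scenario presets:

``in_vivo``
    A 6 mm renal artery crossing a 26 x 26 x 30 mm block of abdominal
    tissue, blood flowing at a mean 0.5 m/s, body temperature 37 degC,
    six gold electrodes apposed to the lumen wall, 60 degC setpoint,
    120 s ablation, 45 degC lesion threshold.

``phantom``
    The same vascular channel cast in a tissue-mimicking agar block at
    room temperature (25 degC) with no flow; the channel is filled with a
    static saline-like medium given blood's electrical/thermal properties.

All lengths at this boundary are millimetres; the solvers convert to SI
once, at discretization time.
"""

from __future__ import annotations

import json
from typing import Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "MaterialProperties",
    "ElectrodeLayout",
    "ControlSettings",
    "ScenarioConfig",
    "UnknownMaterialError",
    "material_preset",
    "build_scenario",
    "validate_config",
    "config_to_yaml",
    "config_from_yaml",
    "config_to_json",
    "config_from_json",
    "MATERIAL_TABLE",
]


class UnknownMaterialError(KeyError):
    """Raised when a material preset name is not recognized."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class MaterialProperties(_Model):
    """Bulk properties of one medium.

    Attributes
    ----------
    rho : float
        Mass density, kg/m^3.
    sigma : float
        Electrical conductivity, S/m.
    c : float
        Specific heat capacity, J/(kg*degC).
    k : float
        Thermal conductivity, W/(m*degC).
    eps_r : float
        Relative permittivity (dimensionless).  Carried as metadata only:
        at 470 kHz the displacement current is negligible next to the
        conduction current, so the field problem is purely resistive and
        ``eps_r`` never enters the solve.
    """

    name: str
    rho: float = Field(gt=0)
    sigma: float = Field(ge=0)
    c: float = Field(gt=0)
    k: float = Field(gt=0)
    eps_r: float = Field(ge=1)


#: Material property table: density, electrical conductivity, specific
#: heat, thermal conductivity, relative permittivity.
MATERIAL_TABLE: Mapping[str, MaterialProperties] = {
    "blood": MaterialProperties(
        name="blood", rho=1050, sigma=0.99, c=4180, k=0.54, eps_r=58.3
    ),
    "abdominal": MaterialProperties(
        name="abdominal", rho=1060, sigma=1.69, c=3600, k=0.512, eps_r=43.03
    ),
    "agar": MaterialProperties(
        name="agar", rho=1300, sigma=2.3, c=4182, k=0.6, eps_r=57.99
    ),
    "gold": MaterialProperties(
        name="gold", rho=19300, sigma=4.1e7, c=127, k=315, eps_r=1.0
    ),
}


def material_preset(name: str) -> MaterialProperties:
    """Return the tabulated properties of a named medium.

    Parameters
    ----------
    name : str
        One of ``blood``, ``abdominal``, ``agar``, ``gold``.

    Raises
    ------
    UnknownMaterialError
        If the name is not in the table; the message lists valid names.
    """
    try:
        return MATERIAL_TABLE[name].model_copy(deep=True)
    except KeyError:
        valid = ", ".join(sorted(MATERIAL_TABLE))
        raise UnknownMaterialError(
            f"unknown material {name!r}; valid names: {valid}"
        ) from None


class ElectrodeLayout(_Model):
    """Geometry of the expandable multi-electrode basket.

    The device carries ``count`` small rectangular electrode patches on a
    mesh basket that apposes them to the lumen wall, successive patches
    rotated by ``angular_spacing`` and shifted axially by ``axial_pitch``
    (a helical ribbon).  Patch dimensions are not published for the
    device; the defaults are a typical band-electrode scale chosen so the
    six-patch helix spans ~5 mm axially, consistent with the 6-8 mm
    ablation band observed in gel phantoms.  All lengths in mm.
    """

    count: int = Field(default=6, ge=1)
    angular_spacing: float = Field(default=60.0, gt=0)
    axial_pitch: float = Field(default=1.0, gt=0)
    electrode_length: float = Field(default=1.5, gt=0)
    electrode_arc: float = Field(default=1.0, gt=0)
    electrode_thickness: float = Field(default=0.15, gt=0)
    #: mm from the artery axis; None means wall apposition (lumen radius).
    radial_position: Optional[float] = Field(default=None)

    @model_validator(mode="after")
    def _closes_circle(self) -> "ElectrodeLayout":
        if self.radial_position is not None and self.radial_position <= 0:
            raise ValueError("radial_position must be positive when given")
        if self.count * self.angular_spacing > 360.0 + self.angular_spacing:
            raise ValueError(
                "count x angular_spacing overfills the circle: "
                f"{self.count} x {self.angular_spacing} > 360 + spacing"
            )
        return self


class ControlSettings(_Model):
    """Temperature feedback control of the RF generator.

    The generator adjusts delivered power to hold the electrode surface
    temperature at ``setpoint``.  Since deposited power scales with the
    square of the drive amplitude, the PI law acts on the squared
    amplitude u = a^2 (volts^2): incremental update
    ``u += kp * (e - e_prev) + ki * e * dt`` with e = setpoint - measured,
    clamped to [0, max_amplitude^2] (clamping the command is the
    anti-windup).  ``mode='common'`` drives all electrodes at one
    amplitude from the hottest probe (a single source voltage on all
    electrode surfaces); ``mode='per-electrode'`` regulates each channel
    independently.
    """

    setpoint: float = Field(default=60.0)
    kp: float = Field(default=3.0, ge=0)
    ki: float = Field(default=0.8, ge=0)
    max_amplitude: float = Field(default=30.0, gt=0)
    max_power_per_electrode: float = Field(default=15.0, gt=0)
    update_interval: float = Field(default=0.1, gt=0)
    #: the generator has one independently regulated source per electrode
    mode: Literal["common", "per-electrode"] = "per-electrode"
    #: electrode probe statistic over face-adjacent tissue cells
    probe: Literal["mean", "max"] = "mean"


class ScenarioConfig(_Model):
    """Complete, validated description of one ablation simulation."""

    scenario_kind: Literal["in_vivo", "phantom"] = "in_vivo"
    domain_size: tuple[float, float, float] = (26.0, 26.0, 30.0)
    artery_diameter: float = Field(default=6.0, gt=0)
    layout: ElectrodeLayout = Field(default_factory=ElectrodeLayout)
    materials: dict[str, MaterialProperties] = Field(default_factory=dict)
    inlet_mean_velocity: float = Field(default=0.5, ge=0)
    flow_profile: Literal["parabolic", "plug"] = "parabolic"
    #: RF excitation frequency, Hz.  Metadata only (resistive model).
    frequency: float = Field(default=470e3, gt=0)
    initial_temperature: float = 37.0
    boundary_temperature: float = 37.0
    duration: float = Field(default=120.0)
    timestep: float = Field(default=0.1)
    grid_spacing: float = Field(default=0.5)
    lesion_threshold: float = 45.0
    control: ControlSettings = Field(default_factory=ControlSettings)
    #: times (s) at which lesion depth is sampled during a run
    sample_times: tuple[float, ...] = (5.0, 30.0, 60.0, 120.0)

    @model_validator(mode="after")
    def _invariants(self) -> "ScenarioConfig":
        dx, dy, dz = self.domain_size
        if min(dx, dy, dz) <= 0:
            raise ValueError("domain_size: all extents must be positive")
        if self.artery_diameter >= min(dx, dy):
            raise ValueError(
                "artery_diameter: must be smaller than the transverse "
                f"domain extent (got {self.artery_diameter} mm vs "
                f"{min(dx, dy)} mm domain)"
            )
        if self.duration <= 0:
            raise ValueError("duration: must be positive")
        if self.timestep <= 0:
            raise ValueError("timestep: must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing: must be positive")
        if self.lesion_threshold <= self.initial_temperature:
            raise ValueError(
                "lesion_threshold: must exceed initial_temperature "
                f"({self.lesion_threshold} <= {self.initial_temperature})"
            )
        if self.control.setpoint <= self.initial_temperature:
            raise ValueError(
                "control.setpoint: must exceed initial_temperature "
                f"({self.control.setpoint} <= {self.initial_temperature})"
            )
        for region in ("lumen", "tissue", "electrode"):
            if self.materials and region not in self.materials:
                raise ValueError(f"materials: missing region {region!r}")
        return self

    @property
    def lumen_radius(self) -> float:
        """Lumen radius, mm."""
        return self.artery_diameter / 2.0


def _deep_merge(base: dict, overrides: Mapping) -> dict:
    out = dict(base)
    for key, value in overrides.items():
        if (
            key in out
            and isinstance(out[key], dict)
            and isinstance(value, Mapping)
        ):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def build_scenario(
    kind: Literal["in_vivo", "phantom"],
    overrides: Optional[Mapping] = None,
) -> ScenarioConfig:
    """Build a preset scenario, optionally overriding any field.

    ``overrides`` is a (possibly nested) mapping merged on top of the
    preset before validation, e.g. ``{"duration": 30, "control":
    {"setpoint": 55}}``.  Unknown fields or invariant violations raise a
    validation error naming the offending field.
    """
    if kind == "in_vivo":
        base = dict(
            scenario_kind="in_vivo",
            materials={
                "lumen": material_preset("blood").model_dump(),
                "tissue": material_preset("abdominal").model_dump(),
                "electrode": material_preset("gold").model_dump(),
            },
            inlet_mean_velocity=0.5,
            initial_temperature=37.0,
            boundary_temperature=37.0,
        )
    elif kind == "phantom":
        # Channel filled with a static saline-like medium (blood-equivalent
        # properties); agar everywhere else; room temperature; no flow.
        saline = material_preset("blood").model_dump()
        saline["name"] = "channel-saline"
        base = dict(
            scenario_kind="phantom",
            materials={
                "lumen": saline,
                "tissue": material_preset("agar").model_dump(),
                "electrode": material_preset("gold").model_dump(),
            },
            inlet_mean_velocity=0.0,
            initial_temperature=25.0,
            boundary_temperature=25.0,
        )
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    merged = _deep_merge(base, overrides or {})
    return ScenarioConfig.model_validate(merged)


def validate_config(config: ScenarioConfig) -> ScenarioConfig:
    """Re-run all invariant checks; return the config unchanged if valid."""
    ScenarioConfig.model_validate(config.model_dump())
    return config


# ---------------------------------------------------------------------------
# serialization

def config_to_yaml(config: ScenarioConfig) -> str:
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


def config_from_yaml(text: str) -> ScenarioConfig:
    return ScenarioConfig.model_validate(yaml.safe_load(text))


def config_to_json(config: ScenarioConfig) -> str:
    return json.dumps(config.model_dump(mode="json"), sort_keys=True, indent=2)


def config_from_json(text: str) -> ScenarioConfig:
    return ScenarioConfig.model_validate(json.loads(text))
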