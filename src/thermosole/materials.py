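"""Thermophysical material properties for tissue, lesion and insole layers.

The bioheat model treats every material as a volumetric continuum with a
conductive term and, for living tissue, a blood-perfusion heat sink
``rho_b * C_pb * omega_b * (T_b - T)`` plus a metabolic source ``Q_met``.
Non-biological materials (insole polymers, copper, shoe rubber) carry zero
perfusion and zero metabolic heat.

The module ships the published property sets used throughout the package:
five plantar tissue layers (epidermis .. muscle), two lesion types
(inflammation, ischemia) and the four insole/shoe materials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MaterialProps",
    "BloodProps",
    "LayerSpec",
    "TISSUE",
    "LESION",
    "INSOLE",
    "foot_tissue_layers",
    "insole_shoe_layers",
    "DEFAULT_BLOOD",
]


@dataclass(frozen=True)
class MaterialProps:
    """Volumetric thermophysical parameters of one material.

    Parameters
    ----------
    name : str
        Label used in grids, reports and region summaries.
    density : float
        kg/m^3, > 0.
    thermal_conductivity : float
        W/m/K, > 0.
    specific_heat : float
        J/kg/K, > 0 (enters only through the perfusion product for the
        steady problem, but is validated for completeness).
    metabolic_heat : float
        Volumetric metabolic source Q_met, W/m^3, >= 0.
    perfusion_rate : float
        Blood perfusion rate omega_b, 1/s, >= 0.
    blood_temperature : float
        Arterial blood temperature T_b in degC toward which perfusion pulls
        the tissue (35 degC inside an ischemic lesion, 37 degC elsewhere).
    """

    name: str
    density: float
    thermal_conductivity: float
    specific_heat: float
    metabolic_heat: float = 0.0
    perfusion_rate: float = 0.0
    blood_temperature: float = 37.0
    biological: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if self.thermal_conductivity <= 0:
            raise ValueError(f"{self.name}: thermal_conductivity must be > 0")
        if self.specific_heat <= 0:
            raise ValueError(f"{self.name}: specific_heat must be > 0")
        if self.metabolic_heat < 0:
            raise ValueError(f"{self.name}: metabolic_heat must be >= 0")
        if self.perfusion_rate < 0:
            raise ValueError(f"{self.name}: perfusion_rate must be >= 0")
        if not self.biological and (self.metabolic_heat != 0 or self.perfusion_rate != 0):
            raise ValueError(
                f"{self.name}: non-biological materials must have zero "
                "metabolic heat and perfusion"
            )

    @property
    def is_perfused(self) -> bool:
        return self.perfusion_rate > 0

    def equilibrium_temperature(self, blood: "BloodProps") -> float:
        """Zero-flux equilibrium T_b + Q_met / (rho_b C_pb omega_b).

        Only defined for perfused materials; this is the temperature a
        fully insulated block of the material relaxes to.
        """
        if not self.is_perfused:
            raise ValueError(f"{self.name} is not perfused; no finite equilibrium")
        return self.blood_temperature + self.metabolic_heat / (
            blood.density * blood.specific_heat * self.perfusion_rate
        )

    def with_blood_temperature(self, t_b: float) -> "MaterialProps":
        return replace(self, blood_temperature=t_b)


@dataclass(frozen=True)
class BloodProps:
    """Blood density and specific heat entering the perfusion sink.

    These two values are not part of the published tissue tables; the
    defaults are the standard human whole-blood values and are configurable
    because the perfused-tissue equilibrium offset Q_met/(rho_b C_pb omega_b)
    depends directly on them.
    """

    density: float = 1050.0  # kg/m^3
    specific_heat: float = 3617.0  # J/kg/K

    def __post_init__(self) -> None:
        if self.density <= 0 or self.specific_heat <= 0:
            raise ValueError("blood density and specific heat must be > 0")

    @property
    def volumetric_heat_capacity(self) -> float:
        return self.density * self.specific_heat


DEFAULT_BLOOD = BloodProps()


@dataclass(frozen=True)
class LayerSpec:
    """One horizontal layer of the stack: a material and its thickness (m)."""

    material: MaterialProps
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(
                f"layer {self.material.name}: thickness must be > 0, "
                f"got {self.thickness}"
            )


# --- published property tables ------------------------------------------------
# Plantar tissue layers (ordering here is by depth below the skin surface).
# Columns: specific heat J/kg/K, conductivity W/m/K, density kg/m^3,
# metabolic heat W/m^3, perfusion rate 1/s, and the layer thickness in m.

TISSUE: dict[str, MaterialProps] = {
    "epidermis": MaterialProps("epidermis", 1200.0, 0.235, 3589.0, 0.0, 0.0),
    "papillary_dermis": MaterialProps(
        "papillary_dermis", 1200.0, 0.445, 3300.0, 368.1, 0.18e-3
    ),
    "reticular_dermis": MaterialProps(
        "reticular_dermis", 1200.0, 0.445, 3300.0, 368.1, 1.26e-3
    ),
    "fat": MaterialProps("fat", 1000.0, 0.185, 2674.0, 368.3, 0.08e-3),
    "muscle": MaterialProps("muscle", 1085.0, 0.51, 3600.0, 684.2, 2.7e-3),
}

#: Lesion materials.  The ischemic lesion additionally has its arterial blood
#: temperature lowered to 35 degC.
LESION: dict[str, MaterialProps] = {
    "inflammation": MaterialProps(
        "inflammation", 1037.0, 0.558, 2450.0, 5262.5, 6.95e-3
    ),
    "ischemia": MaterialProps(
        "ischemia", 1037.0, 0.1, 2450.0, 342.1, 0.405e-3, blood_temperature=35.0
    ),
}

INSOLE: dict[str, MaterialProps] = {
    "polyurethane": MaterialProps(
        "polyurethane", 374.0, 0.06, 1337.0, biological=False
    ),
    "kapton": MaterialProps("kapton", 1300.0, 0.15, 1100.0, biological=False),
    "copper": MaterialProps("copper", 8960.0, 401.0, 384.0, biological=False),
    "rubber": MaterialProps("rubber", 1100.0, 0.13, 2010.0, biological=False),
}

#: Tissue thicknesses, m, skin surface inward.
_TISSUE_THICKNESS = {
    "epidermis": 0.46e-3,
    "papillary_dermis": 1.67e-3,
    "reticular_dermis": 1.67e-3,
    "fat": 5.0e-3,
    "muscle": 25.0e-3,
}


def foot_tissue_layers() -> list[LayerSpec]:
    """Tissue stack ordered top (deep muscle) to bottom (plantar epidermis).

    The grid z axis points downward, from deep muscle through the skin
    surface into the insole, so the deepest tissue comes first.
    """
    order = ["muscle", "fat", "reticular_dermis", "papillary_dermis", "epidermis"]
    return [LayerSpec(TISSUE[n], _TISSUE_THICKNESS[n]) for n in order]


def insole_shoe_layers(rubber_thickness: float = 15.0e-3) -> list[LayerSpec]:
    """Insole stack plus shoe sole, top (foot side) to bottom (floor side).

    1 mm antibacterial polyurethane upper, 0.36 mm kapton flex board,
    18 um copper circuit layer, 3 mm polyurethane bottom, and the rubber
    shoe sole underneath.
    """
    pu = INSOLE["polyurethane"]
    return [
        LayerSpec(pu, 1.0e-3),
        LayerSpec(INSOLE["kapton"], 0.36e-3),
        LayerSpec(INSOLE["copper"], 0.018e-3),
        LayerSpec(pu, 3.0e-3),
        LayerSpec(INSOLE["rubber"], rubber_thickness),
    ]
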