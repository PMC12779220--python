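"""Oxygen unit conversions and the physical constants shared by every module.

All solvers and design formulas in this package work in a single internal
unit system (SI: metres, seconds, mol·m⁻³).  Probe hardware and the
literature report oxygen in three interchangeable ways:

* ``percent_air_saturation`` — optode readout relative to water
  equilibrated with dry air (O₂ fraction 0.2095) at the calibration
  temperature;
* ``mmHg`` — oxygen partial pressure;
* ``mol_per_m3`` — dissolved concentration, related to partial pressure by
  a Henry-law solubility (mol·m⁻³·mmHg⁻¹) at 37 °C.

This module is the single authority for those conversions, so downstream
code never mixes unit systems.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "PERCENT_AIR_SATURATION",
    "MMHG",
    "MOL_PER_M3",
    "UNITS",
    "DRY_AIR_O2_FRACTION",
    "OxygenAmount",
    "ConstantsRegistry",
    "DEFAULT_CONSTANTS",
    "registry_from_mapping",
    "convert_oxygen",
    "ambient_concentration",
    "critical_concentration",
    "UnknownUnitError",
    "NegativeOxygenError",
]

PERCENT_AIR_SATURATION = "percent_air_saturation"
MMHG = "mmHg"
MOL_PER_M3 = "mol_per_m3"
UNITS = frozenset({PERCENT_AIR_SATURATION, MMHG, MOL_PER_M3})

#: O₂ mole fraction of dry air used for optode calibration ("100% air
#: saturation" refers to equilibrium with dry air at this fraction).
DRY_AIR_O2_FRACTION = 0.2095


class UnknownUnitError(ValueError):
    """Raised when an oxygen unit tag is not one of the supported set."""


class NegativeOxygenError(ValueError):
    """Raised when a physically impossible negative oxygen level is supplied."""


@dataclass(frozen=True)
class OxygenAmount:
    """An oxygen level tagged with its unit.

    Parameters
    ----------
    value
        Non-negative magnitude.
    unit
        One of :data:`UNITS`.
    """

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise UnknownUnitError(
                f"unknown oxygen unit {self.unit!r}; expected one of {sorted(UNITS)}"
            )
        if not math.isfinite(self.value):
            raise ValueError("oxygen value must be finite")
        if self.value < 0:
            raise NegativeOxygenError(f"oxygen value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class ConstantsRegistry:
    """Immutable registry of physical constants at the 37 °C set point.

    Every default can be overridden through configuration
    (:func:`registry_from_mapping`); values are validated on construction.

    Attributes
    ----------
    solubility_mol_m3_mmHg
        Henry-law oxygen solubility in aqueous media at 37 °C.  The default
        1.2e-3 reproduces the working correspondence 25 mmHg ↔ 0.03 mol·m⁻³;
        literature values at 37 °C span roughly 1.2–1.35e-3.
    D_water_37C_cm2_s
        Oxygen diffusion coefficient of water at 37 °C (also used for
        culture medium).
    D_tissue_cm2_s
        Oxygen diffusion coefficient of packed tissue, used in the
        cell-fraction-weighted effective diffusivity.
    OCR_MIN6_mol_m3_s, OCR_islet_mol_m3_s
        Volumetric oxygen consumption rates at unit cell volume fraction
        for MIN6 insulinoma cells and human islets.
    pO2_crit_mmHg
        Critical oxygen tension below which immobilized beta cells die;
        defines the live/dead front.
    ambient_O2_fraction
        O₂ mole fraction of the gas phase above the top-up medium
        (incubator gas mix, 18.6% by default once CO₂ and N₂ make-up are
        accounted for).
    total_pressure_mmHg, water_vapor_pressure_37C_mmHg
        Barometric pressure and water vapor pressure used to convert gas
        fractions to partial pressures.  A humidified atmosphere subtracts
        the vapor pressure; set the vapor pressure to 0 to disable.
    theta_boundary_s, tau_boundary_s
        Dead time and time constant of the first-order-plus-dead-time
        response of the gas/liquid interface to an inlet step.
    cell_volume_pL
        Single-cell volume used to convert cell concentrations
        (cells·mL⁻¹) to volume fractions; 1.7 pL is a typical beta-cell
        scale.
    """

    solubility_mol_m3_mmHg: float = 1.2e-3
    D_water_37C_cm2_s: float = 3.1e-5
    D_tissue_cm2_s: float = 1.24e-5
    OCR_MIN6_mol_m3_s: float = 0.129
    OCR_islet_mol_m3_s: float = 0.034
    pO2_crit_mmHg: float = 0.1
    ambient_O2_fraction: float = 0.186
    total_pressure_mmHg: float = 760.0
    water_vapor_pressure_37C_mmHg: float = 47.0
    theta_boundary_s: float = 3.0
    tau_boundary_s: float = 23.0
    cell_volume_pL: float = 1.7

    def __post_init__(self) -> None:
        strictly_positive = (
            "solubility_mol_m3_mmHg",
            "D_water_37C_cm2_s",
            "D_tissue_cm2_s",
            "OCR_MIN6_mol_m3_s",
            "OCR_islet_mol_m3_s",
            "pO2_crit_mmHg",
            "total_pressure_mmHg",
            "tau_boundary_s",
            "cell_volume_pL",
        )
        for name in strictly_positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be > 0")
        # fraction, vapor pressure and dead time may legitimately be zero
        for name in ("ambient_O2_fraction", "water_vapor_pressure_37C_mmHg", "theta_boundary_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"constant {name} must be >= 0")
        if self.water_vapor_pressure_37C_mmHg >= self.total_pressure_mmHg:
            raise ValueError("water vapor pressure must be below total pressure")
        if self.ambient_O2_fraction > 1:
            raise ValueError("ambient O2 fraction must be <= 1")


DEFAULT_CONSTANTS = ConstantsRegistry()


def registry_from_mapping(overrides: Mapping[str, float] | None) -> ConstantsRegistry:
    """Build a registry from defaults plus a flat ``constants:`` mapping.

    Unknown keys are rejected so configuration typos fail loudly.
    """
    if not overrides:
        return DEFAULT_CONSTANTS
    valid = {f.name for f in dataclasses.fields(ConstantsRegistry)}
    bad = set(overrides) - valid
    if bad:
        raise KeyError(f"unknown constants key(s): {sorted(bad)}; valid keys: {sorted(valid)}")
    return dataclasses.replace(DEFAULT_CONSTANTS, **dict(overrides))


def _mmHg_per_100_percent_air_sat(registry: ConstantsRegistry) -> float:
    """pO₂ (mmHg) corresponding to 100% air saturation at calibration."""
    return DRY_AIR_O2_FRACTION * (
        registry.total_pressure_mmHg - registry.water_vapor_pressure_37C_mmHg
    )


def convert_oxygen(
    x: OxygenAmount,
    target_unit: str,
    registry: ConstantsRegistry = DEFAULT_CONSTANTS,
) -> OxygenAmount:
    """Express an oxygen level in another unit.

    Conversions are linear and bijective for a fixed registry, so
    round-tripping returns the input to machine precision.
    """
    if target_unit not in UNITS:
        raise UnknownUnitError(
            f"unknown target unit {target_unit!r}; expected one of {sorted(UNITS)}"
        )
    # hub unit: mmHg
    if x.unit == MMHG:
        mmhg = x.value
    elif x.unit == MOL_PER_M3:
        mmhg = x.value / registry.solubility_mol_m3_mmHg
    else:  # percent air saturation
        mmhg = x.value / 100.0 * _mmHg_per_100_percent_air_sat(registry)

    if target_unit == MMHG:
        out = mmhg
    elif target_unit == MOL_PER_M3:
        out = mmhg * registry.solubility_mol_m3_mmHg
    else:
        out = mmhg / _mmHg_per_100_percent_air_sat(registry) * 100.0
    return OxygenAmount(out, target_unit)


def ambient_concentration(registry: ConstantsRegistry = DEFAULT_CONSTANTS) -> OxygenAmount:
    """Dissolved O₂ concentration in medium equilibrated with the incubator gas.

    Computed as solubility × gas-phase O₂ fraction × (total pressure −
    water vapor pressure); returned in mol·m⁻³.
    """
    p_o2 = registry.ambient_O2_fraction * (
        registry.total_pressure_mmHg - registry.water_vapor_pressure_37C_mmHg
    )
    return OxygenAmount(p_o2 * registry.solubility_mol_m3_mmHg, MOL_PER_M3)


def critical_concentration(registry: ConstantsRegistry = DEFAULT_CONSTANTS) -> OxygenAmount:
    """Critical O₂ concentration (mol·m⁻³) equivalent to ``pO2_crit_mmHg``."""
    return OxygenAmount(
        registry.pO2_crit_mmHg * registry.solubility_mol_m3_mmHg, MOL_PER_M3
    )
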