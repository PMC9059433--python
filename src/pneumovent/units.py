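"""Unit conversions and gas-property bookkeeping.

The physics core runs in one coherent absolute-SI system (Pa, kg/s, m³);
configs and outputs use clinical/engineering units (cmH2O, MPa, L/min, mL).
All conversions here are exact multiplicative factors, so they are linear,
invertible and compose associatively.

Volumetric flows are reported at atmospheric conditions (ATPD): the
conversion to mass flow uses the reference density ρ = p_a/(Rθ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Conventional definition of the centimetre of water column.
PA_PER_CMH2O = 98.0665

_PRESSURE_FACTORS = {
    "Pa": 1.0,
    "kPa": 1e3,
    "MPa": 1e6,
    "cmH2O": PA_PER_CMH2O,
}

_VOLUME_FACTORS = {"m3": 1.0, "L": 1e-3, "mL": 1e-6}

_FLOW_FACTORS = {"m3/s": 1.0, "L/s": 1e-3, "L/min": 1e-3 / 60.0}

_AREA_FACTORS = {"m2": 1.0, "mm2": 1e-6}

_TIME_FACTORS = {"s": 1.0, "min": 60.0, "ms": 1e-3}

#: Unit tags accepted in configuration files and emitted in CSV headers.
KNOWN_UNITS = (
    set(_PRESSURE_FACTORS)
    | set(_VOLUME_FACTORS)
    | set(_FLOW_FACTORS)
    | set(_AREA_FACTORS)
    | set(_TIME_FACTORS)
    | {"L/cmH2O", "mL/cmH2O", "m3/Pa"}
)


@dataclass(frozen=True)
class GasProperties:
    """Thermodynamic properties of the (isothermal) working gas.

    Defaults are standard dry air at room temperature; the model treats the
    gas as ideal and the working process as isothermal, so these four numbers
    fully characterise the gas.

    Parameters
    ----------
    specific_gas_constant : float
        R, J·kg⁻¹·K⁻¹.
    heat_capacity_ratio : float
        k = c_p/c_v, dimensionless; must exceed 1.
    temperature : float
        θ, kelvin.
    atmospheric_pressure : float
        p_a, absolute Pa; the reference downstream pressure for exhaust and
        the reference state for volumetric (ATPD) flow reporting.
    """

    specific_gas_constant: float = 287.05
    heat_capacity_ratio: float = 1.4
    temperature: float = 293.15
    atmospheric_pressure: float = 101325.0

    def __post_init__(self) -> None:
        if not (self.specific_gas_constant > 0):
            raise ValueError("specific gas constant must be positive")
        if not (self.heat_capacity_ratio > 1):
            raise ValueError("heat capacity ratio k must exceed 1")
        if not (250.0 <= self.temperature <= 330.0):
            raise ValueError("temperature outside the sane range [250, 330] K")
        if not (self.atmospheric_pressure > 0):
            raise ValueError("atmospheric pressure must be positive")

    @property
    def reference_density(self) -> float:
        """Density ρ = p_a/(Rθ) at atmospheric conditions, kg/m³."""
        return self.atmospheric_pressure / (
            self.specific_gas_constant * self.temperature
        )


def _convert(value: float, from_unit: str, to_unit: str, factors: dict, what: str) -> float:
    for u in (from_unit, to_unit):
        if u not in factors:
            raise ValueError(
                f"unknown {what} unit {u!r}; expected one of {sorted(factors)}"
            )
    if not math.isfinite(value):
        raise ValueError(f"non-finite {what} value: {value!r}")
    return value * (factors[from_unit] / factors[to_unit])


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure magnitude between Pa, kPa, MPa and cmH2O."""
    return _convert(value, from_unit, to_unit, _PRESSURE_FACTORS, "pressure")


def convert_volume(value: float, from_unit: str, to_unit: str) -> float:
    return _convert(value, from_unit, to_unit, _VOLUME_FACTORS, "volume")


def convert_flow(value: float, from_unit: str, to_unit: str) -> float:
    return _convert(value, from_unit, to_unit, _FLOW_FACTORS, "flow")


def convert_area(value: float, from_unit: str, to_unit: str) -> float:
    return _convert(value, from_unit, to_unit, _AREA_FACTORS, "area")


def convert_time(value: float, from_unit: str, to_unit: str) -> float:
    return _convert(value, from_unit, to_unit, _TIME_FACTORS, "time")


def convert_compliance(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a compliance (volume per gauge pressure) between unit tags."""
    factors = {
        "m3/Pa": 1.0,
        "L/cmH2O": 1e-3 / PA_PER_CMH2O,
        "mL/cmH2O": 1e-6 / PA_PER_CMH2O,
    }
    return _convert(value, from_unit, to_unit, factors, "compliance")


def gauge_to_absolute(p_gauge: float, gas: GasProperties) -> float:
    """Absolute pressure from gauge (relative-to-atmosphere) pressure."""
    p_abs = p_gauge + gas.atmospheric_pressure
    if p_abs <= 0:
        raise ValueError(
            f"gauge pressure {p_gauge} Pa implies non-physical absolute "
            f"pressure {p_abs} Pa"
        )
    return p_abs


def absolute_to_gauge(p_abs: float, gas: GasProperties) -> float:
    """Gauge pressure from absolute pressure; exact inverse of gauge_to_absolute."""
    if p_abs <= 0:
        raise ValueError(f"absolute pressure must be positive, got {p_abs}")
    return p_abs - gas.atmospheric_pressure


def volumetric_to_mass_flow(q_vol: float, gas: GasProperties) -> float:
    """Mass flow (kg/s) of a volumetric flow quoted at atmospheric density."""
    if not math.isfinite(q_vol):
        raise ValueError(f"non-finite volumetric flow: {q_vol!r}")
    return q_vol * gas.reference_density


def mass_to_volumetric_flow(m_dot: float, gas: GasProperties) -> float:
    """Volumetric flow (m³/s at atmospheric density) from mass flow; inverse pair."""
    if not math.isfinite(m_dot):
        raise ValueError(f"non-finite mass flow: {m_dot!r}")
    return m_dot / gas.reference_density
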