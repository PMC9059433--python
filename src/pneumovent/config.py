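"""Scenario configuration: unit-tagged YAML in, resolved SI physics out.

Every physical quantity in a config carries an explicit unit tag, so the
clinical/engineering units (cmH2O, MPa, mL, L/min, mm²) never silently mix
with the internal absolute-SI system.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import units as U
from .controller import VCVSettings, rig_settings
from .engine import Scenario, SimOptions
from .lung import LungParams, TubeParams
from .valves import ARCHETYPE_ALIASES, ValveSpec


class Quantity(BaseModel):
    """A magnitude with an explicit unit tag."""

    model_config = ConfigDict(extra="forbid")
    value: float
    unit: str


class PressureQuantity(Quantity):
    """Pressure magnitude; ``gauge: true`` means relative to atmosphere."""

    gauge: bool = False


class GasConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    specific_gas_constant: float = 287.05  # J/(kg K)
    heat_capacity_ratio: float = 1.4
    temperature: float = 293.15  # K
    atmospheric_pressure: float = 101325.0  # Pa

    def resolve(self) -> U.GasProperties:
        return U.GasProperties(
            specific_gas_constant=self.specific_gas_constant,
            heat_capacity_ratio=self.heat_capacity_ratio,
            temperature=self.temperature,
            atmospheric_pressure=self.atmospheric_pressure,
        )


class TubeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    volume: Quantity = Quantity(value=0.5, unit="L")

    def resolve(self) -> TubeParams:
        return TubeParams(volume=U.convert_volume(
            self.volume.value, self.volume.unit, "m3"))


class LungConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    compliance: Quantity = Quantity(value=0.05, unit="L/cmH2O")
    unstressed_volume: Quantity = Quantity(value=2.0, unit="L")

    def resolve(self) -> LungParams:
        return LungParams(
            compliance=U.convert_compliance(
                self.compliance.value, self.compliance.unit, "m3/Pa"),
            unstressed_volume=U.convert_volume(
                self.unstressed_volume.value, self.unstressed_volume.unit, "m3"),
        )


class ValveConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    archetype: str = "5/2"
    effective_area_supply: Quantity = Quantity(value=12.0, unit="mm2")
    effective_area_exhaust: Quantity = Quantity(value=6.0, unit="mm2")
    switching_delay: Quantity = Quantity(value=0.0, unit="s")

    def resolve(self) -> ValveSpec:
        if self.archetype not in ARCHETYPE_ALIASES:
            raise ValueError(
                f"unknown valve archetype {self.archetype!r}; "
                f"valid: {sorted(ARCHETYPE_ALIASES)}"
            )
        return ValveSpec(
            archetype=ARCHETYPE_ALIASES[self.archetype],
            effective_area_supply=U.convert_area(
                self.effective_area_supply.value,
                self.effective_area_supply.unit, "m2"),
            effective_area_exhaust=U.convert_area(
                self.effective_area_exhaust.value,
                self.effective_area_exhaust.unit, "m2"),
            switching_delay=U.convert_time(
                self.switching_delay.value, self.switching_delay.unit, "s"),
        )


class VCVConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tidal_volume: Quantity = Quantity(value=500.0, unit="mL")
    inspiratory_time: Quantity = Quantity(value=1.2, unit="s")
    plateau_time: Quantity = Quantity(value=0.3, unit="s")
    exhaust_time: Quantity = Quantity(value=1.6, unit="s")
    #: None → cycle period defaults to inspiratory + exhaust time.
    cycle_period: Optional[Quantity] = Quantity(value=4.0, unit="s")
    source_pressure: PressureQuantity = PressureQuantity(value=300.0, unit="kPa")
    source_area: Optional[Quantity] = Quantity(value=3.0, unit="mm2")

    def resolve(self, gas: U.GasProperties) -> VCVSettings:
        t_i = U.convert_time(self.inspiratory_time.value,
                             self.inspiratory_time.unit, "s")
        t_e = U.convert_time(self.exhaust_time.value, self.exhaust_time.unit, "s")
        if self.cycle_period is None:
            cycle = t_i + t_e
        else:
            cycle = U.convert_time(self.cycle_period.value,
                                   self.cycle_period.unit, "s")
        p_src = U.convert_pressure(self.source_pressure.value,
                                   self.source_pressure.unit, "Pa")
        if self.source_pressure.gauge:
            p_src = U.gauge_to_absolute(p_src, gas)
        return VCVSettings(
            tidal_volume=U.convert_volume(
                self.tidal_volume.value, self.tidal_volume.unit, "m3"),
            inspiratory_time=t_i,
            plateau_time=U.convert_time(
                self.plateau_time.value, self.plateau_time.unit, "s"),
            exhaust_time=t_e,
            cycle_period=cycle,
            source_pressure=p_src,
            source_area=(
                None if self.source_area is None
                else U.convert_area(self.source_area.value,
                                    self.source_area.unit, "m2")
            ),
        )


class CircuitConfig(BaseModel):
    """Rig control circuit: preset letter and on-delay timer setting."""

    model_config = ConfigDict(extra="forbid")
    preset: Literal["PA", "PB", "PC"] = "PA"
    timer_delay: Quantity = Quantity(value=10.0, unit="s")


class SimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cycles: int = 4
    washout_cycles: int = 2
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dt: Quantity = Quantity(value=2.0, unit="ms")
    plateau_eps_cmH2O_s: float = 0.5
    plateau_tau_s: float = 0.2

    def resolve(self) -> SimOptions:
        return SimOptions(
            n_cycles=self.n_cycles,
            washout_cycles=self.washout_cycles,
            rtol=self.rtol,
            atol=self.atol,
            output_dt=U.convert_time(self.output_dt.value,
                                     self.output_dt.unit, "s"),
            plateau_eps_cmH2O_s=self.plateau_eps_cmH2O_s,
            plateau_tau_s=self.plateau_tau_s,
        )


class ScenarioConfig(BaseModel):
    """Top-level scenario configuration."""

    model_config = ConfigDict(extra="forbid")
    name: str = "scenario"
    family: Literal["breath", "rig"] = "breath"
    gas: GasConfig = Field(default_factory=GasConfig)
    tube: TubeConfig = Field(default_factory=TubeConfig)
    lung: LungConfig = Field(default_factory=LungConfig)
    valve: ValveConfig = Field(default_factory=ValveConfig)
    vcv: VCVConfig = Field(default_factory=VCVConfig)
    circuit: Optional[CircuitConfig] = None
    sim: SimConfig = Field(default_factory=SimConfig)

    @model_validator(mode="after")
    def _rig_needs_circuit(self):
        if self.family == "rig" and self.circuit is None:
            raise ValueError("rig-family scenarios require a circuit section")
        return self

    def resolve(self) -> Scenario:
        gas = self.gas.resolve()
        vcv = self.vcv.resolve(gas)
        valve = self.valve.resolve()
        if self.family == "rig":
            assert self.circuit is not None
            delay = U.convert_time(self.circuit.timer_delay.value,
                                   self.circuit.timer_delay.unit, "s")
            # valve archetype follows the circuit preset letter
            valve = ValveSpec(
                archetype=ARCHETYPE_ALIASES[self.circuit.preset],
                effective_area_supply=valve.effective_area_supply,
                effective_area_exhaust=valve.effective_area_exhaust,
                switching_delay=valve.switching_delay,
            )
            settings = rig_settings(delay, vcv.tidal_volume, vcv.source_pressure)
            vcv = VCVSettings(
                tidal_volume=settings.tidal_volume,
                inspiratory_time=settings.inspiratory_time,
                plateau_time=settings.plateau_time,
                exhaust_time=settings.exhaust_time,
                cycle_period=settings.cycle_period,
                source_pressure=settings.source_pressure,
                source_area=vcv.source_area,
            )
        return Scenario(
            gas=gas,
            tube=self.tube.resolve(),
            lung=self.lung.resolve(),
            valve=valve,
            vcv=vcv,
            sim=self.sim.resolve(),
            name=self.name,
        )


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path} does not contain a mapping")
    return ScenarioConfig.model_validate(raw)


def dump_scenario_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Serialize a resolved configuration back to YAML (round-trip safe)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
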