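"""Continuum state of the breathable-air circuit.

Two coupled isothermal chambers: a rigid flexible-tube volume V_t and a
single-compartment compliant lung whose volume follows the linear law
V_l(p_l) = V_l0 + C_l·(p_l − p_a), i.e. constant compliance C_l = dV_l/dp_l.

For an isothermal ideal-gas chamber, d(pV)/dt = Rθ·q with q the net mass
inflow. The rigid tube gives dp_t/dt = (Rθ/V_t)·q_t; the compliant lung,
with dV_l/dt = C_l·dp_l/dt, gives dp_l/dt = Rθ·q_l/(V_l + C_l·p_l).
Both reduce to dp/dt = (1/V)Rθq − (mRθ/V²)dV/dt under the ideal-gas
closure m = pV/(Rθ).
"""

from __future__ import annotations

from dataclasses import dataclass

from .units import GasProperties


@dataclass(frozen=True)
class LungParams:
    """Single-compartment lung: compliance (m³/Pa) and unstressed volume (m³)."""

    compliance: float
    unstressed_volume: float

    def __post_init__(self) -> None:
        if not self.compliance > 0:
            raise ValueError("lung compliance must be positive")
        if not self.unstressed_volume > 0:
            raise ValueError("unstressed lung volume must be positive")


@dataclass(frozen=True)
class TubeParams:
    """Rigid flexible-tube chamber volume (m³)."""

    volume: float

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError("tube volume must be positive")


@dataclass(frozen=True)
class CircuitState:
    """Instantaneous circuit state: absolute pressures, delivered volume, time."""

    p_tube: float
    p_lung: float
    delivered_volume: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.p_tube <= 0 or self.p_lung <= 0:
            raise ValueError("absolute pressures must be positive")


def lung_volume(p_lung: float, lung: LungParams, gas: GasProperties) -> float:
    """Lung gas volume V_l = V_l0 + C_l·(p_l − p_a); rejects over-deflation."""
    v = lung.unstressed_volume + lung.compliance * (
        p_lung - gas.atmospheric_pressure
    )
    if v <= 0:
        raise ValueError(
            f"non-physical lung volume {v} m³ at p_lung={p_lung} Pa "
            "(over-deflation; check compliance/unstressed volume)"
        )
    return v


def stored_mass(
    p_tube: float,
    p_lung: float,
    tube: TubeParams,
    lung: LungParams,
    gas: GasProperties,
) -> float:
    """Total gas mass in tube + lung via the ideal-gas closure m = pV/(Rθ)."""
    rt = gas.specific_gas_constant * gas.temperature
    return (p_tube * tube.volume + p_lung * lung_volume(p_lung, lung, gas)) / rt


def pressure_derivatives(
    state: CircuitState,
    m_in: float,
    m_tl: float,
    m_ex: float,
    tube: TubeParams,
    lung: LungParams,
    gas: GasProperties,
) -> tuple[float, float]:
    """(dp_t/dt, dp_l/dt) for the coupled tube/lung chambers.

    Parameters
    ----------
    m_in : float
        Mass flow into the tube from the ventilator source, kg/s.
    m_tl : float
        Mass flow from tube to lung (signed; negative during exhalation), kg/s.
    m_ex : float
        Mass flow from tube to the exhaust port, kg/s.
    """
    rt = gas.specific_gas_constant * gas.temperature
    dp_tube = rt / tube.volume * (m_in - m_tl - m_ex)
    v_l = lung_volume(state.p_lung, lung, gas)
    dp_lung = rt * m_tl / (v_l + lung.compliance * state.p_lung)
    return dp_tube, dp_lung
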