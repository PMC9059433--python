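"""Compressible orifice flow and solenoid-valve switching logic.

The flow model is the standard isentropic converging-nozzle orifice: below
the critical pressure ratio b = (2/(k+1))^(k/(k-1)) (≈0.528 for air) the
flow is choked and depends only on upstream conditions; above it the flow
is subsonic. Both branches are continuous at b and linear in effective
area. Flow is returned as a non-negative magnitude; the circuit graph
assigns orientation.

Discrete switching covers three directional-valve archetypes — 5/2 bistable
double-coil, 5/3 spring-return, 3/2 spring-return — and the on-delay timer
relays that drive them in the electro-pneumatic control circuits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

from .units import GasProperties


class ValveArchetype(Enum):
    """Directional-valve archetypes of the control circuits."""

    FIVE_TWO_BISTABLE = "5/2"
    FIVE_THREE_SPRING = "5/3"
    THREE_TWO_SPRING = "3/2"


#: Config aliases: rig shorthand PA/PB/PC maps onto the port archetypes.
ARCHETYPE_ALIASES = {
    "5/2": ValveArchetype.FIVE_TWO_BISTABLE,
    "5/3": ValveArchetype.FIVE_THREE_SPRING,
    "3/2": ValveArchetype.THREE_TWO_SPRING,
    "PA": ValveArchetype.FIVE_TWO_BISTABLE,
    "PB": ValveArchetype.FIVE_THREE_SPRING,
    "PC": ValveArchetype.THREE_TWO_SPRING,
}


class ValvePosition(Enum):
    HOME = "HOME"
    ACTUATED = "ACTUATED"
    MID = "MID"  # centre position, 5/3 only


#: Open fraction of the (supply→patient, patient→exhaust) paths per position.
#: HOME insufflates (supply path open), ACTUATED exhausts; the 5/3 centre
#: position blocks both paths (hold).
_CONNECTIVITY: dict[tuple[ValveArchetype, ValvePosition], dict[str, float]] = {
    (ValveArchetype.FIVE_TWO_BISTABLE, ValvePosition.HOME): {
        "supply_to_patient": 1.0, "patient_to_exhaust": 0.0},
    (ValveArchetype.FIVE_TWO_BISTABLE, ValvePosition.ACTUATED): {
        "supply_to_patient": 0.0, "patient_to_exhaust": 1.0},
    (ValveArchetype.FIVE_THREE_SPRING, ValvePosition.HOME): {
        "supply_to_patient": 1.0, "patient_to_exhaust": 0.0},
    (ValveArchetype.FIVE_THREE_SPRING, ValvePosition.MID): {
        "supply_to_patient": 0.0, "patient_to_exhaust": 0.0},
    (ValveArchetype.FIVE_THREE_SPRING, ValvePosition.ACTUATED): {
        "supply_to_patient": 0.0, "patient_to_exhaust": 1.0},
    (ValveArchetype.THREE_TWO_SPRING, ValvePosition.HOME): {
        "supply_to_patient": 1.0, "patient_to_exhaust": 0.0},
    (ValveArchetype.THREE_TWO_SPRING, ValvePosition.ACTUATED): {
        "supply_to_patient": 0.0, "patient_to_exhaust": 1.0},
}


def connectivity(archetype: ValveArchetype, position: ValvePosition) -> dict[str, float]:
    """Open fractions of the supply and exhaust paths for a valve position."""
    key = (archetype, position)
    if key not in _CONNECTIVITY:
        raise ValueError(f"position {position} not reachable for archetype {archetype}")
    return dict(_CONNECTIVITY[key])


@dataclass(frozen=True)
class ValveSpec:
    """Static description of a gating valve.

    ``effective_area_supply`` (A_rt) characterises the inspiratory/airway
    path, ``effective_area_exhaust`` (A_ev) the quick-exhaust path; both in
    m² (configs use mm²). ``switching_delay`` is the time between a coil
    command and the position change.
    """

    archetype: ValveArchetype
    effective_area_supply: float
    effective_area_exhaust: float
    switching_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.effective_area_supply < 0 or self.effective_area_exhaust < 0:
            raise ValueError("effective areas must be non-negative")
        if self.effective_area_supply == 0 and self.effective_area_exhaust == 0:
            raise ValueError("at least one effective area must be positive")
        if self.switching_delay < 0:
            raise ValueError("switching delay must be non-negative")


@dataclass(frozen=True)
class ValveState:
    """Instantaneous valve state: position, coil signals, pending motion."""

    position: ValvePosition = ValvePosition.HOME
    coil_a: bool = False
    coil_b: bool = False
    pending_position: ValvePosition | None = None
    pending_since: float = 0.0

    def open_fractions(self, spec: ValveSpec) -> dict[str, float]:
        return connectivity(spec.archetype, self.position)


def critical_pressure_ratio(gas: GasProperties | float) -> float:
    """Critical (choking) downstream/upstream pressure ratio.

    b = (2/(k+1))^(k/(k-1)); ≈0.528 for k = 1.4 (air). Accepts either a
    :class:`GasProperties` or a bare heat-capacity ratio k.
    """
    k = gas.heat_capacity_ratio if isinstance(gas, GasProperties) else float(gas)
    if not k > 1:
        raise ValueError(f"heat capacity ratio must exceed 1, got {k}")
    return (2.0 / (k + 1.0)) ** (k / (k - 1.0))


def orifice_mass_flow(
    area: float,
    p_up: float,
    p_down: float,
    gas: GasProperties,
    linear_blend_width: float = 0.0,
) -> float:
    """Mass flow (kg/s, magnitude) through an orifice of effective area ``area``.

    Choked branch (p_down/p_up ≤ b)::

        ṁ = A·p_up·√(k/(Rθ))·(2/(k+1))^((k+1)/(2(k−1)))

    Subsonic branch::

        ṁ = A·p_up·√(2k/((k−1)Rθ))·√(r^(2/k) − r^((k+1)/k)),  r = p_down/p_up

    The caller supplies orientation (p_up ≥ p_down); the result is ≥ 0 and
    exactly 0 for zero area or equal pressures.

    ``linear_blend_width`` δ > 0 replaces the √-shaped near-equalization
    regime r ∈ (1−δ, 1] by a linear (laminar-like) taper continuous at
    r = 1−δ. The exact subsonic law has infinite slope at r = 1, which
    stalls adaptive integrators as the chambers equalize; a narrow taper
    (the engine uses δ = 1e−4, i.e. driving pressures below ~10 Pa) makes
    the field Lipschitz with negligible bias.
    """
    if p_up <= 0 or p_down <= 0:
        raise ValueError(
            f"absolute pressures must be positive (p_up={p_up}, p_down={p_down})"
        )
    if area < 0:
        raise ValueError("effective area must be non-negative")
    if p_down > p_up:
        raise ValueError(
            "p_down exceeds p_up; orient the call from high to low pressure"
        )
    if area == 0.0 or p_down == p_up:
        return 0.0

    k = gas.heat_capacity_ratio
    rt = gas.specific_gas_constant * gas.temperature
    r = p_down / p_up
    b = critical_pressure_ratio(gas)
    if r <= b:
        return area * p_up * math.sqrt(k / rt) * (2.0 / (k + 1.0)) ** (
            (k + 1.0) / (2.0 * (k - 1.0))
        )

    def subsonic(ratio: float) -> float:
        radicand = ratio ** (2.0 / k) - ratio ** ((k + 1.0) / k)
        # guard rounding when ratio is within an ulp of 1
        radicand = max(radicand, 0.0)
        return (
            area * p_up
            * math.sqrt(2.0 * k / ((k - 1.0) * rt))
            * math.sqrt(radicand)
        )

    if linear_blend_width > 0.0 and r > 1.0 - linear_blend_width:
        edge = subsonic(1.0 - linear_blend_width)
        return edge * (1.0 - r) / linear_blend_width
    return subsonic(r)


def _target_position(
    archetype: ValveArchetype, coil_a: bool, coil_b: bool, current: ValvePosition
) -> ValvePosition:
    if archetype is ValveArchetype.FIVE_TWO_BISTABLE:
        if coil_a and not coil_b:
            return ValvePosition.ACTUATED
        if coil_b and not coil_a:
            return ValvePosition.HOME
        # both or neither: the pistons cancel / nothing drives — memory
        return current
    if archetype is ValveArchetype.FIVE_THREE_SPRING:
        if coil_a and coil_b:
            return ValvePosition.MID  # pressure-centred
        return ValvePosition.ACTUATED if coil_a else ValvePosition.HOME
    # 3/2 spring return, single coil
    return ValvePosition.ACTUATED if coil_a else ValvePosition.HOME


def valve_state_update(
    spec: ValveSpec, state: ValveState, coil_a: bool, coil_b: bool, now: float
) -> ValveState:
    """Advance the valve state machine given the coil signals at time ``now``.

    5/2 bistable: a sole energized coil drives the position after
    ``switching_delay``; both coils (equal opposing forces) or neither
    retain the position. Spring-return archetypes follow the (single) coil:
    energized → ACTUATED, de-energized → HOME.
    """
    target = _target_position(spec.archetype, coil_a, coil_b, state.position)
    if target == state.position:
        return replace(state, coil_a=coil_a, coil_b=coil_b,
                       pending_position=None)
    if spec.switching_delay == 0.0:
        return ValveState(position=target, coil_a=coil_a, coil_b=coil_b)
    if state.pending_position == target:
        if now - state.pending_since >= spec.switching_delay:
            return ValveState(position=target, coil_a=coil_a, coil_b=coil_b)
        return replace(state, coil_a=coil_a, coil_b=coil_b)
    return replace(
        state, coil_a=coil_a, coil_b=coil_b,
        pending_position=target, pending_since=now,
    )


@dataclass(frozen=True)
class OnDelayTimer:
    """On-delay timer relay.

    The output asserts once the input has been continuously true for at
    least ``delay`` seconds; a falling input resets both the rise time and
    the output.
    """

    delay: float
    input_rise_time: float | None = None
    output: bool = False
    last_now: float = field(default=-math.inf)

    def __post_init__(self) -> None:
        if not self.delay > 0:
            raise ValueError("timer delay must be positive")


def on_delay_timer_update(timer: OnDelayTimer, input_: bool, now: float) -> OnDelayTimer:
    """Advance the timer; ``now`` must be non-decreasing across calls."""
    if now < timer.last_now:
        raise ValueError(
            f"time regression: now={now} precedes last update at {timer.last_now}"
        )
    if not input_:
        return OnDelayTimer(delay=timer.delay, input_rise_time=None,
                            output=False, last_now=now)
    rise = timer.input_rise_time if timer.input_rise_time is not None else now
    out = (now - rise) >= timer.delay
    return OnDelayTimer(delay=timer.delay, input_rise_time=rise,
                        output=out, last_now=now)
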