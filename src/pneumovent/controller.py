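"""Volume-controlled ventilation law and breath-cycle phase machine.

The VCV delivery law is piecewise: a constant target flow
Q_T = V_T/(T_i − T_p) while the delivered volume is below the set tidal
volume V_T, and zero afterwards and outside inspiration. The breath cycle
partitions into INSPIRATION → PLATEAU → EXPIRATION → REST over the cycle
period.

The same phase sequence can be produced by the electro-pneumatic relay
ladder of the rig circuits (pushbutton → relay K1 → contact K2 → solenoid
1Y1), where an on-delay timer toggles the gating valve every ``delay``
seconds, alternating insufflation and exhaust with period 2·delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .valves import (
    ARCHETYPE_ALIASES,
    OnDelayTimer,
    ValveArchetype,
    ValvePosition,
    ValveSpec,
    ValveState,
    on_delay_timer_update,
    valve_state_update,
)


class BreathPhase(Enum):
    INSPIRATION = "INSPIRATION"
    PLATEAU = "PLATEAU"
    EXPIRATION = "EXPIRATION"
    REST = "REST"


@dataclass(frozen=True)
class VCVSettings:
    """Ventilator settings for the volume-controlled mode.

    ``tidal_volume`` in m³; times in s; ``source_pressure`` is the absolute
    regulated supply pressure (Pa); ``source_area`` is the effective area of
    the supply regulator orifice that caps the achievable inspiratory flow
    (None → use the valve's inspiratory-path area).
    """

    tidal_volume: float
    inspiratory_time: float
    plateau_time: float
    exhaust_time: float
    cycle_period: float
    source_pressure: float
    source_area: float | None = None

    def __post_init__(self) -> None:
        if not self.tidal_volume > 0:
            raise ValueError("tidal volume must be positive")
        if not self.inspiratory_time > self.plateau_time:
            raise ValueError("inspiratory time must exceed plateau time")
        if self.plateau_time < 0:
            raise ValueError("plateau time must be non-negative")
        if not self.exhaust_time > 0:
            raise ValueError("exhaust time must be positive")
        if self.cycle_period < self.inspiratory_time + self.exhaust_time:
            raise ValueError(
                "cycle period must cover inspiratory + exhaust time"
            )
        if not self.source_pressure > 0:
            raise ValueError("source pressure must be positive (absolute)")


def target_flow(settings: VCVSettings) -> float:
    """Target inspiratory flow Q_T = V_T/(T_i − T_p), m³/s."""
    return settings.tidal_volume / (
        settings.inspiratory_time - settings.plateau_time
    )


def commanded_flow(
    settings: VCVSettings, delivered: float, phase: BreathPhase
) -> float:
    """Piecewise VCV delivery law: Q_T while delivered < V_T in inspiration, else 0."""
    if delivered < 0:
        raise ValueError("delivered volume must be non-negative")
    if phase is BreathPhase.INSPIRATION and delivered < settings.tidal_volume:
        return target_flow(settings)
    return 0.0


def phase_at(t_in_cycle: float, settings: VCVSettings) -> BreathPhase:
    """Phase at a time within one cycle; half-open boundaries.

    [0, T_i−T_p) → INSPIRATION; [T_i−T_p, T_i) → PLATEAU;
    [T_i, T_i+T_e) → EXPIRATION; remainder → REST.
    """
    if not (0.0 <= t_in_cycle < settings.cycle_period):
        raise ValueError(
            f"time {t_in_cycle} outside cycle [0, {settings.cycle_period})"
        )
    t_flow = settings.inspiratory_time - settings.plateau_time
    if t_in_cycle < t_flow:
        return BreathPhase.INSPIRATION
    if t_in_cycle < settings.inspiratory_time:
        return BreathPhase.PLATEAU
    if t_in_cycle < settings.inspiratory_time + settings.exhaust_time:
        return BreathPhase.EXPIRATION
    return BreathPhase.REST


def phase_segments(settings: VCVSettings) -> list[tuple[float, float, BreathPhase]]:
    """(start, end, phase) segments partitioning one cycle, in order."""
    t_flow = settings.inspiratory_time - settings.plateau_time
    t_i = settings.inspiratory_time
    t_ie = t_i + settings.exhaust_time
    segs = [(0.0, t_flow, BreathPhase.INSPIRATION)]
    if t_i > t_flow:  # guards a plateau shorter than float resolution
        segs.append((t_flow, t_i, BreathPhase.PLATEAU))
    segs.append((t_i, t_ie, BreathPhase.EXPIRATION))
    if settings.cycle_period > t_ie:
        segs.append((t_ie, settings.cycle_period, BreathPhase.REST))
    return segs


def valve_coil_commands(
    phase: BreathPhase, archetype: ValveArchetype
) -> tuple[bool, bool]:
    """Coil signals that put a valve of the given archetype into the phase's
    connectivity: exhaust open during EXPIRATION/REST, supply path otherwise.

    For the bistable 5/2 the opposing coil is pulsed to return HOME (a sole
    energized coil drives the position); spring-return archetypes need only
    the working coil.
    """
    exhaust = phase in (BreathPhase.EXPIRATION, BreathPhase.REST)
    if archetype is ValveArchetype.FIVE_TWO_BISTABLE:
        return (exhaust, not exhaust)
    return (exhaust, False)


# --------------------------------------------------------------------------
# Electro-pneumatic rig circuit (relay ladder + on-delay timer oscillator)
# --------------------------------------------------------------------------


@dataclass
class RelayLadderCircuit:
    """Relay-ladder emulation of the rig control circuits (PA/PB/PC presets).

    A latched pushbutton energizes relay K1; its contact K2 feeds an
    on-delay timer which, on firing, toggles the solenoid command of the
    gating valve 1V1 and resets itself, so the valve alternates between
    insufflation (HOME) and exhaust (ACTUATED) every ``delay`` seconds.
    """

    spec: ValveSpec
    delay: float
    pushbutton: bool = True

    def __post_init__(self) -> None:
        self.timer = OnDelayTimer(delay=self.delay)
        self.valve = ValveState(position=ValvePosition.HOME)
        self.relay_k1 = False
        self.exhaust_command = False

    def step(self, now: float) -> ValveState:
        """Advance the ladder to time ``now`` and return the valve state."""
        self.relay_k1 = self.pushbutton  # K1 follows the latched pushbutton
        self.timer = on_delay_timer_update(self.timer, self.relay_k1, now)
        if self.timer.output:
            # firing toggles the solenoid command and re-arms the timer
            self.exhaust_command = not self.exhaust_command
            self.timer = on_delay_timer_update(self.timer, False, now)
            self.timer = on_delay_timer_update(self.timer, self.relay_k1, now)
        if self.spec.archetype is ValveArchetype.FIVE_TWO_BISTABLE:
            coil_a, coil_b = self.exhaust_command, not self.exhaust_command
        else:
            coil_a, coil_b = self.exhaust_command, False
        self.valve = valve_state_update(self.spec, self.valve, coil_a, coil_b, now)
        return self.valve


_PRESET_ARCHETYPES = {"PA": "5/2", "PB": "5/3", "PC": "3/2"}


def circuit_driven_phase(
    preset: str,
    delay: float,
    t_grid: np.ndarray,
    spec: ValveSpec | None = None,
) -> list[BreathPhase]:
    """Phase sequence produced by the relay-ladder circuit on a time grid.

    ``preset`` is one of PA/PB/PC (5/2, 5/3, 3/2 archetypes). The phase is
    derived from the valve connectivity: exhaust path open → EXPIRATION,
    supply path open → INSPIRATION.
    """
    if preset not in _PRESET_ARCHETYPES:
        raise ValueError(
            f"unknown circuit preset {preset!r}; valid: {sorted(_PRESET_ARCHETYPES)}"
        )
    if spec is None:
        spec = ValveSpec(
            archetype=ARCHETYPE_ALIASES[preset],
            effective_area_supply=12e-6,
            effective_area_exhaust=6e-6,
        )
    circuit = RelayLadderCircuit(spec=spec, delay=delay)
    phases: list[BreathPhase] = []
    for t in np.asarray(t_grid, dtype=float):
        state = circuit.step(float(t))
        conn = state.open_fractions(spec)
        if conn["patient_to_exhaust"] > 0:
            phases.append(BreathPhase.EXPIRATION)
        elif conn["supply_to_patient"] > 0:
            phases.append(BreathPhase.INSPIRATION)
        else:
            phases.append(BreathPhase.REST)
    return phases


def rig_settings(
    delay: float, tidal_volume: float, source_pressure: float
) -> VCVSettings:
    """Breath timing equivalent to a rig circuit with timer delay ``delay``:
    insufflation for ``delay`` seconds, exhaust for ``delay`` seconds."""
    return VCVSettings(
        tidal_volume=tidal_volume,
        inspiratory_time=delay,
        plateau_time=0.0,
        exhaust_time=delay,
        cycle_period=2.0 * delay,
        source_pressure=source_pressure,
    )
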