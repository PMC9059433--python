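"""Scenario presets reproducing the study's experimental grids.

Two scenario families:

* ``breath`` scenarios — clinical breath timing (inspiration ~1 s, exhaust
  1.0–1.8 s). The ``validation`` preset anchors the grid: exhalation-valve
  effective area 6 mm², tidal volume 500 mL, exhaust grid 1.0–1.8 s, tidal
  grid 300–700 mL.
* ``rig`` scenarios — the electro-pneumatic bench circuits PA/PB/PC
  (5/2 bistable, 5/3 spring-return, 3/2 spring-return solenoid valves),
  indices 1–4 mapping to on-delay timer settings 10/12/14/16 s, which act
  as actuation half-periods (the valve toggles every ``delay`` seconds).

Lung/tube parameters are not part of the published grids; breath presets
use adult-typical defaults (C_l = 0.05 L/cmH2O, V_l0 = 2 L, V_t = 0.5 L)
and the dedicated builders below use bench test-lung values where the
metric being exercised demands them (see docs/methods.md).
"""

from __future__ import annotations

from .config import (
    CircuitConfig,
    LungConfig,
    Quantity,
    ScenarioConfig,
    SimConfig,
    TubeConfig,
    VCVConfig,
    ValveConfig,
)

_TIMER_INDEX_S = {1: 10.0, 2: 12.0, 3: 14.0, 4: 16.0}
_RIG_LETTERS = ("PA", "PB", "PC")

#: The 12 rig presets plus the breath-family validation anchor.
PRESET_NAMES = tuple(
    f"{letter}{idx}" for letter in _RIG_LETTERS for idx in sorted(_TIMER_INDEX_S)
) + ("validation",)


def _q(value: float, unit: str) -> Quantity:
    return Quantity(value=value, unit=unit)


def make_preset(name: str) -> ScenarioConfig:
    """Fully resolved configuration for a named preset.

    Rig presets (PA1–PC4) set the valve archetype and timer delay
    (e.g. PA3 → 5/2 valve, 14 s); ``validation`` is the breath-family
    anchor scenario (A_ev = 6 mm², V_T = 500 mL, T_i = 1.2 s, T_e = 1.6 s).
    """
    if name == "validation":
        return ScenarioConfig(name="validation", family="breath")
    if name in PRESET_NAMES:
        letter, idx = name[:2], int(name[2])
        return ScenarioConfig(
            name=name,
            family="rig",
            circuit=CircuitConfig(preset=letter,
                                  timer_delay=_q(_TIMER_INDEX_S[idx], "s")),
            valve=ValveConfig(archetype=letter),
            sim=SimConfig(n_cycles=2, washout_cycles=1,
                          output_dt=_q(20.0, "ms")),
        )
    raise ValueError(
        f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
    )


def exhaust_sweep_base() -> ScenarioConfig:
    """Base scenario of the exhaust-time sweep (T_e ∈ 1.0–1.8 s).

    Sized so that passive exhalation completes in ≈1.4 s: a stiff test lung
    (C_l = 0.008 L/cmH2O) ventilated at 300 mL with no inspiratory pause and
    no end-expiratory rest (cycle = T_i + T_e), so the flat expiratory
    "pressure platform in the pipe" appears only when T_e outlasts the
    exhalation (here from T_e ≈ 1.6 s on).
    """
    return ScenarioConfig(
        name="exhaust_sweep",
        family="breath",
        tube=TubeConfig(volume=_q(0.3, "L")),
        lung=LungConfig(compliance=_q(0.008, "L/cmH2O"),
                        unstressed_volume=_q(1.0, "L")),
        valve=ValveConfig(effective_area_supply=_q(16.0, "mm2")),
        vcv=VCVConfig(
            tidal_volume=_q(300.0, "mL"),
            inspiratory_time=_q(1.0, "s"),
            plateau_time=_q(0.0, "s"),
            exhaust_time=_q(1.0, "s"),
            cycle_period=None,  # track T_i + T_e as T_e is swept
        ),
        sim=SimConfig(n_cycles=4, washout_cycles=2),
    )


def compliance_bench_base() -> ScenarioConfig:
    """Base scenario of the static-compliance recovery grid.

    Bench test-lung configuration (V_l0 = 0.5 L, V_t = 0.2 L) with a long
    inspiratory pause (0.5 s) and a long exhaust (5 s): the pause lets tube
    and lung equilibrate (negligible end-inspiratory flow) and the exhaust
    empties the lung fully, so V_delivered/(plateau − PEEP) approximates the
    configured compliance with minimal gas-compression bias.
    """
    return ScenarioConfig(
        name="compliance_bench",
        family="breath",
        tube=TubeConfig(volume=_q(0.2, "L")),
        lung=LungConfig(compliance=_q(0.05, "L/cmH2O"),
                        unstressed_volume=_q(0.5, "L")),
        vcv=VCVConfig(
            tidal_volume=_q(400.0, "mL"),
            inspiratory_time=_q(1.5, "s"),
            plateau_time=_q(0.5, "s"),
            exhaust_time=_q(5.0, "s"),
            cycle_period=_q(7.0, "s"),
        ),
        sim=SimConfig(n_cycles=3, washout_cycles=1, output_dt=_q(5.0, "ms")),
    )


#: Published sweep grids.
TIDAL_VOLUME_GRID_ML = (300.0, 500.0, 600.0, 700.0)
EXHAUST_TIME_GRID_S = (1.0, 1.2, 1.4, 1.6, 1.8)
TIMER_DELAY_GRID_S = tuple(_TIMER_INDEX_S[i] for i in sorted(_TIMER_INDEX_S))
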