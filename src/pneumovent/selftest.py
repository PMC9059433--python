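"""Built-in quick checks of the core physical properties.

These are fast, deterministic versions of the model's defining contracts:
the critical pressure ratio, continuity of the two orifice-flow branches,
tidal-volume delivery, and mass conservation on the validation scenario.
Used by the ``selftest`` CLI subcommand.
"""

from __future__ import annotations

from .engine import simulate, steady_state_metrics
from .presets import make_preset
from .units import GasProperties
from .valves import critical_pressure_ratio, orifice_mass_flow


def run_selftest() -> list[tuple[str, str]]:
    """Run all checks; return a list of (name, message) failures."""
    failures: list[tuple[str, str]] = []
    gas = GasProperties()

    b = critical_pressure_ratio(gas)
    if abs(b - 0.528) > 5e-4:
        failures.append(("critical_ratio", f"b(k=1.4)={b:.6f}, expected ≈0.528"))

    p_up = 2e5
    m_at_b = orifice_mass_flow(6e-6, p_up, b * p_up, gas)
    m_sub = orifice_mass_flow(6e-6, p_up, b * p_up * (1 + 1e-12), gas)
    if abs(m_at_b - m_sub) > 1e-6 * m_at_b:
        failures.append(
            ("branch_continuity",
             f"choked {m_at_b} vs subsonic {m_sub} at the critical ratio"))

    m1 = orifice_mass_flow(6e-6, p_up, 0.3 * p_up, gas)
    m2 = orifice_mass_flow(6e-6, p_up, 0.5 * p_up, gas)
    if abs(m1 - m2) > 1e-12:
        failures.append(
            ("choked_invariance", f"choked flow varies downstream: {m1} vs {m2}"))

    try:
        wf = simulate(make_preset("validation").resolve())
        m = steady_state_metrics(wf)
        if abs(m.delivered_volume_mL - 500.0) > 5.0:
            failures.append(
                ("tidal_delivery",
                 f"delivered {m.delivered_volume_mL:.1f} mL, set 500 mL"))
        if wf.mass_residual_fraction > 0.005:
            failures.append(
                ("mass_conservation",
                 f"residual {wf.mass_residual_fraction:.2%} of throughput"))
        if not (0.0 < m.peak_pressure_cmH2O < 40.0):
            failures.append(
                ("clinical_envelope",
                 f"peak {m.peak_pressure_cmH2O:.1f} cmH2O outside 0–40"))
    except Exception as exc:  # noqa: BLE001
        failures.append(("validation_run", str(exc)))
    return failures
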