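"""Parametric sweep runner: one simulation + metrics row per value.

A sweep takes a base scenario, a dotted parameter path into the
configuration (e.g. ``vcv.tidal_volume``), and a value list; it emits a
tidy table ordered by input value, one row per value, with the per-breath
steady-state metrics and the mass-conservation residual of each run.
Failed runs are recorded per-row with the failure reason and the sweep
continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import Quantity, ScenarioConfig
from .engine import simulate, steady_state_metrics

log = logging.getLogger("pneumovent.sweep")

#: Columns of a sweep results table.
SWEEP_COLUMNS = [
    "param",
    "value",
    "unit",
    "peak_pressure_cmH2O",
    "plateau_pressure_cmH2O",
    "plateau_detected",
    "platform_pressure_cmH2O",
    "platform_detected",
    "peep_cmH2O",
    "delivered_volume_mL",
    "peak_expiratory_flow_L_min",
    "mass_residual_pct",
    "status",
]


@dataclass(frozen=True)
class SweepSpec:
    """A parametric sweep: base scenario, parameter path, value list."""

    base: ScenarioConfig
    param_path: str
    values: tuple
    unit: str | None = None

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("sweep value list must be non-empty")
        # fail fast if the path does not resolve in the schema
        _set_param(self.base, self.param_path, self.values[0], self.unit)


def _set_param(
    cfg: ScenarioConfig, path: str, value: float, unit: str | None
) -> ScenarioConfig:
    """Return a copy of ``cfg`` with the dotted ``path`` set to ``value``."""
    parts = path.split(".")
    data = cfg.model_dump(mode="json")
    node = data
    for key in parts[:-1]:
        if not isinstance(node, dict) or key not in node:
            raise KeyError(f"parameter path {path!r} not found in scenario config")
        node = node[key]
    leaf = parts[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise KeyError(f"parameter path {path!r} not found in scenario config")
    current = node[leaf]
    if isinstance(current, dict) and "value" in current:
        node[leaf] = {**current, "value": value}
        if unit is not None:
            node[leaf]["unit"] = unit
    elif current is None and unit is not None:
        node[leaf] = Quantity(value=value, unit=unit).model_dump(mode="json")
    else:
        node[leaf] = value
    return ScenarioConfig.model_validate(data)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the sweep and return the tidy results table (row per value)."""
    rows = []
    for value in sorted(spec.values):
        row: dict = {
            "param": spec.param_path,
            "value": value,
            "unit": spec.unit or "",
        }
        try:
            cfg = _set_param(spec.base, spec.param_path, value, spec.unit)
            scenario = cfg.resolve()
            wf = simulate(scenario)
            m = steady_state_metrics(
                wf,
                washout_cycles=scenario.sim.washout_cycles,
                plateau_eps=scenario.sim.plateau_eps_cmH2O_s,
                plateau_tau=scenario.sim.plateau_tau_s,
            )
            row.update(
                peak_pressure_cmH2O=m.peak_pressure_cmH2O,
                plateau_pressure_cmH2O=m.plateau_pressure_cmH2O,
                plateau_detected=m.plateau_detected,
                platform_pressure_cmH2O=m.platform_pressure_cmH2O,
                platform_detected=m.platform_detected,
                peep_cmH2O=m.peep_cmH2O,
                delivered_volume_mL=m.delivered_volume_mL,
                peak_expiratory_flow_L_min=m.peak_expiratory_flow_L_min,
                mass_residual_pct=wf.mass_residual_fraction * 100.0,
                status="ok",
            )
            log.info(
                "sweep %s=%s: peak=%.2f cmH2O, delivered=%.1f mL, "
                "mass residual=%.4f%%",
                spec.param_path, value, m.peak_pressure_cmH2O,
                m.delivered_volume_mL, wf.mass_residual_fraction * 100.0,
            )
        except Exception as exc:  # noqa: BLE001 — per-row failure is recorded
            log.warning("sweep %s=%s failed: %s", spec.param_path, value, exc)
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
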