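"""Time integration of the coupled valve–tube–lung system.

The breathable-air circuit is a hybrid dynamical system: smooth isothermal
pressure ODEs within each breath phase, with discontinuous valve switching
at phase boundaries. The integrator therefore advances segment by segment
(inspiration / plateau / expiration / rest), so no step straddles a
discontinuity; the volume cutoff (delivered ≥ V_T) is localized with a
terminal root-finding event and the remainder of the inspiratory window is
treated as plateau.

Outputs are a dense :class:`Waveform` (clinical units) and per-breath
:class:`BreathMetrics` (peak pressure, inspiratory-pause plateau,
expiratory pipe platform, PEEP, delivered volume, peak expiratory flow).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .controller import BreathPhase, VCVSettings, commanded_flow, phase_segments
from .lung import LungParams, TubeParams, lung_volume, stored_mass
from .units import PA_PER_CMH2O, GasProperties
from .valves import ValveSpec, ValveArchetype, orifice_mass_flow

#: Bit-exact CSV header of waveform outputs.
WAVEFORM_COLUMNS = [
    "time_s",
    "phase",
    "p_tube_cmH2O",
    "p_lung_cmH2O",
    "flow_insp_L_min",
    "flow_exh_L_min",
    "v_lung_mL",
]

#: Time constant (s) of the first-order area ramp that models the magnetic
#: cushion of the 5/3 actuator: the exhaust area opens as 1 − exp(−t/τ),
#: avoiding an impulsive expiratory kick. Applied only to the 5/3 archetype.
CUSHION_TAU = 0.2

#: Width δ of the linear near-equalization taper of the orifice law used
#: inside the integrator (driving pressures below δ·p_up ≈ 10 Pa); keeps
#: the vector field Lipschitz as chambers equalize.
ORIFICE_BLEND_WIDTH = 1e-4


@dataclass(frozen=True)
class SimOptions:
    """Integrator and metrics options.

    Tolerances are for the stiff-capable adaptive integrator (LSODA) on the
    internal SI state; ``output_dt`` is the sampling interval of the dense
    output; plateau detection thresholds are in clinical units.
    """

    n_cycles: int = 4
    washout_cycles: int = 2
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dt: float = 2e-3
    plateau_eps_cmH2O_s: float = 0.5
    plateau_tau_s: float = 0.2

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if not (0 <= self.washout_cycles < self.n_cycles):
            raise ValueError("washout must leave at least one reported cycle")
        if self.output_dt <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances and output_dt must be positive")


@dataclass(frozen=True)
class Scenario:
    """Fully resolved physical scenario in internal SI units."""

    gas: GasProperties
    tube: TubeParams
    lung: LungParams
    valve: ValveSpec
    vcv: VCVSettings
    sim: SimOptions = field(default_factory=SimOptions)
    name: str = "scenario"
    initial_gauge_pressure: float = 0.0

    @property
    def source_area(self) -> float:
        a = self.vcv.source_area
        return self.valve.effective_area_supply if a is None else a


@dataclass
class Waveform:
    """Dense simulation output in clinical units plus run diagnostics."""

    data: pd.DataFrame
    cycle_period: float
    n_cycles: int
    mass_residual_fraction: float
    scenario_name: str = "scenario"

    def to_csv(self, path) -> None:
        """Write the waveform with the canonical column header."""
        self.data.to_csv(path, index=False, float_format="%.10g",
                         columns=WAVEFORM_COLUMNS)


@dataclass
class PlateauInterval:
    t_start: float
    t_end: float
    pressure: float


@dataclass
class BreathMetrics:
    """Per-breath summary metrics (clinical units).

    ``plateau_*`` refer to the inspiratory-pause plateau (static recoil);
    ``platform_*`` to the flat expiratory tail of the pipe pressure, the
    feature whose presence depends on the exhaust time.
    """

    breath_index: int
    peak_pressure_cmH2O: float
    plateau_pressure_cmH2O: float | None
    plateau_detected: bool
    platform_pressure_cmH2O: float | None
    platform_detected: bool
    peep_cmH2O: float
    delivered_volume_mL: float
    peak_expiratory_flow_L_min: float

    def to_dict(self) -> dict:
        return asdict(self)


class NonPhysicalStateError(RuntimeError):
    """Raised when integration reaches a non-physical state."""


def _circuit_flows(
    t: float,
    p_t: float,
    p_l: float,
    delivered: float,
    phase: BreathPhase,
    t_exh_open: float,
    sc: Scenario,
) -> tuple[float, float, float]:
    """(ṁ_in, ṁ_tl, ṁ_ex) in kg/s for the instantaneous circuit state."""
    gas = sc.gas
    rho = gas.reference_density
    p_atm = gas.atmospheric_pressure

    m_in = 0.0
    if phase is BreathPhase.INSPIRATION:
        q_cmd = commanded_flow(sc.vcv, delivered, phase)
        if q_cmd > 0 and p_t < sc.vcv.source_pressure:
            cap = orifice_mass_flow(sc.source_area, sc.vcv.source_pressure,
                                    p_t, gas, ORIFICE_BLEND_WIDTH)
            m_in = min(rho * q_cmd, cap)

    a_rt = sc.valve.effective_area_supply
    if p_t >= p_l:
        m_tl = orifice_mass_flow(a_rt, p_t, p_l, gas, ORIFICE_BLEND_WIDTH)
    else:
        m_tl = -orifice_mass_flow(a_rt, p_l, p_t, gas, ORIFICE_BLEND_WIDTH)

    m_ex = 0.0
    if phase in (BreathPhase.EXPIRATION, BreathPhase.REST) and p_t > p_atm:
        a_ev = sc.valve.effective_area_exhaust
        if sc.valve.archetype is ValveArchetype.FIVE_THREE_SPRING:
            a_ev *= 1.0 - math.exp(-(t - t_exh_open) / CUSHION_TAU)
        m_ex = orifice_mass_flow(a_ev, p_t, p_atm, gas, ORIFICE_BLEND_WIDTH)
    return m_in, m_tl, m_ex


def simulate(sc: Scenario) -> Waveform:
    """Integrate the scenario and return the dense waveform.

    Raises :class:`NonPhysicalStateError` (with the offending time and
    state) if pressures go non-positive or the lung over-deflates.
    """
    gas, tube, lung, vcv, sim = sc.gas, sc.tube, sc.lung, sc.vcv, sc.sim
    rt = gas.specific_gas_constant * gas.temperature
    rho = gas.reference_density
    p0 = gas.atmospheric_pressure + sc.initial_gauge_pressure

    # state: [p_tube, p_lung, delivered_volume, m_in_cum, m_ex_cum]
    y = np.array([p0, p0, 0.0, 0.0, 0.0])
    m0 = stored_mass(y[0], y[1], tube, lung, gas)

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    phases: list[str] = []

    def rhs_for(phase: BreathPhase, t_exh_open: float):
        c_l = lung.compliance

        def rhs(t, y):
            p_t, p_l, delivered = y[0], y[1], y[2]
            if p_t <= 0 or p_l <= 0:
                raise NonPhysicalStateError(
                    f"non-positive absolute pressure at t={t:.6f}s: "
                    f"p_tube={p_t}, p_lung={p_l}"
                )
            m_in, m_tl, m_ex = _circuit_flows(
                t, p_t, p_l, delivered, phase, t_exh_open, sc
            )
            v_l = lung_volume(p_l, lung, gas)
            dp_t = rt / tube.volume * (m_in - m_tl - m_ex)
            dp_l = rt * m_tl / (v_l + c_l * p_l)
            return [dp_t, dp_l, m_in / rho, m_in, m_ex]

        return rhs

    def integrate_span(t0, t1, phase, t_exh_open, y0, events=None):
        if t1 - t0 < 1e-12:
            return None, y0
        sol = solve_ivp(
            rhs_for(phase, t_exh_open),
            (t0, t1),
            y0,
            method="LSODA",
            rtol=sim.rtol,
            atol=sim.atol,
            dense_output=True,
            events=events,
        )
        if not sol.success:
            raise NonPhysicalStateError(
                f"integration failed in phase {phase.value} at "
                f"t≈{sol.t[-1]:.6f}s: {sol.message}; state={sol.y[:, -1]}"
            )
        t_stop = sol.t[-1]
        ts = np.arange(t0, t_stop, sim.output_dt)
        if ts.size == 0 or t_stop - ts[-1] > 1e-9:
            ts = np.append(ts, t_stop)
        ys = sol.sol(ts)
        times.append(ts)
        states.append(ys)
        phases.extend([phase.value] * ts.size)
        return sol, sol.y[:, -1].copy()

    for cycle in range(sim.n_cycles):
        t_cycle = cycle * vcv.cycle_period
        y[2] = 0.0  # delivered volume resets each breath
        t_exh_open = t_cycle + vcv.inspiratory_time
        for seg_start, seg_end, phase in phase_segments(vcv):
            t0, t1 = t_cycle + seg_start, t_cycle + seg_end
            if phase is BreathPhase.INSPIRATION:
                def volume_cutoff(t, y):
                    return y[2] - vcv.tidal_volume
                volume_cutoff.terminal = True
                volume_cutoff.direction = 1
                sol, y = integrate_span(t0, t1, phase, t_exh_open, y,
                                        events=[volume_cutoff])
                t_reached = sol.t[-1] if sol is not None else t1
                if t1 - t_reached > 1e-9:
                    # volume cutoff fired early: remainder of T_i is plateau
                    _, y = integrate_span(t_reached, t1, BreathPhase.PLATEAU,
                                          t_exh_open, y)
            else:
                _, y = integrate_span(t0, t1, phase, t_exh_open, y)

    t_all = np.concatenate(times)
    y_all = np.hstack(states)
    phase_all = np.array(phases)

    # de-duplicate segment-boundary points (end of one == start of next)
    keep = np.ones(t_all.size, dtype=bool)
    keep[1:] = np.diff(t_all) > 1e-12
    t_all, y_all, phase_all = t_all[keep], y_all[:, keep], phase_all[keep]

    # recompute instantaneous boundary flows at the sampled states
    flows_in = np.empty(t_all.size)
    flows_ex = np.empty(t_all.size)
    v_lung = np.empty(t_all.size)
    for i, (t, ph) in enumerate(zip(t_all, phase_all)):
        cyc = min(int(t // vcv.cycle_period), sim.n_cycles - 1)
        t_open = cyc * vcv.cycle_period + vcv.inspiratory_time
        m_in, _, m_ex = _circuit_flows(
            t, y_all[0, i], y_all[1, i], y_all[2, i], BreathPhase(ph), t_open, sc
        )
        flows_in[i] = m_in / rho
        flows_ex[i] = m_ex / rho
        v_lung[i] = lung_volume(y_all[1, i], lung, gas)

    m_end = stored_mass(y_all[0, -1], y_all[1, -1], tube, lung, gas)
    m_in_cum, m_ex_cum = y[3], y[4]
    throughput = max(m_in_cum, m_ex_cum, 1e-300)
    residual = abs((m_end - m0) - (m_in_cum - m_ex_cum)) / throughput

    p_a = gas.atmospheric_pressure
    df = pd.DataFrame(
        {
            "time_s": t_all,
            "phase": phase_all,
            "p_tube_cmH2O": (y_all[0] - p_a) / PA_PER_CMH2O,
            "p_lung_cmH2O": (y_all[1] - p_a) / PA_PER_CMH2O,
            "flow_insp_L_min": flows_in * 60e3,
            "flow_exh_L_min": flows_ex * 60e3,
            "v_lung_mL": v_lung * 1e6,
        }
    )
    return Waveform(
        data=df,
        cycle_period=vcv.cycle_period,
        n_cycles=sim.n_cycles,
        mass_residual_fraction=residual,
        scenario_name=sc.name,
    )


def detect_plateau(
    t: np.ndarray,
    p: np.ndarray,
    eps: float = 0.5,
    tau: float = 0.2,
) -> PlateauInterval | None:
    """Earliest maximal interval where \\|dp/dt\\| < eps for at least tau.

    ``eps`` in pressure-units per second, ``tau`` in seconds. Returns None
    when no such interval exists (absence is a valid result).
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    if eps <= 0 or tau <= 0:
        raise ValueError("eps and tau must be positive")
    if t.size < 3:
        return None
    slope = np.gradient(p, t)
    flat = np.abs(slope) < eps
    i = 0
    n = t.size
    while i < n:
        if flat[i]:
            j = i
            while j + 1 < n and flat[j + 1]:
                j += 1
            if t[j] - t[i] >= tau:
                return PlateauInterval(
                    t_start=float(t[i]),
                    t_end=float(t[j]),
                    pressure=float(np.mean(p[i : j + 1])),
                )
            i = j + 1
        else:
            i += 1
    return None


def breath_metrics(
    waveform: Waveform | pd.DataFrame,
    plateau_eps: float = 0.5,
    plateau_tau: float = 0.2,
) -> list[BreathMetrics]:
    """Per-breath metrics from a waveform (or its canonical DataFrame).

    Breaths are delimited by INSPIRATION onsets in the phase column; a
    breath is complete when it contains expiratory samples. Raises
    ValueError (reporting the number of complete cycles found) when no
    complete cycle is present.
    """
    df = waveform.data if isinstance(waveform, Waveform) else waveform
    t = df["time_s"].to_numpy()
    phase = df["phase"].to_numpy()
    p_tube = df["p_tube_cmH2O"].to_numpy()
    q_in = df["flow_insp_L_min"].to_numpy()
    q_ex = df["flow_exh_L_min"].to_numpy()

    insp = phase == BreathPhase.INSPIRATION.value
    onsets = np.flatnonzero(insp & ~np.roll(insp, 1))
    if insp.size and insp[0]:
        onsets = np.unique(np.append(onsets, 0))
    if onsets.size == 0:
        raise ValueError("no breath onsets found; 0 complete cycles in trace")

    metrics: list[BreathMetrics] = []
    bounds = list(onsets) + [t.size]
    for b, (i0, i1) in enumerate(zip(bounds[:-1], bounds[1:])):
        sl = slice(i0, i1)
        ph = phase[sl]
        if not np.any(ph == BreathPhase.EXPIRATION.value):
            continue  # incomplete trailing breath
        tb, pb = t[sl], p_tube[sl]
        insp_mask = (ph == BreathPhase.INSPIRATION.value) | (
            ph == BreathPhase.PLATEAU.value
        )
        exp_mask = ph == BreathPhase.EXPIRATION.value

        plateau = (
            detect_plateau(tb[insp_mask], pb[insp_mask], plateau_eps, plateau_tau)
            if insp_mask.sum() >= 3
            else None
        )
        platform = (
            detect_plateau(tb[exp_mask], pb[exp_mask], plateau_eps, plateau_tau)
            if exp_mask.sum() >= 3
            else None
        )
        delivered_L = np.trapezoid(q_in[sl] / 60.0, tb)
        metrics.append(
            BreathMetrics(
                breath_index=b,
                peak_pressure_cmH2O=float(np.max(pb)),
                plateau_pressure_cmH2O=(
                    plateau.pressure if plateau is not None else None
                ),
                plateau_detected=plateau is not None,
                platform_pressure_cmH2O=(
                    platform.pressure if platform is not None else None
                ),
                platform_detected=platform is not None,
                peep_cmH2O=float(pb[-1]),
                delivered_volume_mL=float(delivered_L * 1e3),
                peak_expiratory_flow_L_min=float(np.max(q_ex[sl])),
            )
        )
    if not metrics:
        raise ValueError(
            f"waveform contains 0 complete cycles ({onsets.size} onsets found)"
        )
    return metrics


def steady_state_metrics(
    waveform: Waveform,
    washout_cycles: int = 2,
    plateau_eps: float = 0.5,
    plateau_tau: float = 0.2,
) -> BreathMetrics:
    """Metrics of the last complete breath after the washout count."""
    all_metrics = breath_metrics(waveform, plateau_eps, plateau_tau)
    post = [m for m in all_metrics if m.breath_index >= washout_cycles]
    return post[-1] if post else all_metrics[-1]
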