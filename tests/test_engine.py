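"""Engine: hybrid integration, plateau detection, breath metrics."""

import numpy as np
import pandas as pd
import pytest

from pneumovent.controller import VCVSettings
from pneumovent.engine import (
    SimOptions,
    Scenario,
    WAVEFORM_COLUMNS,
    breath_metrics,
    detect_plateau,
    simulate,
    steady_state_metrics,
)
from pneumovent.lung import LungParams, TubeParams
from pneumovent.units import PA_PER_CMH2O, GasProperties
from pneumovent.valves import ValveArchetype, ValveSpec, critical_pressure_ratio


def _scenario(gas=None, **over):
    gas = gas or GasProperties()
    defaults = dict(
        gas=gas,
        tube=TubeParams(volume=0.5e-3),
        lung=LungParams(compliance=0.05e-3 / PA_PER_CMH2O,
                        unstressed_volume=2.0e-3),
        valve=ValveSpec(archetype=ValveArchetype.FIVE_TWO_BISTABLE,
                        effective_area_supply=12e-6,
                        effective_area_exhaust=6e-6),
        vcv=VCVSettings(tidal_volume=500e-6, inspiratory_time=1.2,
                        plateau_time=0.3, exhaust_time=1.6, cycle_period=4.0,
                        source_pressure=3e5, source_area=3e-6),
        sim=SimOptions(n_cycles=2, washout_cycles=1),
    )
    defaults.update(over)
    return Scenario(**defaults)


# ------------------------------------------------------------------ simulate


def test_equilibrium_fixed_point(gas):
    """Source at atmospheric pressure: nothing can flow, the waveform is flat."""
    sc = _scenario(vcv=VCVSettings(
        tidal_volume=500e-6, inspiratory_time=1.2, plateau_time=0.3,
        exhaust_time=1.6, cycle_period=4.0,
        source_pressure=gas.atmospheric_pressure, source_area=3e-6))
    wf = simulate(sc)
    assert np.allclose(wf.data["p_tube_cmH2O"], 0.0, atol=1e-9)
    assert np.allclose(wf.data["p_lung_cmH2O"], 0.0, atol=1e-9)
    assert np.allclose(wf.data["flow_insp_L_min"], 0.0)
    assert np.allclose(wf.data["flow_exh_L_min"], 0.0)


def test_rigid_fill_matches_linear_closed_form(gas):
    """With the lung path shut, constant commanded inflow charges the rigid
    tube linearly: p(t) = p0 + Rθ·ṁ·t/V_t."""
    sc = _scenario(
        valve=ValveSpec(archetype=ValveArchetype.FIVE_TWO_BISTABLE,
                        effective_area_supply=0.0,
                        effective_area_exhaust=6e-6),
        vcv=VCVSettings(tidal_volume=0.4e-3, inspiratory_time=2.0,
                        plateau_time=0.0, exhaust_time=0.5, cycle_period=2.5,
                        source_pressure=5e5, source_area=3e-6),
        sim=SimOptions(n_cycles=1, washout_cycles=0),
    )
    wf = simulate(sc)
    insp = wf.data[wf.data["phase"] == "INSPIRATION"]
    rt = gas.specific_gas_constant * gas.temperature
    q_cmd = sc.vcv.tidal_volume / sc.vcv.inspiratory_time  # m³/s
    m_dot = q_cmd * gas.reference_density
    t = insp["time_s"].to_numpy()
    expected_gauge = rt * m_dot * t / sc.tube.volume / PA_PER_CMH2O
    p = insp["p_tube_cmH2O"].to_numpy()
    mask = t > 0.1
    assert np.all(
        np.abs(p[mask] - expected_gauge[mask]) / expected_gauge[mask] < 1e-3
    )


def test_delivered_volume_within_one_percent(validation_waveform):
    m = steady_state_metrics(validation_waveform)
    assert m.delivered_volume_mL == pytest.approx(500.0, rel=0.01)


def test_mass_conservation_reported(validation_waveform):
    assert validation_waveform.mass_residual_fraction < 5e-3


def test_quasi_static_limit(gas):
    """Large tube→lung area, no exhaust, long inspiration: the lung charges
    to the source pressure and gains C_l·(p_source − p_a) of volume."""
    p_src = gas.atmospheric_pressure + 20 * PA_PER_CMH2O
    c_l = 0.05e-3 / PA_PER_CMH2O
    sc = _scenario(
        valve=ValveSpec(archetype=ValveArchetype.FIVE_TWO_BISTABLE,
                        effective_area_supply=20e-6,
                        effective_area_exhaust=6e-6),
        lung=LungParams(compliance=c_l, unstressed_volume=2.0e-3),
        vcv=VCVSettings(tidal_volume=10.0, inspiratory_time=60.0,
                        plateau_time=0.0, exhaust_time=1.0, cycle_period=61.0,
                        source_pressure=p_src, source_area=20e-6),
        sim=SimOptions(n_cycles=1, washout_cycles=0, output_dt=0.05),
    )
    wf = simulate(sc)
    insp = wf.data[wf.data["phase"] == "INSPIRATION"]
    p_lung_final = insp["p_lung_cmH2O"].iloc[-1]
    v_gain = insp["v_lung_mL"].iloc[-1] - insp["v_lung_mL"].iloc[0]
    assert p_lung_final == pytest.approx(20.0, rel=0.01)
    assert v_gain * 1e-6 == pytest.approx(c_l * (p_src - gas.atmospheric_pressure),
                                          rel=0.01)


def test_tolerance_halving_changes_peak_by_under_point1_percent():
    sc = _scenario()
    peak1 = steady_state_metrics(simulate(sc), washout_cycles=1).peak_pressure_cmH2O
    sc2 = _scenario(sim=SimOptions(n_cycles=2, washout_cycles=1,
                                   rtol=5e-9, atol=5e-11))
    peak2 = steady_state_metrics(simulate(sc2), washout_cycles=1).peak_pressure_cmH2O
    assert peak2 == pytest.approx(peak1, rel=1e-3)


def test_determinism_bit_identical_csv(tmp_path):
    sc = _scenario()
    f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
    simulate(sc).to_csv(f1)
    simulate(sc).to_csv(f2)
    assert f1.read_bytes() == f2.read_bytes()
    header = f1.read_text().splitlines()[0]
    assert header == ",".join(WAVEFORM_COLUMNS)


def test_exhaust_flow_is_upstream_determined_when_choked(gas):
    """High-pressure circuit: when p_atm/p_tube < b the expiratory flow must
    equal the choked closed form at the instantaneous tube pressure."""
    b = critical_pressure_ratio(gas)
    stiff = LungParams(compliance=1e-9, unstressed_volume=0.2e-3)
    sc = _scenario(
        lung=stiff,
        vcv=VCVSettings(tidal_volume=1.4e-3, inspiratory_time=1.0,
                        plateau_time=0.0, exhaust_time=1.0, cycle_period=2.0,
                        source_pressure=8e5, source_area=6e-6),
        sim=SimOptions(n_cycles=1, washout_cycles=0),
    )
    wf = simulate(sc)
    df = wf.data
    exp = df[(df["phase"] == "EXPIRATION")]
    p_abs = exp["p_tube_cmH2O"].to_numpy() * PA_PER_CMH2O + gas.atmospheric_pressure
    choked_mask = gas.atmospheric_pressure / p_abs < b
    assert choked_mask.any(), "scenario never reaches the choked exhaust regime"
    from pneumovent.valves import orifice_mass_flow

    q = exp["flow_exh_L_min"].to_numpy()[choked_mask]
    expected = np.array([
        orifice_mass_flow(6e-6, p, gas.atmospheric_pressure, gas)
        for p in p_abs[choked_mask]
    ]) / gas.reference_density * 60e3
    assert np.allclose(q, expected, rtol=1e-9)


def test_five_three_cushion_softens_expiratory_onset():
    """The 5/3 archetype ramps its exhaust area open over ~0.2 s, so its
    initial expiratory flow is lower than the 5/2's for the same circuit."""
    sc_52 = _scenario()
    sc_53 = _scenario(valve=ValveSpec(
        archetype=ValveArchetype.FIVE_THREE_SPRING,
        effective_area_supply=12e-6, effective_area_exhaust=6e-6))
    def onset_flow(wf):
        df = wf.data
        exp = df[df["phase"] == "EXPIRATION"]
        t0 = exp["time_s"].iloc[0]
        early = exp[exp["time_s"] <= t0 + 0.05]
        return early["flow_exh_L_min"].max()
    assert onset_flow(simulate(sc_53)) < 0.5 * onset_flow(simulate(sc_52))


# ------------------------------------------------------------- detect_plateau


def test_plateau_detected_on_constant_segment():
    t = np.linspace(0.0, 1.0, 501)
    p = np.where(t < 0.5, 10.0 * t, 5.0)  # ramp then constant 0.5 s ≥ 2τ
    res = detect_plateau(t, p, eps=0.5, tau=0.2)
    assert res is not None
    assert res.pressure == pytest.approx(5.0, abs=0.05)


def test_plateau_absent_on_steep_ramp():
    t = np.linspace(0.0, 1.0, 501)
    assert detect_plateau(t, 10.0 * t, eps=0.5, tau=0.2) is None


def test_plateau_rejects_bad_arguments():
    with pytest.raises(ValueError):
        detect_plateau(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        detect_plateau(np.arange(5.0), np.arange(5.0), eps=0.0)


def test_earliest_flat_interval_wins():
    t = np.linspace(0.0, 3.0, 1501)
    p = np.piecewise(
        t,
        [t < 1.0, (t >= 1.0) & (t < 2.0), t >= 2.0],
        [8.0, lambda x: 8.0 - 6.0 * (x - 1.0), 2.0],
    )
    res = detect_plateau(t, p, eps=0.5, tau=0.2)
    assert res.t_start == pytest.approx(0.0, abs=0.01)
    assert res.pressure == pytest.approx(8.0, abs=0.05)


# ------------------------------------------------------------- breath_metrics


def _synthetic_frame(t, phase, p, q_in, q_ex):
    return pd.DataFrame({
        "time_s": t, "phase": phase, "p_tube_cmH2O": p, "p_lung_cmH2O": p,
        "flow_insp_L_min": q_in, "flow_exh_L_min": q_ex,
        "v_lung_mL": np.full_like(t, 2000.0),
    })


def test_constant_pressure_waveform_metrics_collapse():
    t = np.arange(0.0, 4.0, 0.01)
    phase = np.where(t < 1.2, "INSPIRATION",
                     np.where(t < 2.8, "EXPIRATION", "REST"))
    df = _synthetic_frame(t, phase, np.full_like(t, 7.5),
                          np.zeros_like(t), np.zeros_like(t))
    (m,) = breath_metrics(df)
    assert m.peak_pressure_cmH2O == 7.5
    assert m.peep_cmH2O == 7.5
    assert m.plateau_detected and m.plateau_pressure_cmH2O == pytest.approx(7.5)


def test_triangular_flow_trace_integrates_to_known_area():
    """Triangular inspiratory flow, peak 60 L/min over 1 s → 0.5 L."""
    t = np.arange(0.0, 2.0, 0.001)
    phase = np.where(t < 1.0, "INSPIRATION", "EXPIRATION")
    q = np.where(t < 0.5, 120.0 * t, np.where(t < 1.0, 120.0 * (1.0 - t), 0.0))
    df = _synthetic_frame(t, phase, np.zeros_like(t), q, np.zeros_like(t))
    (m,) = breath_metrics(df)
    assert m.delivered_volume_mL == pytest.approx(500.0, rel=1e-3)


def test_incomplete_cycle_rejected():
    t = np.arange(0.0, 1.0, 0.01)
    df = _synthetic_frame(t, np.full(t.size, "INSPIRATION"),
                          np.zeros_like(t), np.zeros_like(t), np.zeros_like(t))
    with pytest.raises(ValueError, match="complete cycle"):
        breath_metrics(df)


def test_metric_ordering_invariant(validation_waveform):
    for m in breath_metrics(validation_waveform):
        if m.plateau_detected:
            assert m.peak_pressure_cmH2O >= m.plateau_pressure_cmH2O >= m.peep_cmH2O - 1e-9
        assert m.delivered_volume_mL >= 0
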