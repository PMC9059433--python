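# pneumovent

A desk-scale simulator of the breathable-air circuit of an electro-pneumatic
**volume-controlled ventilator (VCV)**: compressible orifice flow through
solenoid gating valves, coupled isothermal tube/lung pressure dynamics with a
single-compartment compliant lung, a piecewise flow-delivery control law, the
switching logic of 5/2, 5/3 and 3/2 valve archetypes with on-delay timer
relays, and parametric sweep tooling over tidal volume and exhaust time.

It is written for engineers and researchers prototyping pneumatic ventilation
circuits (ventilators, neonatal incubators, bench rigs) who need waveform-level
predictions — peak pressure, plateau, PEEP, delivered volume, expiratory
flow — from a handful of physically meaningful parameters, without a full CFD
or hardware-in-the-loop setup.

## Model

The working gas is ideal, the process isothermal, and the circuit leak-free.
Valves are orifices with an effective area `A`; the mass flow from upstream
pressure `p_u` to downstream `p_d` (absolute) follows the converging-nozzle
law with critical ratio `b = (2/(k+1))^(k/(k−1))` (≈ 0.528 for air, k = 1.4):

```
r = p_d/p_u ≤ b (choked):    ṁ = A·p_u·√(k/(Rθ))·(2/(k+1))^((k+1)/(2(k−1)))
r > b (subsonic):            ṁ = A·p_u·√(2k/((k−1)Rθ))·√(r^(2/k) − r^((k+1)/k))
```

The circuit has two chambers: a rigid tube volume `V_t` and a lung with linear
compliance `C_l = dV_l/dp_l` around an unstressed volume `V_l0`. Isothermal
mass balances give

```
dp_t/dt = (Rθ/V_t)·(ṁ_in − ṁ_tl − ṁ_ex)
dp_l/dt = Rθ·ṁ_tl / (V_l(p_l) + C_l·p_l)
```

where `ṁ_in` is the regulated source flow, `ṁ_tl` the tube↔lung orifice flow
(area `A_rt`) and `ṁ_ex` the exhaust-valve flow (area `A_ev`). The VCV law
commands a constant inspiratory flow `Q_T = V_T/(T_i − T_p)` until the set
tidal volume `V_T` is delivered, then holds (plateau) and exhausts. The same
phase alternation can be produced by the emulated electro-pneumatic relay
ladder (pushbutton → relay → on-delay timer → solenoid), where the timer
toggles the valve every `delay` seconds.

## Worked example

```python
from pneumovent import make_preset, simulate, steady_state_metrics

scenario = make_preset("validation").resolve()   # 500 mL, Ti 1.2 s, Te 1.6 s
waveform = simulate(scenario)
m = steady_state_metrics(waveform)
print(m.peak_pressure_cmH2O, m.plateau_pressure_cmH2O, m.delivered_volume_mL)
```

prints (see `examples/02_single_breath.py` for the full script):

```
peak airway pressure :  24.66 cmH2O
inspiratory plateau  :  11.99 cmH2O
PEEP                 :   2.19 cmH2O
delivered volume     :  499.4 mL (set 500)
peak expiratory flow :   15.4 L/min
```

The peak sits inside the 0–40 cmH2O clinical envelope; the plateau is close
to the static-recoil value `V_T/C_l = 10 cmH2O`; delivered volume tracks the
set tidal volume to 0.1%; the nonzero PEEP shows a 1.6 s exhaust does not
quite empty this adult-compliance lung. The `examples/` directory holds one
short narrative script per capability (orifice physics, a single breath, the
tidal-volume and exhaust-time sweeps, the rig relay circuits).

A thin CLI wraps the same library:

```bash
pneumovent presets                      # list the 13 scenario presets
pneumovent simulate --config s.yaml --out wave.csv
pneumovent sweep --config s.yaml --param vcv.tidal_volume \
    --values 300 --values 500 --unit mL --out table.csv
pneumovent metrics wave.csv             # per-breath JSON records
pneumovent selftest                     # built-in physics checks
```

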