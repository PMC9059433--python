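"""Electro-pneumatic rig circuits: relay ladder, on-delay timer, valve.

The bench circuits PA/PB/PC drive a 5/2, 5/3 or 3/2 solenoid valve from a
latched pushbutton through a relay and an on-delay timer; the timer toggles
the valve every `delay` seconds, alternating insufflation and exhaust.
Shows the switching sequence for PA with a 10 s timer, then simulates the
PB1 preset (5/3 valve, whose magnetic cushion ramps the exhaust open over
~0.2 s).
"""

import numpy as np

from pneumovent import (
    circuit_driven_phase,
    make_preset,
    simulate,
    steady_state_metrics,
)

grid = np.arange(0.0, 40.0, 0.25)
phases = circuit_driven_phase("PA", 10.0, grid)
changes = [
    (float(t), p.value)
    for t, p, prev in zip(grid[1:], phases[1:], phases[:-1])
    if p is not prev
]
print("PA circuit, 10 s on-delay timer — valve switch times:")
for t, phase in changes:
    print(f"  t = {t:5.2f} s -> {phase}")

scenario = make_preset("PB1").resolve()  # 5/3 valve, 10 s half-period
waveform = simulate(scenario)
m = steady_state_metrics(waveform, washout_cycles=1)
print(f"\nPB1 rig breath (10 s insufflation / 10 s exhaust):")
print(f"  peak pressure   : {m.peak_pressure_cmH2O:.2f} cmH2O")
print(f"  delivered volume: {m.delivered_volume_mL:.1f} mL")
print(f"  peak exp. flow  : {m.peak_expiratory_flow_L_min:.2f} L/min")
# The switch times at exact timer multiples reproduce the ladder narrative;
# the slow 10 s half-periods give a gentle fill at V_T/10 s = 3 L/min.
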