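"""Compressible orifice flow through a gating valve.

Builds the flow characteristic of a 6 mm² exhalation valve at 200 kPa
upstream: below the critical pressure ratio (≈0.528 for air) the flow is
choked and independent of downstream pressure; above it the flow falls to
zero as the pressures equalize.
"""

import numpy as np

from pneumovent import GasProperties, critical_pressure_ratio, orifice_mass_flow

gas = GasProperties()  # dry air: R=287.05, k=1.4, 293.15 K, 101.325 kPa

b = critical_pressure_ratio(gas)
print(f"critical pressure ratio for air: {b:.4f}  (choked below this)")

area = 6e-6  # 6 mm² effective area
p_up = 200e3  # 200 kPa absolute upstream
for ratio in (0.3, 0.5, b, 0.7, 0.9, 0.99):
    m_dot = orifice_mass_flow(area, p_up, ratio * p_up, gas)
    q_l_min = m_dot / gas.reference_density * 60e3
    regime = "choked" if ratio <= b else "subsonic"
    print(f"p_down/p_up = {ratio:.3f}: {m_dot * 1e3:.3f} g/s "
          f"= {q_l_min:6.1f} L/min  ({regime})")

# The two choked rows are identical: mass flow in the choked regime is set
# entirely by upstream conditions, which is why the exhalation valve empties
# a pressurized circuit at a rate independent of how full the lung still is.
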