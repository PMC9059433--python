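"""Expiratory pressure platform versus exhaust time.

Sweeps the exhaust time over 1.0-1.8 s on a stiff bench lung sized so
passive exhalation takes about 1.5 s. When the exhaust phase outlasts the
exhalation, the pipe pressure trace ends in a flat segment (the "pressure
platform"); when the exhaust is cut short, the trace is still decaying at
end-expiration and no platform appears.
"""

from pneumovent import SweepSpec, exhaust_sweep_base, run_sweep

table = run_sweep(SweepSpec(
    base=exhaust_sweep_base(),
    param_path="vcv.exhaust_time",
    values=(1.0, 1.2, 1.4, 1.6, 1.8),
    unit="s",
))
cols = ["value", "peak_pressure_cmH2O", "peep_cmH2O", "platform_detected"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:8.2f}"))

onset = table.loc[table["platform_detected"], "value"]
if len(onset):
    print(f"\nplatform first appears at exhaust time {onset.iloc[0]:.1f} s")
else:
    print("\nno platform on this grid")
# Short exhaust times leave gas trapped (elevated PEEP and peak pressure);
# platform detection switches on monotonically as the exhaust time grows.
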