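# Methods

## Model and assumptions

The simulator treats the breathable-air circuit of a volume-controlled
ventilator as a hybrid dynamical system: two isothermal ideal-gas chambers
coupled by orifices, with discrete valve switching between breath phases.

Assumptions, in order of importance:

1. **Ideal gas, isothermal.** Every chamber obeys `pV = mRθ` at a fixed
   temperature θ. Compression heating and humidity are ignored; for the
   pressure range of interest (≤ 40 cmH2O ≈ 4 kPa gauge) the isothermal error
   is far below the other modelling uncertainties.
2. **Quasi-balanced switching.** Valves are either open or closed (discrete
   positions); transitions are instantaneous after an optional switching
   delay. The single exception is the 5/3 archetype's magnetic cushion, see
   below.
3. **No leakage.** The only boundary flows are the regulated source and the
   exhaust valve. Mass conservation is therefore a hard invariant: the
   change of stored mass in tube + lung must equal the net integrated
   boundary flow. The engine reports this residual for every run; across all
   fixture scenarios it is below 2 × 10⁻⁶ of throughput (the acceptance
   suite enforces < 0.5%).
4. **Single-compartment linear lung.** `V_l(p_l) = V_l0 + C_l·(p_l − p_a)`
   with constant compliance `C_l`. No recruitment, overdistension curvature,
   inertance or patient effort.
5. **All resistance is concentrated in valve orifices.** The tube↔lung path
   is an orifice of effective area `A_rt`; the exhaust path an orifice
   `A_ev`. There is no separate linear airway resistance.

### Orifice flow

Flow through every valve follows the compressible converging-nozzle law with
critical ratio `b = (2/(k+1))^(k/(k−1))` (0.528 for air): choked flow
depends only on upstream conditions; subsonic flow vanishes as the pressures
equalize. Flows are computed as magnitudes and oriented by the circuit graph
(tube→lung reverses sign during exhalation). The exhaust path is one-way
(no reverse entrainment when the tube falls below atmospheric), modelling
the check-like behaviour of a quick-exhaust valve.

### Delivery law and phases

Inspiration commands a constant flow `Q_T = V_T/(T_i − T_p)` realized by a
regulated pressure source behind a supply orifice (`source_area`,
`source_pressure`): the delivered flow is `min(Q_T, capacity)` where the
capacity is the orifice flow from the source into the tube. If the source
saturates, the breath is flow-limited. Delivery stops at the earlier of the
volume cutoff (`delivered ≥ V_T`, localized by a root-finding event) and the
end of the flow window; the remainder of `T_i` is plateau. The cycle
partitions as inspiration → plateau → expiration → rest with half-open
boundaries.

The electro-pneumatic rig circuits (PA = 5/2 bistable double-coil,
PB = 5/3 spring-return, PC = 3/2 spring-return) produce the same alternation
through a relay ladder: a latched pushbutton energizes relay K1, contact K2
feeds an on-delay timer, and each timer firing toggles the solenoid command
and re-arms the timer, so the valve toggles at t = d, 2d, 3d, … The timer
settings 10/12/14/16 s act as actuation half-periods. An equivalence test
verifies the ladder and the timed phase machine produce identical
inspiration/expiration sequences.

The 5/3 actuator's magnetic cushion is modelled as a first-order exponential
ramp of the exhaust area with time constant 0.2 s, enabled only for that
archetype — the minimal model with the observed "soft start over ~0.2 s"
signature, avoiding an impulsive expiratory kick.

## Parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| R (specific gas constant) | 287.05 | J·kg⁻¹·K⁻¹ | dry air standard |
| k (heat-capacity ratio) | 1.4 | — | dry air standard |
| θ (temperature) | 293.15 | K | room temperature, isothermal |
| p_a (atmospheric) | 101 325 | Pa | standard atmosphere |
| V_t (tube volume) | 0.5 | L | adult circuit tubing |
| C_l (compliance) | 0.05 | L/cmH2O | adult-typical |
| V_l0 (unstressed lung volume) | 2.0 | L | adult FRC |
| A_rt (tube↔lung area) | 12 | mm² | sized so the flow-drive pressure drop at Q_T ≈ 0.56 L/s stays ≈ 13 cmH2O (endotracheal-tube scale); 6 mm² would alone exceed the 0–40 cmH2O envelope |
| A_ev (exhaust area) | 6 | mm² | published validation value |
| source pressure | 300 | kPa abs | regulated medical-gas supply |
| source area | 3 | mm² | choked capacity ≈ 106 L/min ≫ Q_T |
| V_T, T_i, T_p, T_e, cycle | 500 mL, 1.2 s, 0.3 s, 1.6 s, 4 s | | validation breath timing |

All quantities carry explicit unit tags in YAML configs (`Pa`, `kPa`, `MPa`,
`cmH2O`, `L`, `mL`, `L/min`, `s`, `mm2`); the physics core runs in absolute
SI only. Volumetric flows are quoted at atmospheric density (ATPD).
Internally, mass flow is the primitive; the reference density
ρ = p_a/(Rθ) ≈ 1.204 kg/m³ converts at the I/O boundary.

## Scenario families and fixtures

* **Breath family** — clinical timing. The `validation` preset anchors the
  published grids: tidal volumes 300/500/600/700 mL, exhaust times
  1.0–1.8 s, A_ev = 6 mm². (The source's own parameter table is
  typographically fused; only these unambiguous values are adopted.)
* **Rig family** — presets PA1–PC4 mapping valve archetype × timer delay
  (10/12/14/16 s), run as 10 s insufflation / 10 s exhaust alternations
  (and so on), per the half-period reading of the relay narrative.

Two dedicated bases exercise specific metrics:

* **Compliance bench** (`compliance_bench_base`): a bench test-lung
  configuration (V_l0 = 0.5 L, V_t = 0.2 L, 0.5 s pause, 5 s exhaust). The
  static-compliance estimator `C_est = V_delivered/(p_plat − PEEP)` is
  biased upward by gas compression by `(V_t + V_l0)/(p_a·C_l)` — about 4.8%
  at the adult defaults, i.e. comparable to the 5% recovery tolerance
  itself. The bench volumes reduce this physical bias to ≲ 2%, so the grid
  actually tests the estimator rather than the compressible-volume artifact.
  Recovery error across C_l ∈ {0.04, 0.05, 0.06} L/cmH2O ×
  V_T ∈ {300, 400, 500} mL is ≤ 2.7%.
* **Exhaust sweep** (`exhaust_sweep_base`): a stiff lung
  (C_l = 0.008 L/cmH2O, V_T = 300 mL, A_rt = 16 mm², no pause, no rest)
  sized from `ṁ ≈ A√(2ρΔP)` so passive exhalation finishes in ≈ 1.5 s,
  placing the platform transition inside the 1.0–1.8 s grid.

### The two "plateau" notions

`detect_plateau` finds the earliest maximal interval where |dp/dt| < ε for
at least τ (defaults ε = 0.5 cmH2O/s, τ = 0.2 s; both config-exposed, and
the monotone-trend property is insensitive to them over a decade).
Per-breath metrics apply it twice:

* **Inspiratory plateau** (`plateau_*`) — over inspiration + pause; the
  static-recoil pressure used in compliance recovery.
* **Expiratory platform** (`platform_*`) — over the expiration window; the
  flat "pressure platform in the pipe". It appears only when the exhaust
  time outlasts passive exhalation, which is why platform detection is
  monotone non-decreasing in T_e: a shorter exhaust both truncates the tail
  and raises the starting pressure of the next decay.

## Numerical choices

* **Integrator.** LSODA (stiff-capable, adaptive) segment by segment, so no
  step straddles a valve/phase discontinuity; rtol 1e−8, atol 1e−10 in
  internal SI units. The volume cutoff is a terminal root-finding event.
  Halving the tolerances changes peak pressure by < 0.1% (tested).
* **Near-equalization taper.** The exact subsonic law has infinite slope at
  pressure ratio 1 (√ΔP), which collapses adaptive step sizes as chambers
  equalize. Inside the engine the last δ = 1e−4 of the ratio range (driving
  pressures below ≈ 10 Pa ≈ 0.1 cmH2O) is replaced by a linear taper,
  continuous at the junction — the same device as the laminar near-ratio-1
  regime of standard pneumatic component models. The exact law remains the
  default of `orifice_mass_flow` and is what all orifice-level tests
  exercise; the taper changes reported metrics by less than the integrator
  tolerance while cutting some run times by ~500×.
* **Determinism.** The model is deterministic; identical configs produce
  bit-identical CSV output (fixed float formatting). No randomness exists
  outside test/property sampling.
* **Degenerate inputs.** Zero-width plateau segments are dropped; zero areas
  and equal pressures return exactly zero flow; non-positive absolute
  pressures, over-deflated lungs and time regressions raise with the
  offending state.

## What the simulator does and does not show

Passing tests demonstrate the *model's* contracts: choked/subsonic orifice
physics, mass conservation, the VCV delivery law, compliance recovery from
simulated waveforms, and the qualitative parameter trends (peak pressure
rising with tidal volume; the expiratory platform appearing with longer
exhaust times). They do not validate against a physical rig: the original
bench's tube volume, lung compliance and regulator settings are not
published, its result tables are on an MPa pressure scale that is
irreconcilable with the simultaneously stated 0–40 cmH2O operating range,
and the model here is desk-scale clinical. Absolute pressures and flows of
that rig are therefore out of scope; only trends are comparable.

Other known limitations: single lung compartment, no airway inertance or
patient effort, no humidity/FiO2 gas mixtures, no temperature dynamics, no
partial valve-area ramps other than the 5/3 cushion, and volumetric flows
quoted strictly at ATPD.
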