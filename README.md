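# lovewave

Modelling and S-parameter analysis for **Love-wave (SH-SAW) delay-line
sensors** operated under viscous liquid loading — the instrument class used
to probe cell monolayers and calibration liquids with shear acoustic waves.

A Love-wave sensor guides a shear-horizontal surface mode in a slow
polymer layer (here 8 µm SU-8, z = h/λ ≈ 0.05) on a fast piezoelectric
substrate (LiNbO₃ 36Y-X). Two interdigital transducers (IDTs, λ = 144 µm,
f₀ ≈ 30 MHz) launch and receive the wave across a 37λ delay path; a liquid
resting on the guiding layer loads the mode through its shear impedance
√(jωρη) and shows up as extra insertion loss and phase delay in S₂₁. The
deliberately low 30 MHz operating frequency gives a large penetration depth
δ = √(η/(ρπf)) ≈ 100 nm into the liquid — deep enough to reach past the
focal-adhesion zone of adherent cells.

The package provides, as library modules and a `lovewave` CLI:

- **`lovewave.materials`** — characteristic shear impedance and complex
  propagation factor per medium kind (rigid solid, viscoelastic solid via the
  parallel C/G/L circuit, Newtonian liquid), plus glycerol–water mixture
  correlations (Cheng viscosity, Volk–Kähler density) for calibration
  liquids, and a named material library.
- **`lovewave.tlm`** — the acoustic transmission-line model of the layered
  guide: impedance transformation through layers
  (`Z = Zc(ZL + Zc tanh γh)/(Zc + ZL tanh γh)`), transverse-resonance
  dispersion solving `Z_up(kₓ) + Z_down(kₓ) = 0` for the complex wavenumber,
  attenuation, penetration depth, viscosity sweeps and sensitivities.
- **`lovewave.idt`** — the cross-field (Campbell) IDT circuit model
  (radiation conductance Ga ∝ sinc², susceptance Ba, static capacitance C_T,
  conversion loss into 50 Ω) and full delay-line S₂₁ synthesis, including a
  triple-transit echo term.
- **`lovewave.sparams`** — Touchstone v1 `.s2p` I/O (RI/MA/DB), time-domain
  gating (default window 0.2–1.9 µs), minimum-insertion-loss extraction and
  fixed-frequency phase tracking into sensorgrams.
- **`lovewave.synth`** — seeded synthetic spectra and liquid-exchange
  measurement series (noise, feedthrough, echo, exponential mixing) so the
  whole processing chain is testable without instruments.
- **`lovewave.presets`** — the packaged reference 30 MHz design.

## Worked example

```python
from lovewave import presets, tlm
from lovewave.materials import glycerol_properties

sol_air = tlm.solve_dispersion(presets.reference_stack(), 30e6)
sol_wat = tlm.solve_dispersion(presets.reference_stack("water_25C"), 30e6)
print(f"air:   v = {sol_air.phase_velocity:.1f} m/s, alpha = {sol_air.attenuation_db_per_m:.0f} dB/m")
print(f"water: v = {sol_wat.phase_velocity:.1f} m/s, alpha = {sol_wat.attenuation_db_per_m:.0f} dB/m")
print(f"delta(1 cP, 30 MHz) = {tlm.penetration_depth(1e-3, 1000, 30e6)*1e9:.1f} nm")
g = glycerol_properties(0.252, 25.0)
print(f"25.2% w/w glycerol at 25 C: {g.viscosity_cp:.2f} cP, {g.density:.1f} kg/m3")
```

prints

```
air:   v = 4089.5 m/s, alpha = 2414 dB/m
water: v = 4077.1 m/s, alpha = 4484 dB/m
delta(1 cP, 30 MHz) = 103.0 nm
25.2% w/w glycerol at 25 C: 1.80 cP, 1058.1 kg/m3
```

The guided mode travels at ~4.09 km/s under air; water loading slows it
slightly and roughly doubles the propagation loss — those two shifts,
accumulated over the wetted sensing path and added to the two IDT
conversion losses, are exactly what a sensorgram records as the IL and
phase channels.

From the shell, the same physics is available as:

```sh
lovewave sweep --eta-cp 0.893,1.8,2.5,3.3,4.0 --out sweep.csv
lovewave synth --schedule 0:vacuum,300:water_25C,900:glycerol_1.8cP --seed 1 --out-dir run/
lovewave gate run/*.s2p --out-dir gated/
lovewave track run/*.s2p --f0 30 --out sensorgram.csv
```

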