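# Methods

This note documents the physical model, the numerical choices and the
limitations of the `lovewave` package: a transmission-line model (TLM) of a
Love-wave delay-line sensor combined with a cross-field circuit model of its
interdigital transducers (IDTs), plus the S-parameter post-processing chain
(time-domain gating, sensorgram extraction) and a synthetic-data generator
that emulates liquid-exchange experiments.

## 1. Acoustic transmission-line model of the layered guide

### Media

For shear-horizontal (SH) polarization every isotropic medium is described
by its density ρ and a complex shear modulus

    mu_c = mu + j*omega*eta ,

which unifies the three rheological kinds:

| kind                | mu_c            | Zc = sqrt(rho*mu_c)        | k = omega*sqrt(rho/mu_c) |
|---------------------|-----------------|----------------------------|--------------------------|
| rigid solid         | mu              | real                       | real                     |
| Newtonian liquid    | j*omega*eta     | sqrt(j*omega*rho*eta)      | 45° loss angle           |
| viscoelastic solid  | mu + j*omega*eta| complex                    | complex                  |

The viscoelastic (Voigt-type) parallel circuit per unit line length —
compliance C = mu/(omega²eta² + mu²), loss conductance
G = eta*omega²/(omega²eta² + mu²), mass L = rho — is algebraically the same
statement: Y = G + j*omega*C = j*omega/mu_c. Its limits reproduce the rigid
solid (eta → 0) and the Newtonian liquid (mu → 0) exactly; both limits are
asserted by tests at relative 1e-6.

Conventions: time dependence exp(+j*omega*t), propagation exp(−j*k*x).
All square roots are principal-branch, which gives Re(Zc) ≥ 0 (passivity)
and Im(k) ≤ 0 (decay in the direction of travel). The correctness of the
sign conventions is pinned by one exact property: a semi-infinite Newtonian
half-space must present the surface impedance sqrt(j*omega*rho*eta) (the
classical QCM liquid-loading result), which the test suite checks to
machine precision.

### Transverse resonance

For a trial propagation wavenumber k_x along the surface, each medium i
contributes a transverse line with

    gamma_i = sqrt(k_x² − k_i²)   (principal branch)
    Z_t,i   = −j * gamma_i * mu_c,i / omega ,

i.e. the bulk impedance projected by cos(phi) of the transverse
decomposition (k_y = k·cos(phi) = −j·gamma). Finite layers transform a load
through Z = Zc(ZL + Zc·tanh(gamma·h))/(Zc + ZL·tanh(gamma·h)); the formula
is invariant under the branch choice of gamma for finite layers, while
half-spaces use the decaying branch (Re gamma ≥ 0). A guided mode satisfies
Z_up(k_x) + Z_down(k_x) = 0 at a reference plane. The computed root is
independent of where that plane is placed (asserted to 1e-8 relative), so
the default — the substrate/first-layer interface — is only a convention.

### Root finding

1. **Bracketing (lossless twin).** All viscosities are dropped and a liquid
   top is replaced by vacuum; the resonance function is then purely
   imaginary on the real velocity axis. It is scanned over
   (min layer shear velocity, substrate shear velocity) on 4000 uniform
   points, with extra points crowded (a) geometrically toward the substrate
   cutoff, where the thin-layer root hides, and (b) around every layer's
   tan-type pole q·h = (n+½)π, because a large substrate/layer stiffness
   contrast pins a root arbitrarily close to a pole where a uniform scan
   cannot separate the sign changes of the pole/zero pair. Sign changes are
   polished by Brent bisection; "roots" that are actually poles are rejected
   by a residual threshold.
2. **Mode selection.** Roots are ordered by ascending phase velocity and
   mode 0, the fundamental, is the slowest — higher modes approach the
   substrate cutoff. The reference stack is single-mode at 30 MHz
   (q·h ≈ 1.4 < π/2).
3. **Complex polish.** With losses on, the root is refined by a damped
   Newton iteration (numerical derivative, backtracking line search on the
   residual magnitude). When the direct jump from the lossless root fails —
   which happens when the mode is strongly confined in the lossy polymer
   (z ≳ 0.08) — the solver ramps all viscosities geometrically from 2% to
   100% and tracks the root through the homotopy. The final relative
   residual |Z_up+Z_down|/(|Z_up|+|Z_down|) must be below 1e-8.

The solver is cross-checked against two independent oracles: the classical
two-layer Love dispersion relation tan(q·h) = mu_s·s/(mu_l·q) solved by
bisection (50 randomized lossless stacks, 1e-6 relative agreement), and a
partial-wave boundary-condition determinant assembled without the impedance
recursion (lossy three-layer case).

### Outputs

Phase velocity v = omega/Re(k_x); attenuation alpha = −8.686·Im(k_x) dB/m;
penetration depth into a Newtonian liquid delta = sqrt(eta/(rho·pi·f)),
which equals the 1/e decay length 1/|Im k_liq| of the liquid partial wave
exactly (asserted numerically).

## 2. Cross-field IDT model and S21 synthesis

An N_p-pair transducer of aperture W on a substrate with coupling
coefficient K² and finger-pair capacitance per unit aperture C_s has

    X  = N_p·π·(f − f0)/f0,       f0 = v/λ
    Ga = 8·K²·f0·C_s·W·N_p² · (sin X / X)²
    Ba = Ga0 · (sin 2X − 2X)/(2X²)
    C_T = N_p·C_s·W

and converts source power to one-directional acoustic power with loss

    CL = −10·log10( 2·Ga·R / ((1+Ga·R)² + ((Ba+omega·C_T)·R)²) )  [dB].

Defaults for the 36Y-X lithium niobate reference device: K² = 0.16,
C_s = 5e-10 F/m, R = 50 Ω, N_p = 6 ("12 fingers" read as 6 electrode
pairs; a `fingers_are_pairs` switch covers the other reading). The
synchronous frequency uses the free-surface substrate velocity
(4307.9 m/s → 29.92 MHz ≈ the 30 MHz design value), not the slower guided
velocity under the coated IDTs; this is overridable.

An explicit 3 dB bidirectionality term per transducer is available as a
toggle. The packaged reference design leaves it **off**: the plain
cross-field conversion loss is the convention under which the reference
device's model insertion-loss levels are defined, and the toggle documents
rather than hides the ambiguity.

The delay-line transmission is the product

    S21(f) = t_in(f) · t_out(f) · exp(−j·k_x(f)·L),

with |t|² = 10^(−CL/10) and the conversion phase taken from the loaded
admittance divider. k_x(f) is supplied by the dispersion solver, usually as
a handful of samples across the band interpolated linearly (the curve is
smooth between the sampled points at the 9-sample default). A fixture-grade
triple-transit echo multiplies S21 by (1 + r²·exp(−2j·k_x·L)).

### Partially wetted delay path

The physical device wets only the metallized sensing region under the
fluidic chamber — 14λ (2.0 mm) of the 37λ (5.33 mm) delay path. The model
therefore composes the wavenumber as a path average,

    k_eff·L = k_wet·L_w + k_dry·(L − L_w),

with L_w = 14λ by default in the reference configuration. This matters
quantitatively: a fully wetted 37λ path under water adds ~24 dB of liquid
loss, the 14λ sensing region ~9 dB. The fully wetted configuration remains
the default contract of `tlm.viscosity_sweep` (pass `wetted_path` to
restrict it), and both metal-included and metal-free stacks are runnable
(`presets.reference_stack(include_metal=False)`).

With the reference configuration (metal included, 37λ path, 14λ wetted,
plain cross-field conversion) the simulated |S21| at 30 MHz spans about
−32.4 dB (water, 0.893 cP) to −38.7 dB (4 cP glycerol–water). The
viscosity sensitivities on a 0.1 cP grid are about −2.7 dB/cP and −9 °/cP
at the low-viscosity end, with magnitudes decreasing toward 4 cP; note
that an IL span of ~6 dB across 0.9–4 cP *requires* a mean slope of
~2 dB/cP — the IL extremes and the sensitivity curve are mutually
consistent in this model.

## 3. Glycerol–water calibration liquids

Viscosity follows the Cheng (2008) exponent-blending correlation
(mu = mu_w^alpha · mu_g^(1−alpha) with the published a, b, alpha and
pure-component fits; valid 0–100 °C). Density is volume-additive mixing of
the pure components with the Volk & Kähler (2018) contraction correction
kappa = 1 + A·sin(π·w^1.31)^0.81; with rho_g(T) = 1277 − 0.654·T the
amplitude A = 0.0097 (peak contraction ~1 %) reproduces the calibration
table used for the reference experiments to better than 0.1 %. The
mass-fraction inverse (`solve_mass_fraction`) is monotone bisection to 1e-6
relative. Units: SI internally (Pa·s, kg/m³); centipoise only at the user
boundary (1 cP = 1e-3 Pa·s).

## 4. S-parameter post-processing

Touchstone v1 two-port files are read and written directly (RI/MA/DB
encodings, Hz–GHz unit keywords, v1 column order f, S11, S21, S12, S22);
values are printed at 17 significant digits so round trips are exact at
double precision. A `! timestamp_s = ...` comment carries series timing.

Time gating: the band edges are tapered with a Tukey window (10 % cosine
fraction by default) to control ringing, the spectrum is inverse-DFT'd over
the measured band, multiplied by the gate (rectangular window over
[t_start, t_stop], default 0.2–1.9 µs, with a 5 % cosine roll-off), and
transformed back. The output keeps the band-edge taper; the central ~90 %
of the band is untouched by it, which is where all level comparisons are
made. Gates beyond the unambiguous span 1/Δf are rejected. Non-uniform
grids are linearly resampled first. Guaranteed properties (tested):
pass-through of an in-gate single transit to < 0.5 dB mid-band, ≥ 90 %
ripple removal for an out-of-gate echo, linearity, time-domain energy
non-increase, and mid-band idempotence.

Sensorgrams: per spectrum, the minimum insertion loss in a band (ties break
toward lower frequency) and the phase at a fixed frequency (default
30 MHz), read from the gated spectrum by default; phase is unwrapped along
the time series (period 360°), so excursions beyond ±180° stay continuous.

## 5. Synthetic experiments

`synth` generates what a network analyzer would record during a
liquid-exchange run: one spectrum per sampling interval (default 10 s),
following a schedule of liquid steps. Each plateau spectrum is the physical
model (dispersion + IDTs, partially wetted path) decorated with a
triple-transit echo (r = 0.2 default), a constant feedthrough floor
(−80 dB default) and additive complex Gaussian noise (σ = 1e-4 default,
i.e. ~0.04 dB on a −33 dB carrier). Liquid exchanges blend exponentially
with a 30 s default time constant, a first-order stand-in for chamber
mixing. Everything is deterministic given the seed. An overall `gain_db`
lets fixtures match a measured air baseline (for example the −12 dB gated
air level of the reference instrument) without touching the physics.

What the generator does **not** emulate: electromagnetic crosstalk with
structure (the floor is flat), temperature drift, IDT finger reflections
beyond the single echo term, cell sedimentation or any biological loading.
Passing end-to-end tests therefore demonstrate the correctness of the
processing chain on model-faithful data, not agreement with a physical
instrument.

## 6. Known limitations

- The substrate is treated as an isotropic rigid solid with effective shear
  constants; piezoelectric stiffening and electrical loading are outside
  the model (the physical device grounds the delay path to suppress them),
  as are leaky-SAW radiation and anisotropic corrections.
- SU-8's viscosity at 30 MHz is poorly constrained in the literature; the
  packaged 0.12 Pa·s is a working default, not a measured truth, and the
  dry propagation loss (~2.4 dB/mm) scales with it.
- K² and C_s are literature-grade defaults; absolute insertion-loss levels
  inherit their uncertainty (a few dB), while viscosity *shifts* and
  sensitivities are nearly independent of them.
- Experimental devices show larger responses than the TLM at identical
  nominal parameters (electrical interference, guiding-layer rheology);
  the model targets the simulated, not the measured, behaviour.
- Problem sizes used throughout (4000-point dispersion scans, 2001-point
  spectra, 9 dispersion samples per band, ~36-spectrum series) were chosen
  as the smallest that leave all tested quantities converged; they are
  package defaults, not physical constants.
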