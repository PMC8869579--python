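{
  "vacuum": {
    "kind": "vacuum",
    "comment": "Zero-impedance termination; models an air-loaded (unloaded) sensor surface."
  },
  "LiNbO3_36YX_isotropic": {
    "kind": "rigid_solid",
    "density": 4650.0,
    "shear_modulus": 86.3e9,
    "comment": "36Y-X lithium niobate substrate, isotropic-equivalent shear constants for SH propagation along X; shear velocity ~4308 m/s."
  },
  "Cr": {
    "kind": "rigid_solid",
    "density": 7190.0,
    "shear_modulus": 115.0e9,
    "comment": "Chromium adhesion layer (10 nm in the reference stack)."
  },
  "Au": {
    "kind": "rigid_solid",
    "density": 19300.0,
    "shear_modulus": 28.5e9,
    "comment": "Gold metallization (165 nm in the reference stack)."
  },
  "SU8": {
    "kind": "viscoelastic_solid",
    "density": 1100.0,
    "shear_modulus": 1.21e9,
    "viscosity": 0.12,
    "comment": "SU-8 epoxy guiding layer; the 0.12 Pa*s viscosity is an approximate default (no direct literature value at 30 MHz)."
  },
  "water_25C": {
    "kind": "newtonian_liquid",
    "density": 997.0,
    "viscosity": 0.893e-3,
    "comment": "Deionized water at 25 C."
  },
  "glycerol_1.8cP": {
    "kind": "newtonian_liquid",
    "density": 1058.2,
    "viscosity": 1.8e-3,
    "comment": "25.2% w/w glycerol-water at 25 C."
  },
  "glycerol_2.5cP": {
    "kind": "newtonian_liquid",
    "density": 1082.0,
    "viscosity": 2.5e-3,
    "comment": "34.4% w/w glycerol-water at 25 C."
  },
  "glycerol_3.3cP": {
    "kind": "newtonian_liquid",
    "density": 1100.0,
    "viscosity": 3.3e-3,
    "comment": "41.2% w/w glycerol-water at 25 C."
  },
  "glycerol_4cP": {
    "kind": "newtonian_liquid",
    "density": 1111.4,
    "viscosity": 4.0e-3,
    "comment": "45.44% w/w glycerol-water at 25 C."
  }
}
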