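{
  "comment": "Typical covalent force constants (kcal/mol/A^2 for bonds, kcal/mol/rad^2 for angles/impropers) and van der Waals radii (A). Harmonic convention E = k*delta^2. Editable.",
  "bond_k": {
    "default": 300.0,
    "C-C": 250.0,
    "C-N": 320.0,
    "C-O": 450.0,
    "C-S": 240.0
  },
  "angle_k": {
    "default": 50.0
  },
  "improper_k": {
    "default": 50.0
  },
  "ramachandran_k": 2.0,
  "nonbonded_k": 400.0,
  "vdw_scale": 0.9,
  "vdw_radii": {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "H": 1.2,
    "default": 1.7
  }
}
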