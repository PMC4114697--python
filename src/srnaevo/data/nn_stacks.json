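{
  "comment": "Nearest-neighbor helix parameters for intermolecular RNA duplexes (kcal/mol). Stack keys are 'XY/ZW': pair1 = (X,Z), pair2 = (Y,W), pair2 3'-adjacent on strand 1. The table is closed under reverse-complement symmetry at load time; Watson-Crick stacks follow the standard Turner-style values, wobble-containing stacks are a representative approximate subset (the downstream presence rule compares energy ratios, not absolute energies).",
  "initiation": 4.09,
  "loop_open": 4.0,
  "loop_per_nt": 0.3,
  "max_loop": 30,
  "generic_stack": -0.6,
  "stacks": {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
    "AG/UU": -0.55,
    "AU/UG": -1.36,
    "CG/GU": -1.41,
    "CU/GG": -1.53,
    "GG/CU": -2.11,
    "GU/CG": -2.51,
    "GU/UG": -0.50,
    "UG/GU": -0.30,
    "GA/UU": -1.36,
    "UG/AU": -1.27,
    "GG/UU": -0.50
  }
}
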