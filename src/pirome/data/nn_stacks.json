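{
  "comment": "RNA/RNA nearest-neighbor stacking free energies (kcal/mol, 37C). Key XY/WZ denotes the stack 5'-XY-3' over 3'-WZ-5', so X:W and Y:Z are the base pairs. Watson-Crick values follow the standard Turner-style set; G:U-containing stacks are a simplified approximation with a weak default.",
  "initiation": 4.09,
  "wc": {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42
  },
  "gu": {
    "AG/UU": -0.51,
    "AU/UG": -0.70,
    "CG/GU": -1.53,
    "CU/GG": -1.41,
    "GG/CU": -1.53,
    "GU/CG": -1.98,
    "UG/AU": -0.63,
    "UU/AG": -0.70,
    "GA/UU": -0.80,
    "GU/UG": -0.50,
    "UG/GU": -0.60,
    "GG/UU": -0.50,
    "UU/GG": -0.40,
    "default": -0.50
  },
  "loop_penalty": 3.0
}
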