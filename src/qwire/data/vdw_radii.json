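{
  "comment": "Van-der-Waals radii in angstrom (Bondi 1964 set, common protein/ligand elements). Overridable via config.",
  "radii": {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "SE": 1.9,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.0,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "H": 1.2
  },
  "default": 1.7
}
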