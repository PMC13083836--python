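{
  "comment": "Published channel-coordinate (Path.S), tilt (Path.Z, nm^2, negative), ring-flip and binding-mode assignments for the thirteen closed-state complex I structures with a bound Q species. Path.S/flip are inputs to the mode classifier; Mode is the reference label.",
  "models": [
    {"model": 1,  "pdb": "9SMF", "organism": "Bov",   "q": "UQ_10", "nadh": "+", "preparation": "ND",     "rmsd": null, "path_s": 22.8, "path_z": -0.20, "flip": "on",        "mode": "I"},
    {"model": 2,  "pdb": "9SMG", "organism": "Bov",   "q": "UQ_10", "nadh": "+", "preparation": "ND",     "rmsd": 0.03, "path_s": 24.1, "path_z": -0.23, "flip": "off",       "mode": "K.2"},
    {"model": 3,  "pdb": "7QSK", "organism": "Bov",   "q": "UQ_10", "nadh": "-", "preparation": "ND",     "rmsd": 0.23, "path_s": 23.6, "path_z": -0.23, "flip": "off",       "mode": "J.2"},
    {"model": 4,  "pdb": "8Q48", "organism": "Bov",   "q": "UQ_10", "nadh": "-", "preparation": "PL_out", "rmsd": 0.27, "path_s": 22.9, "path_z": -0.21, "flip": "on",        "mode": "I"},
    {"model": 5,  "pdb": "8Q45", "organism": "Bov",   "q": "UQ_10", "nadh": "-", "preparation": "PL_in",  "rmsd": 0.27, "path_s": 22.8, "path_z": -0.20, "flip": "on",        "mode": "I"},
    {"model": 6,  "pdb": "7V2C", "organism": "Porc",  "q": "UQ_10", "nadh": "-", "preparation": "Det",    "rmsd": 0.26, "path_s": 22.9, "path_z": -0.21, "flip": "on",        "mode": "I"},
    {"model": 7,  "pdb": "7V2R", "organism": "Porc",  "q": "UQ_1",  "nadh": "+", "preparation": "Det",    "rmsd": 0.22, "path_s": 22.8, "path_z": -0.21, "flip": "on",        "mode": "I"},
    {"model": 8,  "pdb": "7V2H", "organism": "Porc",  "q": "dQ",    "nadh": "+", "preparation": "Det",    "rmsd": 0.21, "path_s": 23.1, "path_z": -0.22, "flip": "off",       "mode": "J.1"},
    {"model": 9,  "pdb": "8UEP", "organism": "Porc",  "q": "UQ_10", "nadh": "+", "preparation": "In situ","rmsd": 0.42, "path_s": 23.2, "path_z": -0.23, "flip": "off",       "mode": "J.1"},
    {"model": 10, "pdb": "6ZKC", "organism": "Ovi",   "q": "dQ",    "nadh": "+", "preparation": "Det",    "rmsd": 0.48, "path_s": 23.2, "path_z": -0.23, "flip": "off",       "mode": "J.1"},
    {"model": 11, "pdb": "8ESZ", "organism": "Dros",  "q": "UQ_10", "nadh": "-", "preparation": "Det",    "rmsd": 0.67, "path_s": 23.6, "path_z": -0.23, "flip": "off",       "mode": "J.2"},
    {"model": 12, "pdb": "7Z7S", "organism": "Ecoli", "q": "dQ",    "nadh": "+", "preparation": "Det",    "rmsd": 0.91, "path_s": 24.1, "path_z": -0.21, "flip": "undefined", "mode": "K.1"},
    {"model": 13, "pdb": "7Z80", "organism": "Ecoli", "q": "dQ",    "nadh": "+", "preparation": "Det",    "rmsd": 0.92, "path_s": 24.1, "path_z": -0.21, "flip": "undefined", "mode": "K.1"}
  ]
}
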