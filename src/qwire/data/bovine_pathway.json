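{
  "name": "bovine-CI-default",
  "comment": "Default segment definitions for the bovine complex I proton-transfer connectivity table. Anchors named in the published analysis are used verbatim (bovine numbering); TMH7-Lys and terminal-residue anchors not printed there are filled from the mammalian central-axis literature and should be confirmed against the deposited entry before use. 'surface' anchors match waters flagged surface_waters (user-designated bulk-solvent termini).",
  "surface_waters": [],
  "segments": [
    {"code": "Q",    "A": [{"subunit": "NDUFS2", "resnum": 108, "resname": "TYR"},
                           {"subunit": "NDUFS2", "resnum": 59,  "resname": "HIS"}],
                     "B": [{"subunit": "ND1",    "resnum": 204, "resname": "GLU"}]},
    {"code": "E",    "A": [{"subunit": "ND1",    "resnum": 204, "resname": "GLU"}],
                     "B": [{"subunit": "ND3",    "resnum": 66,  "resname": "ASP"}]},
    {"code": "α",    "A": [{"subunit": "ND3",    "resnum": 66,  "resname": "ASP"}],
                     "B": [{"subunit": "ND4L",   "resnum": 70,  "resname": "GLU"}]},
    {"code": "I(2)", "A": [{"subunit": "ND4L",   "resnum": 70,  "resname": "GLU"}],
                     "B": [{"subunit": "ND2",    "resnum": 34,  "resname": "GLU"}]},
    {"code": "S(2)", "A": [{"subunit": "ND2",    "resnum": 34,  "resname": "GLU"}],
                     "B": [{"subunit": "ND2",    "resnum": 105, "resname": "LYS"}]},
    {"code": "C(2)", "A": [{"subunit": "ND2",    "resnum": 105, "resname": "LYS"}],
                     "B": [{"subunit": "ND2",    "resnum": 135, "resname": "LYS"}]},
    {"code": "2",    "A": ["surface"],
                     "B": [{"subunit": "ND2",    "resnum": 135, "resname": "LYS"}]},
    {"code": "T(2)", "A": [{"subunit": "ND2",    "resnum": 135, "resname": "LYS"}],
                     "B": [{"subunit": "ND2",    "resnum": 263, "resname": "LYS"}]},
    {"code": "I(4)", "A": [{"subunit": "ND2",    "resnum": 263, "resname": "LYS"}],
                     "B": [{"subunit": "ND4",    "resnum": 123, "resname": "GLU"}]},
    {"code": "S(4)", "A": [{"subunit": "ND4",    "resnum": 123, "resname": "GLU"}],
                     "B": [{"subunit": "ND4",    "resnum": 206, "resname": "LYS"}]},
    {"code": "C(4)", "A": [{"subunit": "ND4",    "resnum": 206, "resname": "LYS"}],
                     "B": [{"subunit": "ND4",    "resnum": 220, "resname": "HIS"}]},
    {"code": "4",    "A": ["surface"],
                     "B": [{"subunit": "ND4",    "resnum": 220, "resname": "HIS"},
                           {"subunit": "ND4",    "resnum": 228, "resname": "SER"}]},
    {"code": "T(4)", "A": [{"subunit": "ND4",    "resnum": 220, "resname": "HIS"}],
                     "B": [{"subunit": "ND4",    "resnum": 378, "resname": "GLU"}]},
    {"code": "I(5)", "A": [{"subunit": "ND4",    "resnum": 378, "resname": "GLU"}],
                     "B": [{"subunit": "ND5",    "resnum": 146, "resname": "GLU"}]},
    {"code": "S(5)", "A": [{"subunit": "ND5",    "resnum": 146, "resname": "GLU"}],
                     "B": [{"subunit": "ND5",    "resnum": 223, "resname": "LYS"}]},
    {"code": "C(5)", "A": [{"subunit": "ND5",    "resnum": 223, "resname": "LYS"}],
                     "B": [{"subunit": "ND5",    "resnum": 248, "resname": "HIS"}]},
    {"code": "5",    "A": ["surface"],
                     "B": [{"subunit": "ND5",    "resnum": 248, "resname": "HIS"},
                           {"subunit": "ND5",    "resnum": 244, "resname": "SER"}]},
    {"code": "T(5)", "A": [{"subunit": "ND5",    "resnum": 248, "resname": "HIS"}],
                     "B": [{"subunit": "ND5",    "resnum": 392, "resname": "LYS"}]},
    {"code": "X",    "A": [{"subunit": "ND5",    "resnum": 392, "resname": "LYS"}],
                     "B": ["surface"]}
  ]
}
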