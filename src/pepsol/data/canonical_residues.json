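{
  "comment": "The 20 canonical amino acids. hydropathy_pi is the Fauchere-Pliska octanol/water side-chain hydrophobicity (pi) scale; helix_pref and sheet_pref are the Chou-Fasman P_alpha and P_beta statistical secondary-structure preferences. The package z-scores -pi (hydrophilicity) and the two preferences over the 20 residues to build its dimensionless scale table.",
  "residues": [
    {"code": "A", "name": "alanine",       "smiles": "CC(N)C(=O)O",                    "hydropathy_pi": 0.31,  "helix_pref": 1.42, "sheet_pref": 0.83},
    {"code": "R", "name": "arginine",      "smiles": "NC(CCCNC(=N)N)C(=O)O",           "hydropathy_pi": -1.01, "helix_pref": 0.98, "sheet_pref": 0.93},
    {"code": "N", "name": "asparagine",    "smiles": "NC(=O)CC(N)C(=O)O",              "hydropathy_pi": -0.60, "helix_pref": 0.67, "sheet_pref": 0.89},
    {"code": "D", "name": "aspartate",     "smiles": "OC(=O)CC(N)C(=O)O",              "hydropathy_pi": -0.77, "helix_pref": 1.01, "sheet_pref": 0.54},
    {"code": "C", "name": "cysteine",      "smiles": "SCC(N)C(=O)O",                   "hydropathy_pi": 1.54,  "helix_pref": 0.70, "sheet_pref": 1.19},
    {"code": "Q", "name": "glutamine",     "smiles": "NC(=O)CCC(N)C(=O)O",             "hydropathy_pi": -0.22, "helix_pref": 1.11, "sheet_pref": 1.10},
    {"code": "E", "name": "glutamate",     "smiles": "OC(=O)CCC(N)C(=O)O",             "hydropathy_pi": -0.64, "helix_pref": 1.51, "sheet_pref": 0.37},
    {"code": "G", "name": "glycine",       "smiles": "NCC(=O)O",                       "hydropathy_pi": 0.00,  "helix_pref": 0.57, "sheet_pref": 0.75},
    {"code": "H", "name": "histidine",     "smiles": "NC(Cc1c[nH]cn1)C(=O)O",          "hydropathy_pi": 0.13,  "helix_pref": 1.00, "sheet_pref": 0.87},
    {"code": "I", "name": "isoleucine",    "smiles": "CCC(C)C(N)C(=O)O",               "hydropathy_pi": 1.80,  "helix_pref": 1.08, "sheet_pref": 1.60},
    {"code": "L", "name": "leucine",       "smiles": "CC(C)CC(N)C(=O)O",               "hydropathy_pi": 1.70,  "helix_pref": 1.21, "sheet_pref": 1.30},
    {"code": "K", "name": "lysine",        "smiles": "NCCCCC(N)C(=O)O",                "hydropathy_pi": -0.99, "helix_pref": 1.16, "sheet_pref": 0.74},
    {"code": "M", "name": "methionine",    "smiles": "CSCCC(N)C(=O)O",                 "hydropathy_pi": 1.23,  "helix_pref": 1.45, "sheet_pref": 1.05},
    {"code": "F", "name": "phenylalanine", "smiles": "NC(Cc1ccccc1)C(=O)O",            "hydropathy_pi": 1.79,  "helix_pref": 1.13, "sheet_pref": 1.38},
    {"code": "P", "name": "proline",       "smiles": "OC(=O)C1CCCN1",                  "hydropathy_pi": 0.72,  "helix_pref": 0.57, "sheet_pref": 0.55},
    {"code": "S", "name": "serine",        "smiles": "OCC(N)C(=O)O",                   "hydropathy_pi": -0.04, "helix_pref": 0.77, "sheet_pref": 0.75},
    {"code": "T", "name": "threonine",     "smiles": "CC(O)C(N)C(=O)O",                "hydropathy_pi": 0.26,  "helix_pref": 0.83, "sheet_pref": 1.19},
    {"code": "W", "name": "tryptophan",    "smiles": "NC(Cc1c[nH]c2ccccc12)C(=O)O",    "hydropathy_pi": 2.25,  "helix_pref": 1.08, "sheet_pref": 1.37},
    {"code": "Y", "name": "tyrosine",      "smiles": "NC(Cc1ccc(O)cc1)C(=O)O",         "hydropathy_pi": 0.96,  "helix_pref": 0.69, "sheet_pref": 1.47},
    {"code": "V", "name": "valine",        "smiles": "CC(C)C(N)C(=O)O",                "hydropathy_pi": 1.22,  "helix_pref": 1.06, "sheet_pref": 1.70}
  ]
}
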