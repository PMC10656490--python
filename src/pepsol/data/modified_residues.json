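{
  "comment": "Shipped small modified amino acids (mAAs): side-chain modifications plus terminal caps. Codes starting nt/ct are terminal residues (acetylated N-terminus, amidated C-terminus). Structures are the free amino acids, written without stereocentres.",
  "residues": [
    {"code": "NAC",   "name": "N6-acetyl-lysine",            "smiles": "CC(=O)NCCCCC(N)C(=O)O",          "terminal": "none"},
    {"code": "AIB",   "name": "2-aminoisobutyric acid",      "smiles": "CC(C)(N)C(=O)O",                 "terminal": "none"},
    {"code": "NLE",   "name": "norleucine",                  "smiles": "CCCCC(N)C(=O)O",                 "terminal": "none"},
    {"code": "CHA",   "name": "beta-cyclohexyl-alanine",     "smiles": "NC(CC1CCCCC1)C(=O)O",            "terminal": "none"},
    {"code": "CIT",   "name": "citrulline",                  "smiles": "NC(=O)NCCCC(N)C(=O)O",           "terminal": "none"},
    {"code": "DAP",   "name": "2,3-diaminopropionic acid",   "smiles": "NCC(N)C(=O)O",                   "terminal": "none"},
    {"code": "NAP",   "name": "1-naphthyl-alanine",          "smiles": "NC(Cc1cccc2ccccc12)C(=O)O",      "terminal": "none"},
    {"code": "TBA",   "name": "tert-butyl-alanine",          "smiles": "CC(C)(C)CC(N)C(=O)O",            "terminal": "none"},
    {"code": "OPO",   "name": "O-phospho-tyrosine",          "smiles": "NC(Cc1ccc(OP(=O)(O)O)cc1)C(=O)O", "terminal": "none"},
    {"code": "ntDAC", "name": "N-acetyl-aspartate (N-terminal cap)",    "smiles": "CC(=O)NC(CC(=O)O)C(=O)O",  "terminal": "n_term"},
    {"code": "ctFAD", "name": "phenylalaninamide (C-terminal cap)",     "smiles": "NC(Cc1ccccc1)C(N)=O",      "terminal": "c_term"},
    {"code": "ctYAD", "name": "tyrosinamide (C-terminal cap)",          "smiles": "NC(Cc1ccc(O)cc1)C(N)=O",   "terminal": "c_term"}
  ]
}
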