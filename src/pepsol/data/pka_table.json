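[
  {
    "smarts_id": "phosphate_monoester_oh",
    "kind": "acidic",
    "pka": [2.1, 6.7],
    "smarts": "[OX2H1;$([OX2H1][PX4](=[OX1])([OX2H1,OX1-])[OX2H0])]"
  },
  {
    "smarts_id": "carboxylic_acid",
    "kind": "acidic",
    "pka": 4.0,
    "smarts": "[OX2H1;$([OX2H1][CX3]=[OX1])]"
  },
  {
    "smarts_id": "imidazole",
    "kind": "basic",
    "pka": 6.0,
    "smarts": "[nX2H0;$([nX2H0]1c[nX3H1]cc1),$([nX2H0]1cc[nX3H1]c1)]"
  },
  {
    "smarts_id": "thiol",
    "kind": "acidic",
    "pka": 8.3,
    "smarts": "[SX2H1]"
  },
  {
    "smarts_id": "phenol",
    "kind": "acidic",
    "pka": 10.0,
    "smarts": "[OX2H1;$([OX2H1]c)]"
  },
  {
    "smarts_id": "primary_aliphatic_amine",
    "kind": "basic",
    "pka": 10.5,
    "smarts": "[NX3H2;+0;!$([NX3H2][CX3]=[OX1,SX1,NX2,NX3]);!$([NX3H2]a)]"
  },
  {
    "smarts_id": "guanidinium",
    "kind": "basic",
    "pka": 12.5,
    "smarts": "[CX3;$([CX3](=[NX2])([NX3])[NX3]),$([CX3+](=[NX3])([NX3])[NX3])]"
  }
]
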