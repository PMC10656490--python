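{
  "name": "18A amphipathic helix",
  "template": "[ntDAC]WFKAFYDKVAEKFKEA[ctFAD]",
  "numbering_offset": 0,
  "single_site": 11,
  "excluded_positions": [],
  "excluded_residue_letters": [],
  "class_constraints": {
    "hydrophilic": {"letters": ["D", "E", "K"], "mods": ["CIT", "AIB"]},
    "hydrophobic": {"letters": ["W", "F", "A", "V"], "mods": ["CHA", "NAC", "NLE"]}
  },
  "max_substitutions": 2,
  "comment": "The amphipathic character of the helix is preserved by replacing hydrophilic residues only with hydrophilic modifications and hydrophobic residues only with hydrophobic ones; the single-substitution site is the alanine on the edge between the two faces."
}
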