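{
  "name": "GLP-1 (7-36)",
  "template": "HAEGTFTSDVSSYLEGQAAKEFIAWLVKGR",
  "numbering_offset": 6,
  "single_site": 24,
  "excluded_positions": [7, 8, 9, 11, 12, 13, 14, 16, 17, 18, 19, 20, 21, 26, 28, 29, 31, 32, 33, 34],
  "excluded_residue_letters": [],
  "class_constraints": null,
  "max_substitutions": 2,
  "comment": "Positions are in biological numbering (active fragment starts at residue 7). Excluded positions are the receptor-binding residues; the single-substitution site is the first alanine of the linker between the two helices."
}
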