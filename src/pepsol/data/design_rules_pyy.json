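{
  "name": "PYY (3-36)",
  "template": "IKPEAPREDASPEELNRYYASLRHYLNLVTRQR[ctYAD]",
  "numbering_offset": 2,
  "single_site": 12,
  "excluded_positions": [],
  "excluded_residue_letters": ["P", "R", "H", "K", "D", "E", "N", "Q"],
  "class_constraints": null,
  "max_substitutions": 2,
  "comment": "Prolines maintain the N-terminal polyproline fold and the listed hydrogen-bonding residues mediate the helix-helix contacts, so neither may be substituted; the single-substitution site is the alanine in the proline-rich region."
}
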