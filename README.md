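# pepsol

Sequence-based prediction of the intrinsic aqueous solubility of peptides
containing **modified amino acids** (mAAs) — non-canonical residues such as
citrulline, norleucine, acetyl-lysine or phospho-tyrosine that are widely
used in peptide drug development to tune half-life, protease resistance and
binding, but that ordinary sequence-based solubility predictors cannot
handle.

`pepsol` is written for peptide chemists and developability groups who want
to rank large substitution libraries (tens of thousands of variants) by
predicted solubility before committing to synthesis.

## The model

A peptide sequence is written in an extended alphabet: canonical residues as
one-letter codes, modified residues as bracketed codes (`A[NLE]G` =
Ala–norleucine–Gly; `[ntDAC]…[ctFAD]` = acetylated/amidated termini).
Each residue *i* contributes a linear combination of four dimensionless,
z-scored components

```
raw_i = w_H · H_i + w_q · |q_i| − w_α · p_i^α − w_β · p_i^β
```

where `H_i` is hydrophilicity, `q_i` the net fractional charge at the
solution pH (Henderson–Hasselbalch over SMARTS-matched ionizable groups,
plus free-terminus contributions when a terminus is uncapped), and
`p_i^α`, `p_i^β` the α-helix and β-sheet propensities. The raw profile is
smoothed with a boundary-truncated moving average (window 7) and the global
score is its mean; **higher = more soluble**.

Canonical residues use fixed tabulated scales. A modified residue needs only
a SMILES string: RDKit computes molecular weight, H-bond donors/acceptors,
rotatable bonds, TPSA and a Crippen atom-contribution logP, and three
calibrated linear models map these onto the canonical scales —
hydrophilicity from logP (fitted on all 20 canonical residues), and the two
propensities from the descriptor subsets {H_D, TPSA} (α) and
{MW, RB, TPSA} (β), fitted on 18 residues (Gly and Pro excluded as
secondary-structure outliers). An exhaustive best-subset search over all 31
descriptor combinations is available for refitting against custom scales.

The variant designer enumerates all single/double substitutions allowed by
positional design rules (excluded binding residues, forbidden residue
letters, hydrophilic-for-hydrophilic class constraints), scores each variant
and ranks the library. Three shipped rule files replay the GLP-1, PYY3-36
and 18A design campaigns, and the package ships the 37 validation peptides
plus the GLP-1 ultracentrifugation measurements used in `evaluation`.

## Worked example

```sh
$ pepsol predict --seq "HAEGTFTSDVSSYLEGQ[CIT]AKEFIAWLVKGR" \
                 --seq "HAEGTFTSDVSSYLEGQ[CHA]AKEFIAWLVKGR"
seq1	global_score=0.2600
seq2	global_score=0.1312
```

Two GLP-1 variants substituting the same alanine: citrulline (polar side
chain, seq1) scores clearly higher than cyclohexylalanine (bulky aliphatic
ring, seq2) — in the ultracentrifugation data the citrulline variant stayed
fully soluble while the cyclohexylalanine variant precipitated completely.

```sh
$ pepsol screen --campaign pyy --mods CHA,NLE,NAC,AIB,CIT --max-subs 1
scored 75 variants
wild-type score: 0.5935
rank 1	L30CIT	0.6817
rank 38	S23CIT	0.5940
rank 75	S13CHA	0.4803
```

75 = 15 substitutable positions × 5 modifications; positions are reported
in biological numbering (PYY3-36 starts at residue 3). The selection shows
the most soluble, median and least soluble designs.

The same is available from Python:

```python
import pepsol
reg = pepsol.default_registry()
result = pepsol.predict("A[NLE]G", reg)
result.global_score, result.to_frame()
```

New residues register from SMILES alone:

```python
pepsol.register_residue("ORN", "NCCCC(N)C(=O)O", "ornithine", reg)
pepsol.predict("A[ORN]G", reg).global_score
```

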