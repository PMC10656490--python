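# Methods

## Scope and assumptions

`pepsol` predicts *intrinsic* solubility: the sequence-determined component
of aqueous solubility at room temperature, separate from extrinsic factors
(ionic strength, excipients, temperature). The model is additive and local —
each residue contributes independently, a short smoothing window captures
neighbourhood effects, and no tertiary structure, aggregation kinetics, or
pattern corrections (gatekeeper effects, charge alternation) are modelled.
Modifications are restricted to side-chain and terminal changes of roughly
canonical-residue size; lipids, glycans and backbone chemistry changes
(D-amino acids, N-methylation as such) are out of scope — a distinct
stereoisomer or backbone variant can only be represented as its own residue
code with its own structure.

## Chemistry layer

Descriptors are computed on the **whole free amino acid** in its neutral
form, not the side-chain fragment. This makes every registered structure
unambiguous and lets calibration oracles be reproduced from public compound
records; per-residue overrides are possible by editing a saved registry.
Input SMILES are round-tripped through RDKit's canonical writer before any
computation, so every writing of the same molecule yields bit-identical
descriptors and logP.

logP is RDKit's Crippen atom-contribution estimate. Atom-contribution logP
is systematically offset from experimental octanol/water values for
zwitterion-forming compounds, but the calibration layer absorbs affine
scale differences, which is all the downstream model needs.

Ionizable groups are found by an ordered SMARTS table
(`data/pka_table.json`). Each pattern anchors on the single titratable atom
(recursive SMARTS), and matches claim their atoms in table order, so
overlap resolution is first-listed-pattern-wins. Polyprotic groups list
successive macroscopic pKas on one record (phosphate monoester: 2.1, 6.7);
the k-th accepted match of a record takes the k-th value. The shipped
constants are textbook values (carboxylic acid 4.0, imidazole 6.0, thiol
8.3, phenol 10.0, primary aliphatic amine 10.5, guanidinium 12.5) and the
table is a plain editable config. Fractional charge follows
Henderson–Hasselbalch: −1/(1+10^(pKa−pH)) per acidic and +1/(1+10^(pH−pKa))
per basic group.

Backbone α-amine and α-carboxyl groups are excluded from per-residue charge
by a backbone SMARTS filter; they titrate as *termini*, which the engine
adds explicitly: amine pKa 9.0 at the first residue, carboxylate pKa 3.5 at
the last, suppressed when the terminus is capped (N-acetylated or
C-amidated terminal residues). The default pH is 7.0, the pH of the
citrate/phosphate buffer used in the reference solubility assays.

## Canonical scales

The canonical hydrophilicity, helix and sheet scales are declared,
swappable substitutes (the upstream reference tables are not public):

* hydrophilicity: the Fauchère–Pliška side-chain octanol/water π scale,
  negated (hydrophilicity ≈ inverse logP);
* α/β propensities: Chou–Fasman P_α and P_β statistical preferences;
* all three z-scored over the 20 residues, so components are dimensionless
  and commensurable.

Side-chain charges of canonical residues are derived from the same SMARTS
table as modified residues, which keeps the two code paths numerically
identical (verified to 1e-12 by the canonical-path-equivalence tests).

## Calibration

Three ordinary-least-squares models map structure-derived quantities onto
the canonical scales so that registered modified residues land on the same
footing without ever changing the canonical tables:

* hydrophilicity ~ logP, trained on all 20 canonical residues
  (fitted slope ≈ −1.04, r ≈ 0.82 with the shipped scales);
* p^α ~ {H_D, TPSA} and p^β ~ {MW, RB, TPSA}, trained on 18 residues.
  Gly and Pro are excluded: their backbone flexibility/rigidity gives them
  outlying propensities that would skew a fit driven by side-chain
  descriptors.

The propensity feature subsets are pinned defaults; an exhaustive search
over all 2⁵−1 = 31 nonempty subsets of {MW, H_D, H_A, RB, TPSA} is exposed
(`select_propensity_features`) for users refitting against their own
scales. Ranking uses the fit correlation rounded to two decimals, then
fewest features, then lexicographic order — the parsimony tie-break favours
models with as few parameters as possible, and the rounding step is what
makes "fewest features" meaningful. Rank-deficient designs raise a
collinearity error naming the offending columns rather than silently
pseudo-inverting.

## Engine numerics

Component weights default to (+1.0 hydrophilicity, +0.5 |charge|,
−0.3 α, −0.5 β) on the z-scored scales, chosen so that hydrophobicity and
β-propensity reduce the score and charge (either sign) raises it. They are
declared substitutes for unpublished upstream weights and are plain
`EngineParams` fields. Consequences to keep in mind: only *relative* scores
are meaningful, and the shipped defaults are validated by rank behaviour
(see below), not by matching any published absolute values.

Smoothing is a boundary-truncated moving average, default window 7 —
consistent with the short-range windows used across sequence-based
aggregation predictors. It is computed as a full convolution with a ones
kernel divided by per-position counts: each output depends only on raw
values inside its window, so a substitution cannot perturb positions
outside ±(window//2) even in the last floating-point bit. Peptides shorter
than the window use the widest admissible odd window (2L−1), making scores
well-defined down to single residues. The global score is the mean of the
smoothed profile, so peptides of different lengths are comparable.

Degenerate inputs: even or oversized windows and out-of-range pH raise
parameter errors; empty sequences are parse errors; unknown residue codes
surface as lookup errors carrying the offending codes and near-miss
suggestions.

## Designer and evaluation

Variant enumeration is streamed (a generator), never materialized: singles
are |P|·|M|, doubles C(|P|,2)·|M|² with two modifications never sharing a
site. Ranking sorts by descending score with a lexicographic tie-break on
sequence text, making screens bit-reproducible and independent of input
order. The wild type is always scored as the reference row. The shipped
campaign rule files (GLP-1, PYY3-36, 18A) encode the published positional
constraints in biological numbering with a per-template offset.

Measurements support censoring: "S" marks variants that never precipitated
(solubility only bounded from below) and uncensored zeros mark variants
that precipitated completely. Correlation offers two first-class policies —
`drop` (exclude censored records) and `clamp` (assign the extreme observed
value of the matching side) — because there is no single correct way to
correlate against bounds; both are reported with `n_used`. Replicates are
averaged arithmetically before correlation by default.

With the shipped defaults, predicted scores of the ten GLP-1 variants rank
the ultracentrifugation measurements at Spearman ρ ≈ 0.84 (clamp policy,
n = 10; recomputed by `scripts/acceptance.py`, not hard-coded anywhere).

## Synthetic screening conditions

The large-scale checks emulate a realistic single-substitution campaign: a
random 60-residue template, four designated substitutable sites and 10,000
synthetic residue codes (40,000 variants), and a 10-site × 5,000-code
configuration (50,000 variants) for the streamed-scoring check. Synthetic
residues carry standard-normal z-scored property values — matching the
scale, but not the covariance structure, of real residues. Passing these
checks demonstrates enumeration identities, determinism and throughput;
it says nothing further about chemical accuracy, which rests on the
calibration and rank-consistency checks above.

## Known limitations

* Component weights, window and the canonical scales are substitutes;
  absolute scores are not comparable across different scale/weight configs.
* pKa constants are context-free textbook values; microenvironment shifts
  (buried residues, adjacent charges) are ignored.
* The charge term rewards net charge magnitude but has no same-sign
  neighbour damping, so highly charged stretches may be over-rewarded.
* Crippen logP is least reliable for structures far from its training
  chemistry (e.g. organophosphates); registry overrides are the escape
  hatch.
* Only linear (unbranched, uncyclized) topologies are representable.
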