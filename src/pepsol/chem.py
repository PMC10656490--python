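"""Molecular descriptors, logP, ionizable groups and pH-dependent charge.

This module is the chemistry layer of the package: everything downstream
(residue registration, calibration, the solubility engine) sees molecules
only through the quantities computed here.

Descriptors are computed on the whole free amino acid (neutral form) with
RDKit; logP is the Crippen atom-contribution estimate.  Ionizable groups are
located by matching an ordered table of SMARTS patterns, each anchored on the
titratable atom, and converted to fractional charges with the
Henderson-Hasselbalch equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit import RDLogger

from .errors import ConfigurationError, ParameterError, StructureError

RDLogger.DisableLog("rdApp.*")

#: pH of the reference aqueous buffer (10 mM citrate / 10 mM phosphate).
DEFAULT_PH = 7.0


@dataclass(frozen=True)
class DescriptorSet:
    """The five structural descriptors plus logP for one residue structure.

    mw is in g/mol, tpsa in Å², logp in log10 units; the three counts are
    plain non-negative integers.  ``logp`` is ``None`` until estimated.
    """

    mw: float
    h_donors: int
    h_acceptors: int
    rot_bonds: int
    tpsa: float
    logp: float | None = None

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"molecular weight must be positive, got {self.mw}")
        for name in ("h_donors", "h_acceptors", "rot_bonds"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.tpsa < 0:
            raise ValueError(f"tpsa must be non-negative, got {self.tpsa}")

    def with_logp(self, logp: float) -> "DescriptorSet":
        return replace(self, logp=float(logp))

    def as_dict(self) -> dict[str, float]:
        d = {
            "mw": self.mw,
            "h_donors": float(self.h_donors),
            "h_acceptors": float(self.h_acceptors),
            "rot_bonds": float(self.rot_bonds),
            "tpsa": self.tpsa,
        }
        if self.logp is not None:
            d["logp"] = self.logp
        return d


#: Ordered feature names usable in calibration models.
DESCRIPTOR_FEATURES = ("mw", "h_donors", "h_acceptors", "rot_bonds", "tpsa", "logp")


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable site: the pattern that matched, its acid/base kind and
    its dissociation constant."""

    smarts_id: str
    kind: str  # "acidic" | "basic"
    pka: float

    def __post_init__(self) -> None:
        if self.kind not in ("acidic", "basic"):
            raise ValueError(f"kind must be 'acidic' or 'basic', got {self.kind!r}")
        if not 0.0 < self.pka < 14.0:
            raise ValueError(f"pKa must lie in (0, 14), got {self.pka}")


@dataclass(frozen=True)
class PkaRecord:
    """One entry of the ionizable-group table.

    ``pkas`` holds the successive macroscopic dissociation constants assigned
    to successive matches of the pattern in one molecule; polyprotic groups
    (phosphate monoesters) therefore list two values, everything else one.
    """

    smarts_id: str
    kind: str
    pkas: tuple[float, ...]
    smarts: str
    _pattern: Chem.Mol = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ConfigurationError(
                f"invalid SMARTS for ionizable group {self.smarts_id!r}: {self.smarts!r}"
            )
        object.__setattr__(self, "_pattern", patt)


def load_pka_table(path=None) -> list[PkaRecord]:
    """Load an ordered ionizable-group table from JSON.

    With no argument, loads the table shipped with the package.  Invalid
    SMARTS raise :class:`ConfigurationError` here, at load time.
    """
    if path is None:
        text = resources.files("pepsol.data").joinpath("pka_table.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    records = []
    for row in json.loads(text):
        pkas = row["pka"]
        if not isinstance(pkas, list):
            pkas = [pkas]
        records.append(
            PkaRecord(
                smarts_id=row["smarts_id"],
                kind=row["kind"],
                pkas=tuple(float(p) for p in pkas),
                smarts=row["smarts"],
            )
        )
    return records


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"could not parse SMILES {smiles!r}")
    # round-trip through the canonical writing so every SMILES of the same
    # molecule yields a bit-identical atom order (and hence descriptor sums)
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def compute_descriptors(smiles: str) -> DescriptorSet:
    """Compute MW, H-bond donor/acceptor counts, rotatable bonds and TPSA.

    The structure must be a single connected molecule; the returned
    :class:`DescriptorSet` has its ``logp`` field unset (see
    :func:`estimate_logp`).
    """
    mol = _mol_from_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StructureError(
            f"SMILES {smiles!r} describes a disconnected structure; "
            "a single connected molecule is required"
        )
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        h_donors=rdMolDescriptors.CalcNumHBD(mol),
        h_acceptors=rdMolDescriptors.CalcNumHBA(mol),
        rot_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
    )


def estimate_logp(smiles: str) -> float:
    """Crippen atom-contribution octanol/water logP.

    Deterministic: the same molecule (any SMILES writing of it) always gives
    the identical value.
    """
    return Crippen.MolLogP(_mol_from_smiles(smiles))


def assign_pka_groups(
    smiles: str, pka_table: Sequence[PkaRecord]
) -> list[IonizableGroup]:
    """Match the ionizable-group table against a structure.

    Patterns are tried in table order; each match claims its matched atoms and
    later patterns whose match would reuse a claimed atom are skipped
    (first-listed pattern wins).  Successive matches of one polyprotic record
    receive its successive pKa values.  Returns an empty list when nothing
    matches.
    """
    if not pka_table:
        raise ConfigurationError("pKa table must not be empty")
    mol = _mol_from_smiles(smiles)
    claimed: set[int] = set()
    groups: list[IonizableGroup] = []
    for record in pka_table:
        n_accepted = 0
        for match in mol.GetSubstructMatches(record._pattern):
            atoms = set(match)
            if atoms & claimed:
                continue
            claimed |= atoms
            pka = record.pkas[min(n_accepted, len(record.pkas) - 1)]
            groups.append(
                IonizableGroup(smarts_id=record.smarts_id, kind=record.kind, pka=pka)
            )
            n_accepted += 1
    return groups


def assign_pka_groups_with_atoms(
    smiles: str, pka_table: Sequence[PkaRecord]
) -> list[tuple[IonizableGroup, tuple[int, ...]]]:
    """Like :func:`assign_pka_groups` but also report matched atom indices.

    Used by the registry to discard groups that sit on backbone atoms
    (the α-amine and α-carboxyl titrate as termini, not as side chains).
    """
    if not pka_table:
        raise ConfigurationError("pKa table must not be empty")
    mol = _mol_from_smiles(smiles)
    claimed: set[int] = set()
    out: list[tuple[IonizableGroup, tuple[int, ...]]] = []
    for record in pka_table:
        n_accepted = 0
        for match in mol.GetSubstructMatches(record._pattern):
            atoms = set(match)
            if atoms & claimed:
                continue
            claimed |= atoms
            pka = record.pkas[min(n_accepted, len(record.pkas) - 1)]
            out.append(
                (
                    IonizableGroup(
                        smarts_id=record.smarts_id, kind=record.kind, pka=pka
                    ),
                    tuple(match),
                )
            )
            n_accepted += 1
    return out


def group_charge(group: IonizableGroup, ph: float) -> float:
    """Henderson-Hasselbalch fractional charge of one group at a given pH.

    Acidic groups contribute -1/(1 + 10^(pKa - pH)) in (-1, 0); basic groups
    +1/(1 + 10^(pH - pKa)) in (0, +1).
    """
    if group.kind == "acidic":
        return -1.0 / (1.0 + 10.0 ** (group.pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - group.pka))


def fractional_charge(groups: Iterable[IonizableGroup], ph: float = DEFAULT_PH) -> float:
    """Net fractional charge of a set of ionizable groups at a given pH."""
    if not 0.0 <= ph <= 14.0:
        raise ParameterError(f"pH must lie in [0, 14], got {ph}")
    return sum(group_charge(g, ph) for g in groups)
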