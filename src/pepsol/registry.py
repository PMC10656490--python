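"""Catalogue of canonical and modified residues with calibrated properties.

The registry is the single per-residue source of truth downstream of the
chemistry layer.  Canonical residues carry tabulated scale values (z-scored
inverse-logP hydrophilicity and statistical helix/sheet preferences) that are
never recomputed from structure; modified residues carry values predicted by
the calibration models from their SMILES.  Side-chain ionizable groups are
assigned by SMARTS matching, with groups sitting on backbone atoms discarded
(the α-amine and α-carboxyl titrate as termini and are handled by the
solubility engine, not per residue).
"""

from __future__ import annotations

import difflib
import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np
from rdkit import Chem

from . import chem
from .calibration import CalibratorSet, fit_default_calibrators
from .chem import DescriptorSet, IonizableGroup
from .errors import (
    DuplicateCodeError,
    RegistryFormatError,
    ResidueLookupError,
    StructureError,
)

SCHEMA_VERSION = 1

CANONICAL_CODES = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Backbone SMARTS: α-amine (primary or secondary, optionally N-acylated),
#: α-carbon, α-carboxyl or C-terminal amide.  Matched atoms are treated as
#: backbone and excluded from side-chain ionizable-group assignment.
_BACKBONE_SMARTS = (
    "[NX3;H2,H1;+0;!$([NX3][CX3]=[OX1])][CX4][CX3](=[OX1])[OX2H1,NX3H2]",
    "[NX3H1;$([NX3H1][CX3]=[OX1])][CX4][CX3](=[OX1])[OX2H1,NX3H2]",
)
_BACKBONE_PATTERNS = tuple(Chem.MolFromSmarts(s) for s in _BACKBONE_SMARTS)


@dataclass(frozen=True)
class ScaleTable:
    """Per-canonical-residue scale values (dimensionless, z-scored) plus the
    net side-chain charge at the reference pH."""

    hydrophilicity: dict[str, float]
    alpha_prop: dict[str, float]
    beta_prop: dict[str, float]
    charge_ref: dict[str, float]
    reference_ph: float = chem.DEFAULT_PH

    def __post_init__(self) -> None:
        for name in ("hydrophilicity", "alpha_prop", "beta_prop", "charge_ref"):
            table = getattr(self, name)
            if set(table) != set(CANONICAL_CODES):
                raise ValueError(f"{name} must cover exactly the 20 canonical codes")
            if not all(math.isfinite(v) for v in table.values()):
                raise ValueError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class ResidueDefinition:
    """One canonical or modified residue with its calibrated property values."""

    code: str
    name: str
    smiles: str
    hydrophilicity: float
    alpha_prop: float
    beta_prop: float
    charge_groups: tuple[IonizableGroup, ...] = ()
    terminal: str = "none"  # none | n_term | c_term
    provenance: str = "predicted"  # tabulated | predicted
    descriptors: DescriptorSet | None = None

    def __post_init__(self) -> None:
        if self.terminal not in ("none", "n_term", "c_term"):
            raise ValueError(f"invalid terminal flag {self.terminal!r}")
        if self.provenance not in ("tabulated", "predicted"):
            raise ValueError(f"invalid provenance {self.provenance!r}")

    def side_chain_charge(self, ph: float) -> float:
        return chem.fractional_charge(self.charge_groups, ph)


class Registry:
    """Mapping of residue code -> :class:`ResidueDefinition`.

    Entries are immutable; the 20 canonical entries can never be replaced or
    removed once present.
    """

    def __init__(self, entries: dict[str, ResidueDefinition] | None = None):
        self._entries: dict[str, ResidueDefinition] = dict(entries or {})

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def codes(self) -> list[str]:
        return list(self._entries)

    def add(self, definition: ResidueDefinition) -> None:
        if definition.code in self._entries:
            raise DuplicateCodeError(
                f"residue code {definition.code!r} is already registered"
            )
        self._entries[definition.code] = definition

    def get(self, code: str) -> ResidueDefinition:
        try:
            return self._entries[code]
        except KeyError:
            near = difflib.get_close_matches(code, self._entries, n=3, cutoff=0.4)
            hint = f"; nearest known codes: {near}" if near else ""
            raise ResidueLookupError(
                f"unknown residue code {code!r}{hint}"
            ) from None

    def __eq__(self, other) -> bool:
        return isinstance(other, Registry) and self._entries == other._entries


def get_properties(code: str, registry: Registry) -> ResidueDefinition:
    """Fetch one residue; canonical letters always return tabulated values."""
    return registry.get(code)


def _zscore(values: dict[str, float]) -> dict[str, float]:
    arr = np.array([values[c] for c in CANONICAL_CODES], dtype=float)
    mu, sigma = arr.mean(), arr.std()
    return {c: float((values[c] - mu) / sigma) for c in CANONICAL_CODES}


def _load_json_resource(name: str) -> dict:
    return json.loads(resources.files("pepsol.data").joinpath(name).read_text())


@lru_cache(maxsize=1)
def _canonical_source() -> dict[str, dict]:
    data = _load_json_resource("canonical_residues.json")
    return {row["code"]: row for row in data["residues"]}


def _side_chain_groups(smiles: str, pka_table) -> tuple[IonizableGroup, ...]:
    """Assign ionizable groups, dropping those anchored on backbone atoms."""
    # same canonicalized mol as the assignment below, so atom indices agree
    mol = chem._mol_from_smiles(smiles)
    backbone: set[int] = set()
    for patt in _BACKBONE_PATTERNS:
        match = mol.GetSubstructMatch(patt)
        if match:
            backbone = set(match)
            break
    groups = chem.assign_pka_groups_with_atoms(smiles, pka_table)
    return tuple(g for g, atoms in groups if not set(atoms) & backbone)


@lru_cache(maxsize=1)
def default_scales() -> ScaleTable:
    """Canonical scale table: z-scored inverse-logP hydrophilicity, z-scored
    helix/sheet statistical preferences and the side-chain charge at pH 7."""
    src = _canonical_source()
    pka_table = tuple(chem.load_pka_table())
    charge_ref = {
        c: chem.fractional_charge(
            _side_chain_groups(src[c]["smiles"], pka_table), chem.DEFAULT_PH
        )
        for c in CANONICAL_CODES
    }
    return ScaleTable(
        hydrophilicity=_zscore({c: -src[c]["hydropathy_pi"] for c in CANONICAL_CODES}),
        alpha_prop=_zscore({c: src[c]["helix_pref"] for c in CANONICAL_CODES}),
        beta_prop=_zscore({c: src[c]["sheet_pref"] for c in CANONICAL_CODES}),
        charge_ref=charge_ref,
    )


def canonical_descriptor_rows() -> dict[str, dict[str, float]]:
    """Descriptors plus logP for the 20 canonical free amino acids."""
    rows = {}
    for code, row in _canonical_source().items():
        d = chem.compute_descriptors(row["smiles"]).with_logp(
            chem.estimate_logp(row["smiles"])
        )
        rows[code] = d.as_dict()
    return rows


@lru_cache(maxsize=1)
def default_calibrators() -> CalibratorSet:
    """The shipped calibrators, fitted on the canonical residues."""
    return fit_default_calibrators(canonical_descriptor_rows(), default_scales())


def _predict_definition(
    code: str,
    smiles: str,
    name: str,
    calibrators: CalibratorSet,
    pka_table,
    terminal: str = "none",
) -> ResidueDefinition:
    calibrators.require_fitted()
    desc = chem.compute_descriptors(smiles).with_logp(chem.estimate_logp(smiles))
    row = desc.as_dict()
    return ResidueDefinition(
        code=code,
        name=name,
        smiles=smiles,
        hydrophilicity=calibrators.hydrophilicity.predict(row),
        alpha_prop=calibrators.alpha.predict(row),
        beta_prop=calibrators.beta.predict(row),
        charge_groups=_side_chain_groups(smiles, pka_table),
        terminal=terminal,
        provenance="predicted",
        descriptors=desc,
    )


def register_residue(
    code: str,
    smiles: str,
    name: str,
    registry: Registry,
    calibrators: CalibratorSet | None = None,
    pka_table=None,
    terminal: str = "none",
) -> Registry:
    """Register a new modified residue from its SMILES alone.

    Descriptors, logP and ionizable groups are computed from the structure;
    hydrophilicity and propensities come from the calibrated models.  The
    operation never touches other entries.  Canonical one-letter codes are
    reserved and cannot be re-registered.
    """
    if code in CANONICAL_CODES:
        raise DuplicateCodeError(
            f"code {code!r} is a reserved canonical residue letter"
        )
    if code in registry:
        raise DuplicateCodeError(f"residue code {code!r} is already registered")
    if calibrators is None:
        calibrators = default_calibrators()
    if pka_table is None:
        pka_table = tuple(chem.load_pka_table())
    registry.add(
        _predict_definition(code, smiles, name, calibrators, pka_table, terminal)
    )
    return registry


def build_canonical_registry(scales: ScaleTable | None = None) -> Registry:
    """Registry holding only the 20 canonical residues (tabulated values)."""
    scales = scales or default_scales()
    src = _canonical_source()
    pka_table = tuple(chem.load_pka_table())
    reg = Registry()
    for code in CANONICAL_CODES:
        row = src[code]
        desc = chem.compute_descriptors(row["smiles"]).with_logp(
            chem.estimate_logp(row["smiles"])
        )
        reg.add(
            ResidueDefinition(
                code=code,
                name=row["name"],
                smiles=row["smiles"],
                hydrophilicity=scales.hydrophilicity[code],
                alpha_prop=scales.alpha_prop[code],
                beta_prop=scales.beta_prop[code],
                charge_groups=_side_chain_groups(row["smiles"], pka_table),
                terminal="none",
                provenance="tabulated",
                descriptors=desc,
            )
        )
    return reg


def default_registry() -> Registry:
    """The shipped registry: 20 canonical residues plus the 12 stock modified
    amino acids (9 side-chain modifications and 3 terminal caps), the latter
    with properties predicted by the default calibrators."""
    reg = build_canonical_registry()
    calibrators = default_calibrators()
    pka_table = tuple(chem.load_pka_table())
    for row in _load_json_resource("modified_residues.json")["residues"]:
        reg.add(
            _predict_definition(
                row["code"],
                row["smiles"],
                row["name"],
                calibrators,
                pka_table,
                terminal=row.get("terminal", "none"),
            )
        )
    return reg


# ---------------------------------------------------------------------------
# persistence

_REQUIRED_FIELDS = (
    "code",
    "name",
    "smiles",
    "hydrophilicity",
    "alpha_prop",
    "beta_prop",
    "charge_groups",
    "terminal",
    "provenance",
)


def _definition_to_json(d: ResidueDefinition) -> dict:
    out = {
        "code": d.code,
        "name": d.name,
        "smiles": d.smiles,
        "hydrophilicity": d.hydrophilicity,
        "alpha_prop": d.alpha_prop,
        "beta_prop": d.beta_prop,
        "charge_groups": [
            {"smarts_id": g.smarts_id, "kind": g.kind, "pka": g.pka}
            for g in d.charge_groups
        ],
        "terminal": d.terminal,
        "provenance": d.provenance,
    }
    if d.descriptors is not None:
        out["descriptors"] = d.descriptors.as_dict()
    return out


def _definition_from_json(obj: dict, index: int) -> ResidueDefinition:
    for f in _REQUIRED_FIELDS:
        if f not in obj:
            raise RegistryFormatError(
                f"residue entry missing field {f!r} at $.residues[{index}]"
            )
    desc = None
    if "descriptors" in obj:
        dd = obj["descriptors"]
        desc = DescriptorSet(
            mw=dd["mw"],
            h_donors=int(dd["h_donors"]),
            h_acceptors=int(dd["h_acceptors"]),
            rot_bonds=int(dd["rot_bonds"]),
            tpsa=dd["tpsa"],
            logp=dd.get("logp"),
        )
    try:
        groups = tuple(
            IonizableGroup(g["smarts_id"], g["kind"], g["pka"])
            for g in obj["charge_groups"]
        )
        return ResidueDefinition(
            code=obj["code"],
            name=obj["name"],
            smiles=obj["smiles"],
            hydrophilicity=float(obj["hydrophilicity"]),
            alpha_prop=float(obj["alpha_prop"]),
            beta_prop=float(obj["beta_prop"]),
            charge_groups=groups,
            terminal=obj["terminal"],
            provenance=obj["provenance"],
            descriptors=desc,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise RegistryFormatError(
            f"invalid residue entry at $.residues[{index}]: {exc}"
        ) from exc


def save_registry(registry: Registry, path) -> None:
    """Write a registry to the documented JSON dialect."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "residues": [_definition_to_json(registry.get(c)) for c in registry.codes()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_registry(path) -> Registry:
    """Load a registry saved by :func:`save_registry`.

    ``load(save(r)) == r`` by value; schema violations raise
    :class:`RegistryFormatError` naming the JSON path of the first problem.
    """
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise RegistryFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "residues" not in payload:
        raise RegistryFormatError("missing top-level 'residues' key at $")
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise RegistryFormatError(
            f"unsupported schema_version {payload.get('schema_version')!r} at "
            f"$.schema_version"
        )
    reg = Registry()
    for i, obj in enumerate(payload["residues"]):
        reg.add(_definition_from_json(obj, i))
    return reg
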