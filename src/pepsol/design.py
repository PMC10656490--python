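"""Combinatorial substitution libraries under positional design rules.

A design campaign fixes a template peptide and the positions where modified
amino acids may be substituted without disturbing binding or fold:
positions can be excluded explicitly (receptor-binding residues), by residue
letter (prolines, hydrogen-bonding residues), or constrained by class so
that hydrophilic residues only receive hydrophilic modifications and
hydrophobic residues hydrophobic ones.  The designer enumerates all single
or double substitutions allowed by the rules, scores every variant with the
solubility engine, and ranks them; typical selections pick the extremes and
the median of the ranked list.

Three shipped rule files replay the GLP-1, PYY3-36 and 18A campaigns.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

import numpy as np

from .engine import EngineParams, predict_peptide
from .errors import ParameterError
from .parser import (
    ParsedPeptide,
    format_sequence,
    parse_sequence,
    substitution_notation,
)
from .registry import Registry


@dataclass(frozen=True)
class DesignRuleSet:
    """Positional constraints of one design campaign.

    ``excluded_positions`` are 1-based token indices (already converted from
    any biological numbering).  ``class_constraints`` maps a template residue
    letter to the set of modification codes allowed at its positions; when
    present, letters absent from the map are not substitutable at all.
    """

    template: ParsedPeptide
    excluded_positions: frozenset[int] = frozenset()
    excluded_residue_letters: frozenset[str] = frozenset()
    class_constraints: dict[str, frozenset[str]] | None = None
    max_substitutions: int = 2
    numbering_offset: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.template)
        if any(not 1 <= p <= n for p in self.excluded_positions):
            raise ParameterError(
                f"excluded positions outside template length {n}: "
                f"{sorted(self.excluded_positions)}"
            )
        if self.max_substitutions not in (1, 2):
            raise ParameterError("max_substitutions must be 1 or 2")


@dataclass(frozen=True)
class VariantSpec:
    """One library member: where it differs from the template and how."""

    substitutions: tuple[tuple[int, str], ...]
    peptide: ParsedPeptide
    score: float | None = None

    @property
    def sequence_text(self) -> str:
        return format_sequence(self.peptide)

    def variant_id(self, rules: DesignRuleSet) -> str:
        return substitution_notation(
            rules.template, self.substitutions, rules.numbering_offset
        )


def load_rules(path) -> DesignRuleSet:
    """Load a rule file (JSON); positions given in biological numbering are
    converted to 1-based token indices via ``numbering_offset``."""
    with open(path) as fh:
        obj = json.load(fh)
    return _rules_from_json(obj)


def load_builtin_rules(campaign: str) -> DesignRuleSet:
    """Shipped campaigns: ``"glp1"``, ``"pyy"`` or ``"18a"``."""
    name = f"design_rules_{campaign}.json"
    obj = json.loads(resources.files("pepsol.data").joinpath(name).read_text())
    return _rules_from_json(obj)


def _rules_from_json(obj: dict) -> DesignRuleSet:
    template = parse_sequence(obj["template"])
    offset = int(obj.get("numbering_offset", 0))
    constraints = None
    if obj.get("class_constraints"):
        constraints = {}
        for cls in obj["class_constraints"].values():
            allowed = frozenset(cls["mods"])
            for letter in cls["letters"]:
                constraints[letter] = allowed
    return DesignRuleSet(
        template=template,
        excluded_positions=frozenset(
            int(p) - offset for p in obj.get("excluded_positions", ())
        ),
        excluded_residue_letters=frozenset(obj.get("excluded_residue_letters", ())),
        class_constraints=constraints,
        max_substitutions=int(obj.get("max_substitutions", 2)),
        numbering_offset=offset,
        name=obj.get("name", ""),
    )


def allowed_substitutions(
    rules: DesignRuleSet, mods: Iterable[str], registry: Registry | None = None
) -> list[tuple[int, str]]:
    """All (position, modification code) pairs the rules permit.

    Only bare canonical letters are substitutable (terminal caps and existing
    modifications stay); excluded positions and letters are removed, and class
    constraints restrict which modifications each letter may receive.
    Deterministic ordering: by position, then code.
    """
    mods = list(dict.fromkeys(mods))
    if registry is not None:
        for m in mods:
            registry.get(m)  # raises ResidueLookupError for unknown codes
    pairs: list[tuple[int, str]] = []
    for pos, letter in enumerate(rules.template.tokens, start=1):
        if len(letter) != 1:
            continue
        if pos in rules.excluded_positions:
            continue
        if letter in rules.excluded_residue_letters:
            continue
        if rules.class_constraints is not None:
            allowed = rules.class_constraints.get(letter)
            if allowed is None:
                continue
            site_mods = [m for m in mods if m in allowed]
        else:
            site_mods = mods
        pairs.extend((pos, m) for m in sorted(site_mods))
    return pairs


def enumerate_variants(
    rules: DesignRuleSet,
    mods: Iterable[str],
    max_substitutions: int | None = None,
    registry: Registry | None = None,
) -> Iterator[VariantSpec]:
    """Stream all distinct variants with up to ``max_substitutions`` changes.

    Singles: one variant per allowed (position, code) pair.  Doubles: every
    unordered pair of distinct positions with every ordered assignment of
    allowed codes, i.e. two modifications never share a site.  Counts follow
    the closed forms |P|·|M| and C(|P|,2)·|M|² when every site admits every
    modification.
    """
    k = rules.max_substitutions if max_substitutions is None else max_substitutions
    if k not in (1, 2):
        raise ParameterError("max_substitutions must be 1 or 2")
    pairs = allowed_substitutions(rules, mods, registry)
    by_pos: dict[int, list[str]] = {}
    for pos, code in pairs:
        by_pos.setdefault(pos, []).append(code)
    positions = sorted(by_pos)
    for pos in positions:
        for code in by_pos[pos]:
            peptide = rules.template.substitute(pos, code)
            yield VariantSpec(substitutions=((pos, code),), peptide=peptide)
    if k == 2:
        for p1, p2 in itertools.combinations(positions, 2):
            for c1 in by_pos[p1]:
                for c2 in by_pos[p2]:
                    peptide = rules.template.substitute(p1, c1).substitute(p2, c2)
                    yield VariantSpec(
                        substitutions=((p1, c1), (p2, c2)), peptide=peptide
                    )


@dataclass(frozen=True)
class RankedVariant:
    rank: int
    variant_id: str
    sequence_text: str
    score: float
    substitutions: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class ScreenResult:
    """Ranked library plus the wild-type reference and a selection."""

    ranked: tuple[RankedVariant, ...]
    wild_type: RankedVariant
    selection: tuple[RankedVariant, ...]


def screen_and_rank(
    variants: Iterable[VariantSpec],
    rules: DesignRuleSet,
    registry: Registry,
    params: EngineParams | None = None,
    select: str = "extremes+median",
) -> ScreenResult:
    """Score every variant and rank the library.

    Variants are sorted by descending score with a lexicographic tie-break on
    sequence text, so the ranking is deterministic and independent of input
    order.  The wild-type template is always scored and reported as the
    reference.  Strategy ``"extremes+median"`` selects the top, the median
    (element ⌈n/2⌉ of the ranked list) and the bottom variant; ``"all"``
    selects everything.
    """
    params = params or EngineParams()
    scored: list[tuple[float, str, VariantSpec]] = []
    for v in variants:
        result = predict_peptide(v.peptide, registry, params)
        scored.append((result.global_score, v.sequence_text, v))
    scored.sort(key=lambda t: (-t[0], t[1]))
    ranked = tuple(
        RankedVariant(
            rank=i + 1,
            variant_id=v.variant_id(rules),
            sequence_text=text,
            score=score,
            substitutions=v.substitutions,
        )
        for i, (score, text, v) in enumerate(scored)
    )
    wt_result = predict_peptide(rules.template, registry, params)
    wild_type = RankedVariant(
        rank=0,
        variant_id="wild-type",
        sequence_text=format_sequence(rules.template),
        score=wt_result.global_score,
        substitutions=(),
    )
    if not ranked:
        selection: tuple[RankedVariant, ...] = ()
    elif select == "extremes+median":
        median = ranked[(len(ranked) - 1) // 2]
        selection = tuple(dict.fromkeys((ranked[0], median, ranked[-1])))
    elif select == "all":
        selection = ranked
    else:
        raise ParameterError(f"unknown selection strategy {select!r}")
    return ScreenResult(ranked=ranked, wild_type=wild_type, selection=selection)


@dataclass(frozen=True)
class DistributionSummary:
    """Histogram of library scores with the wild type located in it."""

    counts: tuple[int, ...]
    edges: tuple[float, ...]
    minimum: float
    maximum: float
    quantiles: dict[str, float]
    wild_type_score: float | None
    wild_type_bin: int | None
    top_ids: tuple[str, ...]
    bottom_ids: tuple[str, ...]


def summarize_distribution(
    scores,
    bins: int = 50,
    wild_type_score: float | None = None,
    variant_ids: Iterable[str] | None = None,
    k_tails: int = 10,
) -> DistributionSummary:
    """Histogram summary of a screened library's score distribution.

    Bin counts always sum to the number of scores.  When ``variant_ids`` are
    given, the ``k_tails`` highest- and lowest-scoring ids are listed — the
    tails are where the most and least solubilizing modifications show up.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ParameterError("scores must be nonempty")
    if bins < 1:
        raise ParameterError("bins must be >= 1")
    counts, edges = np.histogram(scores, bins=bins)
    q = {
        "q05": float(np.quantile(scores, 0.05)),
        "q25": float(np.quantile(scores, 0.25)),
        "median": float(np.quantile(scores, 0.5)),
        "q75": float(np.quantile(scores, 0.75)),
        "q95": float(np.quantile(scores, 0.95)),
    }
    wt_bin = None
    if wild_type_score is not None:
        wt_bin = int(np.clip(np.digitize(wild_type_score, edges) - 1, 0, bins - 1))
    top_ids: tuple[str, ...] = ()
    bottom_ids: tuple[str, ...] = ()
    if variant_ids is not None:
        ids = list(variant_ids)
        if len(ids) != scores.size:
            raise ParameterError("variant_ids and scores must have equal length")
        order = np.argsort(-scores, kind="stable")
        top_ids = tuple(ids[i] for i in order[:k_tails])
        bottom_ids = tuple(ids[i] for i in order[::-1][:k_tails])
    return DistributionSummary(
        counts=tuple(int(c) for c in counts),
        edges=tuple(float(e) for e in edges),
        minimum=float(scores.min()),
        maximum=float(scores.max()),
        quantiles=q,
        wild_type_score=wild_type_score,
        wild_type_bin=wt_bin,
        top_ids=top_ids,
        bottom_ids=bottom_ids,
    )
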