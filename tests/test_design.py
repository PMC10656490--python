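"""Variant designer: rules, enumeration, screening, distribution summary."""

import itertools
import math

import numpy as np
import pytest

from pepsol.design import (
    DesignRuleSet,
    allowed_substitutions,
    enumerate_variants,
    load_builtin_rules,
    screen_and_rank,
    summarize_distribution,
)
from pepsol.errors import ParameterError, ResidueLookupError
from pepsol.parser import parse_sequence

MODS = ["CHA", "NLE", "NAC", "AIB", "CIT"]


class TestBuiltinRules:
    def test_glp1_excludes_exactly_the_binding_residues(self):
        rules = load_builtin_rules("glp1")
        pairs = allowed_substitutions(rules, MODS)
        touched = {p for p, _ in pairs}
        # biological numbering 7..36 -> token indices 1..30; the 20 binding
        # residues are excluded
        excluded_bio = {7, 8, 9, 11, 12, 13, 14, 16, 17, 18, 19, 20, 21, 26,
                        28, 29, 31, 32, 33, 34}
        expected = {
            i for i in range(1, 31) if i + rules.numbering_offset not in excluded_bio
        }
        assert touched == expected

    def test_pyy_never_touches_hydrogen_bonding_residues(self):
        rules = load_builtin_rules("pyy")
        pairs = allowed_substitutions(rules, MODS)
        forbidden = set("PRHKDENQ")
        for pos, _ in pairs:
            assert rules.template.tokens[pos - 1] not in forbidden

    def test_18a_class_constraints_pair_like_with_like(self, registry):
        rules = load_builtin_rules("18a")
        pairs = allowed_substitutions(rules, MODS, registry)
        hydrophilic, hydrophobic = set("DEK"), set("WFAV")
        for pos, code in pairs:
            letter = rules.template.tokens[pos - 1]
            if letter in hydrophilic:
                assert code in {"CIT", "AIB"}
            else:
                assert letter in hydrophobic and code in {"CHA", "NAC", "NLE"}

    def test_18a_terminal_caps_never_substituted(self):
        rules = load_builtin_rules("18a")
        positions = {p for p, _ in allowed_substitutions(rules, MODS)}
        assert 1 not in positions and len(rules.template) not in positions

    def test_single_sites_are_alanines(self):
        # each campaign's single-substitution site is an alanine of the
        # template (common baseline across campaigns)
        for campaign in ("glp1", "pyy", "18a"):
            rules = load_builtin_rules(campaign)
            import json
            from importlib import resources

            obj = json.loads(
                resources.files("pepsol.data")
                .joinpath(f"design_rules_{campaign}.json")
                .read_text()
            )
            token_index = obj["single_site"] - rules.numbering_offset
            assert rules.template.tokens[token_index - 1] == "A", campaign


class TestAllowedSubstitutions:
    def test_empty_mods_gives_empty_result(self):
        rules = load_builtin_rules("pyy")
        assert allowed_substitutions(rules, []) == []

    def test_unknown_mod_code_raises(self, registry):
        rules = load_builtin_rules("pyy")
        with pytest.raises(ResidueLookupError):
            allowed_substitutions(rules, ["QQQ"], registry)

    def test_ordering_deterministic(self):
        rules = load_builtin_rules("pyy")
        pairs = allowed_substitutions(rules, list(reversed(MODS)))
        assert pairs == sorted(pairs)


def _toy_rules(seq="AAAGA", max_subs=2, **kw):
    return DesignRuleSet(template=parse_sequence(seq), max_substitutions=max_subs, **kw)


class TestEnumeration:
    def test_single_count_closed_form(self):
        rules = _toy_rules("AAAA", max_subs=1)
        variants = list(enumerate_variants(rules, ["X1", "X2", "X3"]))
        assert len(variants) == 4 * 3  # |P| * |M|

    def test_one_position_five_mods(self):
        rules = _toy_rules("A", max_subs=1)
        variants = list(enumerate_variants(rules, MODS))
        assert len(variants) == 5

    def test_double_count_matches_brute_force(self):
        rules = _toy_rules("AAA", max_subs=2)
        mods = ["X1", "X2"]
        variants = list(enumerate_variants(rules, mods))
        # brute force: exhaustive nested loops with dedup by sequence text
        brute = set()
        positions = [1, 2, 3]
        for p, m in itertools.product(positions, mods):
            brute.add(rules.template.substitute(p, m).tokens)
        for (p1, p2) in itertools.combinations(positions, 2):
            for m1, m2 in itertools.product(mods, repeat=2):
                brute.add(rules.template.substitute(p1, m1).substitute(p2, m2).tokens)
        assert {v.peptide.tokens for v in variants} == brute
        n_singles = 3 * 2
        n_doubles = math.comb(3, 2) * 2**2
        assert len(variants) == n_singles + n_doubles == 18
        assert len({v.sequence_text for v in variants}) == len(variants)

    @pytest.mark.parametrize("n_pos,n_mods", [(2, 1), (4, 3), (6, 4)])
    def test_count_identity_property(self, n_pos, n_mods):
        rules = _toy_rules("A" * n_pos, max_subs=2)
        mods = [f"X{i}" for i in range(n_mods)]
        variants = list(enumerate_variants(rules, mods))
        expected = n_pos * n_mods + math.comb(n_pos, 2) * n_mods**2
        assert len(variants) == expected
        assert len({v.sequence_text for v in variants}) == expected

    def test_two_mods_never_share_a_site(self):
        rules = _toy_rules("AAAA", max_subs=2)
        for v in enumerate_variants(rules, ["X1", "X2"]):
            positions = [p for p, _ in v.substitutions]
            assert len(positions) == len(set(positions))

    def test_invalid_max_substitutions(self):
        rules = _toy_rules("AAA")
        with pytest.raises(ParameterError):
            list(enumerate_variants(rules, ["X"], max_substitutions=3))


class TestScreening:
    def test_extremes_plus_median_ordering(self, registry):
        rules = _toy_rules("KAKAK", max_subs=1)
        variants = enumerate_variants(rules, ["CHA", "CIT", "NLE"])
        result = screen_and_rank(variants, rules, registry)
        assert len(result.selection) == 3
        top, median, bottom = result.selection
        assert top.score >= median.score >= bottom.score
        assert top.rank == 1 and bottom.rank == len(result.ranked)

    def test_wild_type_always_scored(self, registry):
        rules = _toy_rules("KAKAK", max_subs=1)
        result = screen_and_rank(enumerate_variants(rules, ["CIT"]), rules, registry)
        assert result.wild_type.variant_id == "wild-type"
        assert math.isfinite(result.wild_type.score)

    def test_order_independence(self, registry):
        rules = _toy_rules("KAKAK", max_subs=2)
        variants = list(enumerate_variants(rules, ["CHA", "CIT"]))
        forward = screen_and_rank(variants, rules, registry)
        backward = screen_and_rank(list(reversed(variants)), rules, registry)
        assert forward.ranked == backward.ranked

    def test_ranking_bit_identical_across_runs(self, registry, fixture_peptides):
        rules = load_builtin_rules("glp1")
        variants = list(enumerate_variants(rules, MODS, max_substitutions=1))
        r1 = screen_and_rank(variants, rules, registry)
        r2 = screen_and_rank(variants, rules, registry)
        assert r1.ranked == r2.ranked

    def test_duplicate_scores_tie_broken_lexicographically(self):
        from pepsol.registry import Registry, ResidueDefinition

        reg = Registry()
        for code in ("A", "G"):
            reg.add(ResidueDefinition(code=code, name=code, smiles="",
                                      hydrophilicity=0.0, alpha_prop=0.0,
                                      beta_prop=0.0, provenance="tabulated"))
        for code in ("X1", "X2"):  # identical properties -> tied scores
            reg.add(ResidueDefinition(code=code, name=code, smiles="",
                                      hydrophilicity=1.0, alpha_prop=0.0,
                                      beta_prop=0.0))
        rules = _toy_rules("AGA", max_subs=1)
        result = screen_and_rank(enumerate_variants(rules, ["X2", "X1"]), rules, reg)
        texts = [r.sequence_text for r in result.ranked]
        scores = [r.score for r in result.ranked]
        for a, b, sa, sb in zip(texts, texts[1:], scores, scores[1:]):
            if sa == sb:
                assert a < b


class TestDistribution:
    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        summary = summarize_distribution(scores, bins=10)
        assert sum(summary.counts) == 100

    def test_all_equal_scores_occupy_one_bin(self):
        summary = summarize_distribution([1.5] * 40, bins=8)
        assert sorted(summary.counts)[-1] == 40
        assert sum(1 for c in summary.counts if c) == 1

    def test_tails_match_full_sort_oracle(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60)
        ids = [f"v{i}" for i in range(60)]
        summary = summarize_distribution(scores, bins=5, variant_ids=ids, k_tails=4)
        order = np.argsort(-scores, kind="stable")
        assert list(summary.top_ids) == [ids[i] for i in order[:4]]
        assert list(summary.bottom_ids) == [ids[i] for i in order[::-1][:4]]

    def test_wild_type_bin_annotated(self):
        summary = summarize_distribution(
            np.linspace(0, 1, 50), bins=10, wild_type_score=0.55
        )
        assert summary.wild_type_bin == 5
        assert summary.quantiles["median"] == pytest.approx(0.5, abs=0.02)
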