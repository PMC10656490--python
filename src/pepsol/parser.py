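"""Extended-alphabet peptide sequence parsing.

Sequences use the 20 canonical one-letter codes plus bracketed multi-letter
codes for modified amino acids, e.g. ``A[NLE]G`` for Ala-norleucine-Gly.
Codes beginning ``nt``/``ct`` denote capped terminal residues and may appear
only as the first/last token (``[ntDAC]WFK...A[ctFAD]``).  A terminal-capped
residue counts as one residue.

The grammar is deliberately permissive about what goes inside brackets: any
nonempty bracket content is accepted as a residue code, so any modification
nomenclature can be used as long as it is registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SequenceSyntaxError

CANONICAL_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ParsedPeptide:
    """An ordered list of residue codes with terminal-modification state."""

    tokens: tuple[str, ...]
    n_term_mod: str | None = None
    c_term_mod: str | None = None
    source_text: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def substitute(self, position: int, code: str) -> "ParsedPeptide":
        """Return a copy with the residue at 1-based ``position`` replaced."""
        if not 1 <= position <= len(self.tokens):
            raise IndexError(f"position {position} outside 1..{len(self.tokens)}")
        tokens = list(self.tokens)
        tokens[position - 1] = code
        p = ParsedPeptide(
            tokens=tuple(tokens),
            n_term_mod=self.n_term_mod,
            c_term_mod=self.c_term_mod,
        )
        return ParsedPeptide(
            tokens=p.tokens,
            n_term_mod=p.n_term_mod,
            c_term_mod=p.c_term_mod,
            source_text=format_sequence(p),
        )


def _is_terminal_code(token: str) -> str | None:
    if len(token) > 2 and token.startswith("nt"):
        return "n_term"
    if len(token) > 2 and token.startswith("ct"):
        return "c_term"
    return None


def parse_sequence(text: str) -> ParsedPeptide:
    """Parse an extended-alphabet sequence string.

    Raises :class:`SequenceSyntaxError` (with the character offset) for
    unbalanced, nested or empty brackets, for characters outside the
    uppercase canonical alphabet, and for terminal-capped codes that are not
    at the corresponding sequence end.
    """
    stripped = text.strip()
    if not stripped:
        raise SequenceSyntaxError("empty sequence")
    tokens: list[str] = []
    token_offsets: list[int] = []
    i = 0
    n = len(stripped)
    while i < n:
        ch = stripped[i]
        if ch == "[":
            close = stripped.find("]", i + 1)
            if close == -1:
                raise SequenceSyntaxError("unbalanced '['", offset=i)
            inner = stripped[i + 1 : close]
            if not inner:
                raise SequenceSyntaxError("empty brackets", offset=i)
            if "[" in inner:
                raise SequenceSyntaxError("nested '['", offset=i + 1 + inner.index("["))
            tokens.append(inner)
            token_offsets.append(i)
            i = close + 1
        elif ch == "]":
            raise SequenceSyntaxError("unbalanced ']'", offset=i)
        elif ch in CANONICAL_LETTERS:
            tokens.append(ch)
            token_offsets.append(i)
            i += 1
        else:
            raise SequenceSyntaxError(
                f"invalid character {ch!r}: bare residues must be uppercase "
                "canonical letters",
                offset=i,
            )
    n_term_mod = c_term_mod = None
    for idx, (tok, off) in enumerate(zip(tokens, token_offsets)):
        role = _is_terminal_code(tok)
        if role == "n_term":
            if idx != 0:
                raise SequenceSyntaxError(
                    f"N-terminal code {tok!r} only allowed as first residue",
                    offset=off,
                )
            n_term_mod = tok
        elif role == "c_term":
            if idx != len(tokens) - 1:
                raise SequenceSyntaxError(
                    f"C-terminal code {tok!r} only allowed as last residue",
                    offset=off,
                )
            c_term_mod = tok
    return ParsedPeptide(
        tokens=tuple(tokens),
        n_term_mod=n_term_mod,
        c_term_mod=c_term_mod,
        source_text=stripped,
    )


def format_sequence(p: ParsedPeptide) -> str:
    """Render a peptide canonically: bare canonical letters, everything else
    bracketed.  ``parse_sequence(format_sequence(p))`` is structurally ``p``."""
    parts = []
    for tok in p.tokens:
        if len(tok) == 1 and tok in CANONICAL_LETTERS:
            parts.append(tok)
        else:
            parts.append(f"[{tok}]")
    return "".join(parts)


def validate_tokens(p: ParsedPeptide, registry) -> list[str]:
    """Report residue codes not resolvable against a registry.

    Returns the distinct unknown codes in first-appearance order; an empty
    list means the peptide is fully resolvable.  Never raises for unknown
    codes — reporting is the contract.
    """
    seen: list[str] = []
    for tok in p.tokens:
        if tok not in registry and tok not in seen:
            seen.append(tok)
    return seen


def substitution_notation(p: ParsedPeptide, substitutions, offset: int = 0) -> str:
    """Human-readable ``A24CHA``-style notation for a substitution list.

    ``offset`` shifts reported positions into a biological numbering
    (position printed = token index + offset).
    """
    parts = []
    for pos, code in substitutions:
        parts.append(f"{p.tokens[pos - 1]}{pos + offset}{code}")
    return "+".join(parts) if parts else "wild-type"


def read_fasta(path) -> list[tuple[str, ParsedPeptide]]:
    """Read a FASTA-dialect file whose sequence lines may contain bracket
    tokens.

    Sequence lines of one record are concatenated before parsing, but a
    bracket token may not be split across lines: every line must have
    balanced brackets, otherwise a :class:`SequenceSyntaxError` is raised
    with the offending line number.
    """
    records: list[tuple[str, ParsedPeptide]] = []
    header: str | None = None
    chunks: list[str] = []

    def flush():
        if header is not None:
            records.append((header, parse_sequence("".join(chunks))))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if line.count("[") != line.count("]"):
                    raise SequenceSyntaxError(
                        f"bracket token split across lines near line {lineno}"
                    )
                if header is None:
                    raise SequenceSyntaxError(
                        f"sequence data before first header at line {lineno}"
                    )
                chunks.append(line)
    flush()
    return records


def load_fixture_peptides() -> list[tuple[str, ParsedPeptide]]:
    """The 37 shipped validation peptides (GLP-1, 18A and PYY3-36 families)."""
    from importlib import resources

    with resources.as_file(
        resources.files("pepsol.data").joinpath("validation_peptides.fasta")
    ) as path:
        return read_fasta(path)
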