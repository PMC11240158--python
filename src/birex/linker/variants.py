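"""Sequence-variant normalization: dbSNP lookup contract and tmVar code generation.

Most sequence variants have no single knowledge-base identifier; the
pipe-delimited tmVar notation standardizes their description instead, e.g.
``Arg-114`` -> ``p|Allele|R|114`` and ``-3170G>A`` -> ``c|SUB|G|-3170|A``.
The leading letter names the sequence type — c (DNA/coding), r (RNA),
g (genome), p (protein), m (mitochondrial) — and is inferred from surface
cues (explicit ``c./g./p./r./m.`` prefix; protein-residue names imply p;
DNA bases default to c).  A substitution with no target allele is emitted
with kind ``Allele`` rather than ``SUB``.

Known variants resolve first through an injected offline dbSNP lookup
mapping ``(surface, gene code)`` to an rs identifier; generation is the
fallback.  Amino acids (three-letter or full names) and codons normalize to
single-letter residue codes through the standard genetic code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Protocol

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import IUPACData


class TranslationError(ValueError):
    pass


class TmvarGenerationError(ValueError):
    pass


_FULL_NAMES = {
    "alanine": "A", "arginine": "R", "asparagine": "N", "aspartate": "D",
    "asparticacid": "D", "cysteine": "C", "glutamine": "Q", "glutamate": "E",
    "glutamicacid": "E", "glycine": "G", "histidine": "H", "isoleucine": "I",
    "leucine": "L", "lysine": "K", "methionine": "M", "phenylalanine": "F",
    "proline": "P", "serine": "S", "threonine": "T", "tryptophan": "W",
    "tyrosine": "Y", "valine": "V",
}

_THREE_LETTER = {k.lower(): v for k, v in IUPACData.protein_letters_3to1.items()}
_CODON_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
_CODONS = {codon.lower(): aa for codon, aa in _CODON_TABLE.forward_table.items()}
_CODONS.update({codon.lower(): "*" for codon in _CODON_TABLE.stop_codons})


def aa_or_codon_to_letter(token: str) -> str:
    """Single-letter residue code for an amino-acid name or DNA codon.

    Accepts three-letter codes (``Arg``), full names (``Arginine``) and
    codons (``CGG``), case-insensitively; stop codons map to ``*``.
    """
    key = token.strip().lower().replace(" ", "")
    if key in _THREE_LETTER:
        return _THREE_LETTER[key]
    if key in _FULL_NAMES:
        return _FULL_NAMES[key]
    if key in _CODONS:
        return _CODONS[key]
    raise TranslationError(f"cannot translate {token!r} to a single-letter residue code")


class VariantLookup(Protocol):
    """Offline dbSNP-style lookup: (variant surface, gene code) -> rs id or None."""

    def __call__(self, surface: str, gene_code: str | None) -> str | None: ...


@dataclass
class DictVariantLookup:
    """Table-backed lookup used in tests and offline runs."""

    table: Mapping[tuple[str, str | None], str]

    def __call__(self, surface: str, gene_code: str | None) -> str | None:
        return self.table.get((surface.lower(), gene_code)) or self.table.get(
            (surface.lower(), None)
        )


def apply_allele_correction(code: str) -> str:
    """Rewrite a substitution lacking its target allele as an Allele code.

    ``c|SUB|C|1188|`` becomes ``c|Allele|C|1188``: the notation guidelines
    use ``Allele`` when only one allele is stated.
    """
    parts = code.split("|")
    if len(parts) == 5 and parts[1] == "SUB" and parts[4] == "":
        return "|".join([parts[0], "Allele", parts[2], parts[3]])
    return code


_PREFIX_RE = re.compile(r"^\s*([crgpm])\.\s*", re.IGNORECASE)
_DNA = set("ACGTacgt")
# amino-acid word: three-letter code or full name
_AA_WORD = r"(?:[A-Za-z]{3,})"
_POS = r"[+-]?\d+"

_SUB_ARROW = re.compile(rf"^({_POS})\s*([A-Za-z])\s*(?:>|->|/|to)\s*([A-Za-z])$")
_SUB_ARROW2 = re.compile(rf"^([A-Za-z])({_POS})\s*(?:>|->|/|to)\s*([A-Za-z])$")
_SUB_COMPACT = re.compile(rf"^([A-Za-z])\s*({_POS})\s*([A-Za-z])$")
_SUB_WORDS = re.compile(rf"^({_AA_WORD})\s*[- ]?\s*({_POS})\s*[- ]?\s*({_AA_WORD})$")
_ALLELE_WORD = re.compile(rf"^({_AA_WORD})\s*[- ]?\s*({_POS})$")
_ALLELE_LETTER = re.compile(rf"^([A-Za-z])\s*[- ]?\s*({_POS})$")
_ALLELE_POSFIRST = re.compile(rf"^({_POS})\s*[- ]?\s*({_AA_WORD})$")
_INDEL = re.compile(rf"^({_POS})?\s*(del|ins|dup)\s*([A-Za-z]*)$", re.IGNORECASE)
_RS = re.compile(r"^rs\d+$", re.IGNORECASE)


def _residue(token: str) -> tuple[str, bool]:
    """(single-letter code, is_protein_cue). Single letters pass through."""
    if len(token) == 1:
        up = token.upper()
        return up, up not in "ACGT"
    return aa_or_codon_to_letter(token), len(token) != 3 or token.lower() not in _CODONS


def generate_tmvar_code(surface: str) -> str:
    """Standardized pipe-delimited variant code from a free-text mention."""
    s = surface.strip()
    if _RS.match(s):
        return s.lower()
    seq = None
    m = _PREFIX_RE.match(s)
    if m:
        seq = m.group(1).lower()
        s = s[m.end():]
    s = s.strip()

    def finish(kind: str, fields: list[str], protein_cue: bool) -> str:
        st = seq or ("p" if protein_cue else "c")
        return apply_allele_correction("|".join([st, kind] + fields))

    m = _SUB_ARROW.match(s)
    if m:
        pos, ref, alt = m.groups()
        r, p1 = _residue(ref)
        a, p2 = _residue(alt)
        return finish("SUB", [r, pos, a], p1 or p2)
    m = _SUB_ARROW2.match(s)
    if m:
        ref, pos, alt = m.groups()
        r, p1 = _residue(ref)
        a, p2 = _residue(alt)
        return finish("SUB", [r, pos, a], p1 or p2)
    m = _SUB_WORDS.match(s)
    if m:
        ref, pos, alt = m.groups()
        try:
            r, _ = _residue(ref)
            a, _ = _residue(alt)
        except TranslationError:
            r = a = None
        if r is not None and a is not None:
            return finish("SUB", [r, pos, a], True)
    m = _ALLELE_WORD.match(s)
    if m:
        word, pos = m.groups()
        try:
            r = aa_or_codon_to_letter(word)
        except TranslationError:
            r = None
        if r is not None:
            return finish("Allele", [r, pos], True)
    m = _INDEL.match(s)
    if m:
        pos, kind, rest = m.groups()
        protein_cue = False
        res = rest.upper()
        if len(rest) >= 3:
            try:
                res = aa_or_codon_to_letter(rest)
                protein_cue = rest.lower() not in _CODONS
            except TranslationError:
                res = rest.upper()
        return finish(kind.upper(), [pos or "", res], protein_cue)
    m = _SUB_COMPACT.match(s)
    if m:
        ref, pos, alt = m.groups()
        r, p1 = _residue(ref)
        a, p2 = _residue(alt)
        return finish("SUB", [r, pos, a], p1 or p2)
    m = _ALLELE_LETTER.match(s)
    if m:
        ref, pos = m.groups()
        r, p = _residue(ref)
        return finish("Allele", [r, pos], p)
    m = _ALLELE_POSFIRST.match(s)
    if m:
        pos, word = m.groups()
        try:
            r = aa_or_codon_to_letter(word)
        except TranslationError as exc:
            raise TmvarGenerationError(f"cannot parse variant mention {surface!r}") from exc
        return finish("Allele", [r, pos], True)
    raise TmvarGenerationError(f"cannot parse variant mention {surface!r}")
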