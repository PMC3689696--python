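"""IUPAC nucleotide alphabet, ambiguity expansion, and RNA pairing rules.

T and U denote the same state throughout: input letters are preserved, but
every comparison and every pairing decision goes through :func:`canon`,
which maps U to T. The only non-canonical pair admitted is the G:U wobble.
"""

from __future__ import annotations

IUPAC_EXPAND: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"
ALPHABET = frozenset(IUPAC_EXPAND) | {GAP}
BASES = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# minimal IUPAC code for each non-empty base set
_CODE_FOR_SET = {v: k for k, v in IUPAC_EXPAND.items() if k != "U"}

# admitted RNA pairs (canonical + G:U wobble), on canonical (T==U) letters
WOBBLE_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")})
WATSON_CRICK = {"A": "T", "T": "A", "G": "C", "C": "G"}


def canon(ch: str) -> str:
    """Canonical one-letter state: upper-case, U folded onto T."""
    ch = ch.upper()
    return "T" if ch == "U" else ch


def expand(symbol: str) -> frozenset[str]:
    """Base set denoted by an IUPAC symbol (gap expands to the empty set)."""
    s = canon(symbol)
    if s == GAP:
        return frozenset()
    try:
        return IUPAC_EXPAND[s]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide symbol: {symbol!r}") from None


def is_ambiguous(symbol: str) -> bool:
    return len(expand(symbol)) > 1


def minimal_code(bases: set[str] | frozenset[str]) -> str:
    """Smallest IUPAC symbol covering exactly the given bases ({A,G} -> R)."""
    key = frozenset(canon(b) for b in bases)
    if not key <= BASES or not key:
        raise ValueError(f"not a set of unambiguous bases: {sorted(bases)}")
    return _CODE_FOR_SET[key]


def pairs_with(a: str, b: str) -> bool:
    """True if states a, b can base-pair (canonical or G:U wobble)."""
    return (canon(a), canon(b)) in WOBBLE_PAIRS


def complement(ch: str) -> str:
    return WATSON_CRICK[canon(ch)]


def is_transition(a: str, b: str) -> bool:
    x, y = canon(a), canon(b)
    return x != y and ({x, y} <= PURINES or {x, y} <= PYRIMIDINES)
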