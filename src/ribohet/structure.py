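"""Hairpin secondary structure and structural classification of substitutions.

Structures are nested (pseudoknot-free) pair tables over a folded window,
obtained either from the built-in base-pair-maximization folder
(:func:`fold_maxpair`, a Nussinov-style dynamic program with pair scores
GC=3, AU=2, GU=1 and a minimum hairpin loop) or imported from dot-bracket
strings produced by an external thermodynamic predictor. The analyses here
depend only on stem/loop topology, not on folding free energies.

Substitutions at stem sites are classified by the RNA pairing rule
{A:U, G:C, G:U}: a variable site whose every observed state still pairs
with its partner is wobble-neutral (the G:U wobble is what neutralizes
C<->U transitions opposite a stable G); a variable site paired with another
variable site where some joint state combination restores pairing is
compensatory; anything else is disruptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .alphabet import GAP, canon, pairs_with
from .variation import VariableSite

__all__ = [
    "PairTable",
    "SiteRole",
    "SiteContext",
    "StructuralEffect",
    "EffectClass",
    "CompensatoryAssignment",
    "fold_maxpair",
    "parse_dot_bracket",
    "write_dot_bracket",
    "map_site_context",
    "classify_structural_effect",
    "assign_compensatory_type",
    "pairing_integrity",
    "VR1_DIAGNOSTIC",
    "VR2_DIAGNOSTIC_5P",
    "VR2_DIAGNOSTIC_3P",
]

DEFAULT_PAIR_SCORES: dict[frozenset[str], float] = {
    frozenset("GC"): 3.0,
    frozenset("AT"): 2.0,
    frozenset("GT"): 1.0,
}


@dataclass(frozen=True)
class PairTable:
    """Nested structure as a 1-based partner array over a folded window.

    ``partner[i-1] == j`` (1-based j) if window positions i and j pair, else 0.
    ``offset`` maps window position 1 onto its amplicon position.
    """

    partner: tuple[int, ...]
    offset: int = 1

    def __post_init__(self) -> None:
        n = len(self.partner)
        for i, j in enumerate(self.partner, start=1):
            if j:
                if not 1 <= j <= n or j == i:
                    raise ValueError(f"partner out of range at {i}")
                if self.partner[j - 1] != i:
                    raise ValueError(f"non-reciprocal pair ({i},{j})")
        # nestedness
        stack: list[int] = []
        for i, j in enumerate(self.partner, start=1):
            if j > i:
                stack.append(j)
            elif j and j < i:
                if not stack or stack[-1] != i:
                    raise ValueError(f"crossing pair ending at {i}")
                stack.pop()

    def __len__(self) -> int:
        return len(self.partner)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """(i, j) window-coordinate pairs with i < j."""
        return tuple(
            (i, j) for i, j in enumerate(self.partner, start=1) if j > i
        )

    def amplicon_position(self, i: int) -> int:
        return self.offset + i - 1

    def window_index(self, position: int) -> int:
        i = position - self.offset + 1
        if not 1 <= i <= len(self.partner):
            raise IndexError(f"position {position} outside folded window")
        return i

    def partner_of_position(self, position: int) -> int | None:
        j = self.partner[self.window_index(position) - 1]
        return self.amplicon_position(j) if j else None


def fold_maxpair(
    seq: str,
    min_loop: int = 3,
    scores: Mapping[frozenset[str], float] | None = None,
    offset: int = 1,
) -> PairTable:
    """Best nested structure by weighted base-pair maximization.

    Dynamic programming over subsequences; hairpin loops keep at least
    ``min_loop`` unpaired positions. The traceback is deterministic: when an
    interval's optimum is attainable both by pairing its endpoints and by a
    split, pairing (i,j) wins; among equal-scoring splits the smallest split
    point wins.
    """
    s = [canon(c) for c in seq]
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"cannot fold characters {sorted(bad)}")
    sc = DEFAULT_PAIR_SCORES if scores is None else dict(scores)

    def pair_score(a: str, b: str) -> float:
        return sc.get(frozenset((a, b)), float("-inf")) if a != b else float("-inf")

    n = len(s)
    import numpy as np

    M = np.zeros((n + 1, n + 1))  # M[i][j], 1-based inclusive, j<i+... empty -> 0
    for span in range(2, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            best = M[i][j - 1]  # j unpaired
            if j - i - 1 >= min_loop:
                ps = pair_score(s[i - 1], s[j - 1])
                if ps > float("-inf"):
                    best = max(best, M[i + 1][j - 1] + ps)
            for k in range(i, j - 1):  # j paired inside: split before k+1? simple bifurcation
                cand = M[i][k] + M[k + 1][j]
                if cand > best:
                    best = cand
            M[i][j] = best

    partner = [0] * n

    def trace(i: int, j: int) -> None:
        # deterministic preference order: pair (i,j), then leave j unpaired,
        # then the smallest equal-scoring bifurcation
        while i < j:
            if j - i - 1 >= min_loop:
                ps = pair_score(s[i - 1], s[j - 1])
                if ps > float("-inf") and M[i][j] == M[i + 1][j - 1] + ps:
                    partner[i - 1], partner[j - 1] = j, i
                    i, j = i + 1, j - 1
                    continue
            if M[i][j] == M[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - 1):
                if M[i][j] == M[i][k] + M[k + 1][j]:
                    trace(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover - DP bookkeeping guarantees a branch
                raise AssertionError("traceback failed")

    if n:
        trace(1, n)
    return PairTable(partner=tuple(partner), offset=offset)


def parse_dot_bracket(s: str, offset: int = 1) -> PairTable:
    """Pair table from a dot-bracket string (characters . ( ) only)."""
    partner = [0] * len(s)
    stack: list[int] = []
    for i, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i - 1], partner[j - 1] = j, i
        elif ch != ".":
            raise ValueError(f"illegal character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return PairTable(partner=tuple(partner), offset=offset)


def write_dot_bracket(pt: PairTable) -> str:
    out = []
    for i, j in enumerate(pt.partner, start=1):
        out.append("." if not j else "(" if j > i else ")")
    return "".join(out)


class SiteRole(str, Enum):
    stem_forward = "stem_forward"  # 5' strand of a helix
    stem_backfold = "stem_backfold"  # 3' (back-folding) strand
    loop = "loop"
    unpaired_other = "unpaired_other"


@dataclass(frozen=True)
class SiteContext:
    position: int
    role: SiteRole
    partner_position: int | None
    partner_states: frozenset[str]


def _loop_positions(pt: PairTable) -> set[int]:
    """Window indices inside hairpin loops (unpaired, enclosed by a pair
    with no pair in between)."""
    loops: set[int] = set()
    for i, j in pt.pairs:
        inner = range(i + 1, j)
        if all(pt.partner[k - 1] == 0 for k in inner):
            loops.update(inner)
    return loops


def map_site_context(
    pt: PairTable,
    sites: Sequence[VariableSite],
    aln=None,
) -> list[SiteContext]:
    """Stem/loop context for each variable site inside the folded window.

    If an alignment is given, partner_states holds the states observed at
    the partner column; otherwise it is empty.
    """
    outside = [s.position for s in sites
               if not pt.offset <= s.position <= pt.offset + len(pt) - 1]
    if outside:
        raise ValueError(f"sites outside folded window: {outside}")
    loops = _loop_positions(pt)
    out: list[SiteContext] = []
    for s in sites:
        i = pt.window_index(s.position)
        j = pt.partner[i - 1]
        if j:
            role = SiteRole.stem_backfold if i > j else SiteRole.stem_forward
            ppos = pt.amplicon_position(j)
            if aln is not None:
                c = aln.column_of_position(ppos)
                pstates = frozenset(canon(ch) for ch in aln.column(c))
            else:
                pstates = frozenset()
            out.append(SiteContext(s.position, role, ppos, pstates))
        else:
            role = SiteRole.loop if i in loops else SiteRole.unpaired_other
            out.append(SiteContext(s.position, role, None, frozenset()))
    return out


class EffectClass(str, Enum):
    wobble_neutral = "wobble_neutral"
    compensatory = "compensatory"
    disruptive = "disruptive"
    loop_variant = "loop_variant"
    unpaired_variant = "unpaired_variant"
    indeterminate = "indeterminate"


@dataclass(frozen=True)
class StructuralEffect:
    position: int
    effect: EffectClass
    detail: str = ""


def classify_structural_effect(
    site: VariableSite,
    ctx: SiteContext,
    joint_states: Iterable[tuple[str, str]] | None = None,
) -> StructuralEffect:
    """Structural effect of the variation at one site.

    ``joint_states`` are per-clone (site, partner) character pairs; they are
    required to recognise compensatory co-variation when the partner site is
    itself variable. Gap states at stem sites yield ``indeterminate`` (a
    deleted stem position has no defined pairing to preserve or break).
    """
    if ctx.position != site.position:
        raise ValueError("context/site position mismatch")
    if ctx.role is SiteRole.loop:
        return StructuralEffect(site.position, EffectClass.loop_variant)
    if ctx.role is SiteRole.unpaired_other:
        return StructuralEffect(site.position, EffectClass.unpaired_variant)

    states = site.pooled_states
    if GAP in states or GAP in ctx.partner_states:
        return StructuralEffect(site.position, EffectClass.indeterminate,
                                "gap at a stem position")
    partner_variable = len(ctx.partner_states - {GAP}) >= 2
    if not partner_variable:
        (p,) = set(map(canon, ctx.partner_states)) or {"?"}
        if all(pairs_with(a, p) for a in states):
            return StructuralEffect(
                site.position, EffectClass.wobble_neutral,
                f"all of {''.join(sorted(states))} pair with invariant {p}",
            )
        return StructuralEffect(
            site.position, EffectClass.disruptive,
            f"some of {''.join(sorted(states))} cannot pair with {p}",
        )
    combos = set(joint_states or ())
    restored = [ab for ab in combos if pairs_with(*ab)]
    if restored:
        return StructuralEffect(
            site.position, EffectClass.compensatory,
            f"partner {ctx.partner_position} variable; pairing combinations "
            + ",".join(sorted(a + b for a, b in restored)),
        )
    return StructuralEffect(site.position, EffectClass.disruptive,
                            f"partner {ctx.partner_position} variable, no joint state pairs")


# --- compensatory typing at the diagnostic stem positions ----------------

# VR1 diagnostic pair and VR2 diagnostic triplet (5' strand read 389,390,391;
# its back-folding partner read 443,442,441 so that position k pairs with the
# k-th character of the other block).
VR1_DIAGNOSTIC = (103, 159)
VR2_DIAGNOSTIC_5P = (389, 390, 391)
VR2_DIAGNOSTIC_3P = (443, 442, 441)

VR1_TYPES: dict[tuple[str, str], str] = {
    ("A", "T"): "I",
    ("G", "T"): "II",
    ("A", "C"): "III",
    ("G", "C"): "IV",
}
# type V is the ambiguity-coded database-consensus row (R or N at 103, T at 159)
VR2_TYPES: dict[tuple[str, str], str] = {
    ("AAA", "TTT"): "I",
    ("AAA", "CTT"): "II",
    ("AAA", "TTC"): "III",
    ("AAA", "CTC"): "IV",
    ("GAG", "CTC"): "V",
    ("GAG", "CTT"): "VI",
}


@dataclass(frozen=True)
class CompensatoryAssignment:
    clone_id: str
    region: str  # "VR1" | "VR2"
    observed_states: tuple[str, ...]
    type_label: str


def assign_compensatory_type(
    clone_id: str,
    states: Sequence[str],
    region: str,
    is_consensus: bool = False,
) -> CompensatoryAssignment:
    """Look up the published compensatory-substitution type for one clone.

    VR1 types are keyed by the bases at (103, 159); VR2 types by the
    triplets at (389,390,391) and (443,442,441). Combinations absent from
    the catalog are labelled "novel". The VR1 ambiguity-consensus type V is
    matched only for consensus records, never clones.
    """
    st = tuple(canon(c) for c in states)
    if GAP in st:
        raise ValueError(f"{clone_id}: gap at a diagnostic position")
    if region == "VR1":
        if len(st) != 2:
            raise ValueError("VR1 typing needs states at positions 103 and 159")
        if is_consensus and st[0] in {"R", "N"} and st[1] == "T":
            label = "V"
        else:
            label = VR1_TYPES.get((st[0], st[1]), "novel")
    elif region == "VR2":
        if len(st) != 6:
            raise ValueError(
                "VR2 typing needs states at 389,390,391 and 443,442,441")
        label = VR2_TYPES.get(("".join(st[:3]), "".join(st[3:])), "novel")
    else:
        raise ValueError(f"unknown region {region!r}")
    return CompensatoryAssignment(clone_id, region, st, label)


def pairing_integrity(assignment: CompensatoryAssignment) -> int:
    """Number of diagnostic stem pairs kept intact (A:U, G:C or G:U)."""
    st = assignment.observed_states
    if assignment.region == "VR1":
        duos = [(st[0], st[1])]
    else:
        duos = list(zip(st[:3], st[3:]))
    return sum(1 for a, b in duos if pairs_with(a, b))
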