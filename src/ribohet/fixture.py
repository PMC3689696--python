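"""Published variable-site catalog for the *Metschnikowia* D1/D2 study set.

The type strains of *M. andauensis* (CBS 10809) and *M. fructicola*
(CBS 8853) carry non-homogenised rDNA arrays. From their cloned D1/D2
repeats (GenBank KC411953-KC411970) variability was tabulated at 35
positions (11 in the D1 domain, 24 in D2, numbered from the first base
behind primer NL1), together with the states of the database consensus
sequences (AJ745110, AJ745108, AF360542) and a catalog of compensatory
substitution types at the diagnostic stem pairs 103-159 (VR1) and
389/390/391-443/442/441 (VR2).

:func:`reconstruct_alignment` realises this catalog as a minimal synthetic
499-nt alignment: per-clone states are taken from the compensatory-type
catalog where given, remaining within-group alternatives are distributed by
a fixed round-robin rule, and all other columns are invariant background
engineered so that the two published hairpins base-pair as drawn (stems at
90-113/149-172 and 380-413/419-452). Group-level state sets — the
quantities the analyses consume — are exact; per-clone states away from the
diagnostic positions are a documented convention, not data.
"""

from __future__ import annotations

from itertools import cycle

from .alphabet import GAP, complement
from .seqio import Alignment, SequenceRecord
from .structure import PairTable

__all__ = [
    "REPEAT_LENGTH",
    "ANDAUENSIS",
    "FRUCTICOLA",
    "CLONES",
    "GROUPS",
    "CONSENSUS_IDS",
    "CONSENSUS_GROUPS",
    "SITE_CATALOG",
    "VR1_WINDOW",
    "VR2_WINDOW",
    "VR1_PINNED",
    "VR2_PINNED",
    "reconstruct_alignment",
    "pair_tables",
]

REPEAT_LENGTH = 499

ANDAUENSIS = "M. andauensis"
FRUCTICOLA = "M. fructicola"

CLONES: dict[str, tuple[str, ...]] = {
    ANDAUENSIS: ("a77", "a78", "aa20", "aa23", "aa23a", "ab24", "ab27"),
    FRUCTICOLA: (
        "fb1", "fb3", "fb6", "fb9", "fb10", "fb11",
        "fc15", "fc17", "fc21", "f39a1", "f39b2",
    ),
}
GROUPS: dict[str, str] = {
    c: g for g, cs in CLONES.items() for c in cs
}

ACCESSIONS: dict[str, str] = {
    "a77": "KC411953", "a78": "KC411954", "aa20": "KC411955", "aa23": "KC411956",
    "aa23a": "KC411957", "ab24": "KC411958", "ab27": "KC411959",
    "f39a1": "KC411960", "f39b2": "KC411961", "fb1": "KC411962", "fb3": "KC411963",
    "fb6": "KC411964", "fb9": "KC411965", "fb10": "KC411966", "fb11": "KC411967",
    "fc15": "KC411968", "fc17": "KC411969", "fc21": "KC411970",
}

CONSENSUS_IDS = ("AJ745110", "AJ745108", "AF360542")
CONSENSUS_GROUPS = {
    "AJ745110": ANDAUENSIS,  # CBS 10809 type-strain entry
    "AJ745108": ANDAUENSIS,  # strain HA 1622 entry
    "AF360542": FRUCTICOLA,  # CBS 8853 type-strain entry
}

# position -> (andauensis states, AJ745110, AJ745108, fructicola states, AF360542)
# state strings list the alternating nucleotides, majority first, '-' = deletion
SITE_CATALOG: dict[int, tuple[str, str, str, str, str]] = {
    # D1 domain
    103: ("AG", "R", "R", "AG", "N"),
    154: ("A", "A", "A", "AG", "G"),
    159: ("TC", "T", "T", "T", "T"),
    160: ("T", "T", "T", "TC", "T"),
    161: ("C", "C", "C", "TC", "T"),
    164: ("AC", "M", "M", "AC", "N"),
    168: ("TC", "T", "T", "TC", "T"),
    169: ("T", "T", "T", "TC", "T"),
    170: ("C", "C", "C", "TCA", "N"),
    172: ("T", "T", "T", "TC", "T"),
    280: ("AC", "A", "A", "AG", "A"),
    # D2 domain
    389: ("AG", "G", "R", "AG", "A"),
    391: ("AG", "G", "R", "AG", "A"),
    401: ("TC", "C", "C", "C", "C"),
    402: ("G", "G", "G", "AG", "G"),
    415: ("TC", "T", "T", "TC", "T"),
    428: ("A", "A", "A", "ACT", "N"),
    432: ("C", "C", "C", "TC", "C"),
    435: ("TC", "T", "T", "TC", "N"),
    436: ("TC", "C", "C", "C", "C"),
    437: ("TC", "T", "T", "TC", "N"),
    438: ("TC", "T", "Y", "TC", "T"),
    439: ("AT", "T", "T", "AT", "T"),
    440: ("A", "A", "A", "AT-", "A"),
    441: ("TC", "T", "T", "TC", "T"),
    443: ("TC", "C", "Y", "TC", "T"),
    446: ("AT", "T", "T", "AT", "A"),
    447: ("TC", "Y", "Y", "TC", "T"),
    448: ("AG", "G", "G", "AG", "G"),
    449: ("TC", "Y", "Y", "TC", "T"),
    450: ("TC", "Y", "Y", "TC", "T"),
    451: ("AG", "R", "R", "AG", "G"),
    452: ("TC", "Y", "Y", "C", "C"),
    466: ("AT", "A", "A", "AT", "T"),
    467: ("T", "T", "T", "T-", "T"),
}

# canonical variable-region report windows (VR1 holds 9 of the 35 sites,
# VR2 holds 16; site 103 sits apart on the 5' stem strand)
VR1_WINDOW = (154, 172)
VR2_WINDOW = (432, 452)

# compensatory-type catalog pins per-clone states at the diagnostic positions
VR1_PINNED: dict[str, tuple[str, str]] = {  # clone -> (103, 159)
    "a78": ("A", "T"), "aa23a": ("A", "T"), "ab27": ("A", "T"),
    "fc15": ("A", "T"), "fc17": ("A", "T"), "fb1": ("A", "T"), "fb9": ("A", "T"),
    "a77": ("G", "T"), "f39a1": ("G", "T"), "f39b2": ("G", "T"), "fb3": ("G", "T"),
    "fb6": ("G", "T"), "fb10": ("G", "T"), "fb11": ("G", "T"), "fc21": ("G", "T"),
    "aa23": ("A", "C"),
    "aa20": ("G", "C"), "ab24": ("G", "C"),
}
VR2_PINNED: dict[str, tuple[str, str, str, str]] = {  # clone -> (389, 391, 441, 443)
    **{c: ("A", "A", "T", "T") for c in
       ("a78", "aa20", "ab24", "fb1", "fb6", "fb10", "fc21", "fc17", "fc15",
        "f39a1", "f39b2")},
    **{c: ("A", "A", "C", "C") for c in ("a77", "ab27")},
    **{c: ("G", "G", "C", "C") for c in ("aa23a", "fb3", "fb11", "fb9")},
    "aa23": ("G", "G", "T", "C"),
}

# hairpin geometry: position i pairs position (PAIR_SUM - i) inside each stem
_D1_STEM = (90, 113, 262)  # 5' strand 90..113, i+j = 262, back strand 149..172
_D2_STEM = (380, 413, 832)  # 5' strand 380..413, back strand 419..452
_D1_LOOP = (114, 148)
_D2_LOOP = (414, 418)
_D1_WINDOW = (85, 180)
_D2_WINDOW = (375, 460)

# 5'-strand bases fixed so each back-strand variable site faces the partner
# the structural analysis expects (G opposite the T/C wobble sites, T
# opposite the A/G and A/T sites); back-strand bases opposite the variable
# forward sites 401/402 likewise
_PARTNER_CONSTRAINTS: dict[int, str] = {
    90: "G", 92: "G", 93: "G", 94: "G", 98: "G", 101: "G", 102: "G", 108: "T",
    380: "G", 381: "T", 382: "G", 383: "G", 384: "T", 385: "G", 386: "T",
    390: "A", 392: "T", 393: "T", 394: "G", 395: "G", 396: "G", 397: "G",
    400: "G", 404: "T", 430: "T", 431: "G",
}


def _stem_pairs() -> list[tuple[int, int]]:
    out = []
    for f0, f1, s in (_D1_STEM, _D2_STEM):
        out.extend((i, s - i) for i in range(f0, f1 + 1))
    return out


def background_sequence() -> str:
    """Invariant 499-nt background realizing the hairpin geometry."""
    bg: list[str | None] = [None] * REPEAT_LENGTH

    def put(pos: int, ch: str) -> None:
        bg[pos - 1] = ch

    for lo, hi in (_D1_LOOP, _D2_LOOP):
        for p in range(lo, hi + 1):
            put(p, "A")
    for pos, ch in _PARTNER_CONSTRAINTS.items():
        put(pos, ch)
    for pos, (and_states, *_rest) in SITE_CATALOG.items():
        put(pos, and_states[0])  # majority background; overwritten per record
    filler = cycle("TCAG")
    variable = set(SITE_CATALOG)
    for i, j in _stem_pairs():
        if bg[i - 1] is None:
            put(i, next(filler))
        if bg[j - 1] is None and j not in variable:
            put(j, complement(bg[i - 1]))
    for p in range(1, REPEAT_LENGTH + 1):
        if bg[p - 1] is None:
            put(p, next(filler))
    return "".join(bg)  # type: ignore[arg-type]


def _clone_states(group: str) -> dict[str, dict[int, str]]:
    """Per-clone states at every catalog position for one group.

    Diagnostic positions come from the compensatory catalog; at the
    remaining within-group variable positions the r-th such position (in
    ascending order) hands its j-th alternative state to clone
    (r + j - 1) mod n, everything else takes the majority state.
    """
    clones = CLONES[group]
    n = len(clones)
    col = 0 if group == ANDAUENSIS else 3
    pinned_pos = {103, 159, 389, 391, 441, 443}
    states: dict[str, dict[int, str]] = {c: {} for c in clones}
    for c in clones:
        p103, p159 = VR1_PINNED[c]
        p389, p391, p441, p443 = VR2_PINNED[c]
        states[c].update({103: p103, 159: p159, 389: p389, 391: p391,
                          441: p441, 443: p443})
    free = [p for p in sorted(SITE_CATALOG)
            if p not in pinned_pos and len(SITE_CATALOG[p][col]) >= 2]
    invariant = [p for p in sorted(SITE_CATALOG)
                 if p not in pinned_pos and len(SITE_CATALOG[p][col]) == 1]
    for c in clones:
        for p in invariant:
            states[c][p] = SITE_CATALOG[p][col]
    for r, p in enumerate(free):
        alts = SITE_CATALOG[p][col]
        for c in clones:
            states[c][p] = alts[0]
        for j in range(1, len(alts)):
            states[clones[(r + j - 1) % n]][p] = alts[j]
    return states


def reconstruct_alignment(include_consensus: bool = True) -> Alignment:
    """The synthetic study alignment: 18 clones (plus optionally the three
    database consensus rows), invariant everywhere except the 35 catalog
    positions."""
    bg = background_sequence()
    records: list[SequenceRecord] = []

    def realize(states: dict[int, str]) -> str:
        s = list(bg)
        for pos, ch in states.items():
            s[pos - 1] = ch
        return "".join(s)

    for group in (ANDAUENSIS, FRUCTICOLA):
        per_clone = _clone_states(group)
        for c in CLONES[group]:
            records.append(
                SequenceRecord(id=c, seq=realize(per_clone[c]), group=group)
            )
    if include_consensus:
        for rid, col in (("AJ745110", 1), ("AJ745108", 2), ("AF360542", 4)):
            states = {p: row[col] for p, row in SITE_CATALOG.items()}
            records.append(
                SequenceRecord(id=rid, seq=realize(states),
                               group=CONSENSUS_GROUPS[rid])
            )
    return Alignment(records=tuple(records), offset=1)


def pair_tables() -> list[PairTable]:
    """The two hairpin windows as pair tables in amplicon coordinates."""
    out = []
    for (w0, w1), (f0, f1, s) in ((_D1_WINDOW, _D1_STEM), (_D2_WINDOW, _D2_STEM)):
        n = w1 - w0 + 1
        partner = [0] * n
        for i in range(f0, f1 + 1):
            j = s - i
            partner[i - w0] = j - w0 + 1
            partner[j - w0] = i - w0 + 1
        out.append(PairTable(partner=tuple(partner), offset=w0))
    return out
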