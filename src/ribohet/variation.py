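"""Variable-site profiling of repeat alignments.

Given an alignment of cloned repeat units grouped by strain/species, this
module identifies the variable columns, classifies the alternating states
(transition / transversion / multistate, with indel involvement as an
orthogonal flag), clusters them into variable regions (VR1/VR2-style),
reconciles IUPAC-ambiguous database consensus sequences against the clone
pool, and computes pairwise difference statistics.

Counting convention for the substitution spectrum: percentages are per
variable *site*, not per inferred mutation event. A site enters the
transition/transversion denominator when its gap-stripped state set for the
group contains exactly two bases; sites with three or more bases are tallied
as multistate and excluded. This site-based rule is what reproduces the
published spectrum of the Metschnikowia D1/D2 clone sets (79%/82%
transitions, 74%/65% T-C among transitions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import GAP, canon, expand, is_ambiguous, is_transition
from .seqio import Alignment, SequenceRecord

__all__ = [
    "SiteClass",
    "SubstClass",
    "VariableSite",
    "VariableRegion",
    "AmbiguityCheck",
    "SpectrumSummary",
    "profile_variable_sites",
    "classify_substitution",
    "substitution_spectrum",
    "detect_variable_regions",
    "check_ambiguity_consistency",
    "position_frequency_matrix",
    "pairwise_differences",
]


class SiteClass(str, Enum):
    invariant = "invariant"
    dimorphic = "dimorphic"
    multistate = "multistate"
    indel_involved = "indel_involved"


class SubstClass(str, Enum):
    not_variable = "not_variable"
    transition = "transition"
    transversion = "transversion"
    multistate = "multistate"
    indel = "indel"


@dataclass(frozen=True)
class VariableSite:
    position: int
    states_by_group: Mapping[str, frozenset[str]]
    pooled_states: frozenset[str]
    site_class: SiteClass
    indel_involved: bool
    subst_class_by_group: Mapping[str, SubstClass]

    def group_states(self, group: str) -> frozenset[str]:
        return self.states_by_group.get(group, frozenset())


@dataclass(frozen=True)
class VariableRegion:
    label: str
    start: int
    end: int
    member_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if any(not self.start <= p <= self.end for p in self.member_positions):
            raise ValueError("member outside [start, end]")

    def __len__(self) -> int:
        return len(self.member_positions)


class Verdict(str, Enum):
    consistent = "consistent"
    inconsistent = "inconsistent"
    uninformative = "uninformative"


@dataclass(frozen=True)
class AmbiguityCheck:
    position: int
    symbol: str
    expansion: frozenset[str]
    observed: frozenset[str]
    verdict: Verdict
    note: str = ""


@dataclass(frozen=True)
class SpectrumSummary:
    group: str
    n_variable_sites: int
    n_dimorphic: int
    n_transition_sites: int
    n_transversion_sites: int
    n_multistate_sites: int
    n_indel_sites: int
    n_tc_transition_sites: int
    pct_transitions_exact: Fraction | None
    pct_tc_among_transitions_exact: Fraction | None

    @staticmethod
    def _round(x: Fraction | None) -> int | None:
        if x is None:
            return None
        # nearest integer, half away from zero
        return int(math.floor(x + Fraction(1, 2))) if x >= 0 else -int(math.floor(-x + Fraction(1, 2)))

    @property
    def pct_transitions(self) -> int | None:
        return self._round(self.pct_transitions_exact)

    @property
    def pct_tc_among_transitions(self) -> int | None:
        return self._round(self.pct_tc_among_transitions_exact)


def _column_states(chars: Iterable[str]) -> frozenset[str]:
    return frozenset(canon(c) for c in chars)


def classify_substitution(states: Iterable[str]) -> SubstClass:
    """Classify a site's alternating states; gaps are stripped first."""
    s = _column_states(states)
    if not s:
        raise ValueError("empty state set")
    bases = s - {GAP}
    if len(bases) <= 1:
        return SubstClass.indel if GAP in s and bases else SubstClass.not_variable
    if len(bases) >= 3:
        return SubstClass.multistate
    a, b = sorted(bases)
    return SubstClass.transition if is_transition(a, b) else SubstClass.transversion


def profile_variable_sites(
    aln: Alignment, grouping: Mapping[str, str]
) -> list[VariableSite]:
    """One VariableSite per non-invariant column, in positional order.

    ``grouping`` maps record id -> group label; only mapped records are
    profiled, so consensus/outgroup rows can sit in the same alignment
    without contributing states.
    """
    members = [r for r in aln.records if r.id in grouping]
    if not members:
        raise ValueError("no alignment record is mapped to a group")
    unmapped = [r.id for r in aln.records if r.id not in grouping]
    groups = sorted({grouping[r.id] for r in members})
    out: list[VariableSite] = []
    for c in range(1, aln.column_count + 1):
        by_group = {
            g: _column_states(r.seq[c - 1] for r in members if grouping[r.id] == g)
            for g in groups
        }
        if not any(len(st) >= 2 for st in by_group.values()):
            continue  # invariant, or a pure fixed between-group difference
        pooled = frozenset().union(*by_group.values())
        bases = pooled - {GAP}
        if len(bases) <= 1:
            site_class = SiteClass.indel_involved
        elif len(bases) == 2 and GAP not in pooled:
            site_class = SiteClass.dimorphic
        elif len(bases) >= 3:
            site_class = SiteClass.multistate
        else:
            site_class = SiteClass.dimorphic  # two bases + gap; flag carries the indel
        subst = {g: classify_substitution(st) if st else SubstClass.not_variable for g, st in by_group.items()}
        out.append(
            VariableSite(
                position=aln.column_position(c),
                states_by_group=by_group,
                pooled_states=pooled,
                site_class=site_class,
                indel_involved=GAP in pooled,
                subst_class_by_group=subst,
            )
        )
    return out


def substitution_spectrum(sites: Sequence[VariableSite], group: str) -> SpectrumSummary:
    """Per-site substitution spectrum for one group.

    Exact rationals are retained; rounded integers are derived properties.
    With zero transition+transversion sites the percentages are None
    (undefined), never 0.
    """
    n_var = n_ts = n_tv = n_multi = n_indel = n_tc = n_dimorphic = 0
    for s in sites:
        st = s.group_states(group)
        bases = st - {GAP}
        if len(st) <= 1 or (len(bases) <= 1 and GAP not in st):
            continue
        n_var += 1
        if GAP in st:
            n_indel += 1
        if len(bases) == 2 and GAP not in st:
            n_dimorphic += 1
        cls = classify_substitution(st)
        if cls is SubstClass.transition:
            n_ts += 1
            if bases == frozenset("CT"):
                n_tc += 1
        elif cls is SubstClass.transversion:
            n_tv += 1
        elif cls is SubstClass.multistate:
            n_multi += 1
    denom = n_ts + n_tv
    return SpectrumSummary(
        group=group,
        n_variable_sites=n_var,
        n_dimorphic=n_dimorphic,
        n_transition_sites=n_ts,
        n_transversion_sites=n_tv,
        n_multistate_sites=n_multi,
        n_indel_sites=n_indel,
        n_tc_transition_sites=n_tc,
        pct_transitions_exact=Fraction(100 * n_ts, denom) if denom else None,
        pct_tc_among_transitions_exact=Fraction(100 * n_tc, n_ts) if n_ts else None,
    )


def detect_variable_regions(
    sites: Sequence[VariableSite], max_gap: int = 5, min_sites: int = 3
) -> list[VariableRegion]:
    """Cluster variable positions into maximal runs with inter-site gaps <= max_gap."""
    positions = sorted(s.position for s in sites)
    regions: list[VariableRegion] = []
    run: list[int] = []
    for p in positions:
        if run and p - run[-1] > max_gap:
            if len(run) >= min_sites:
                regions.append(_region(len(regions) + 1, run))
            run = []
        run.append(p)
    if len(run) >= min_sites:
        regions.append(_region(len(regions) + 1, run))
    return regions


def _region(index: int, run: list[int]) -> VariableRegion:
    return VariableRegion(
        label=f"VR{index}", start=run[0], end=run[-1], member_positions=tuple(run)
    )


def check_ambiguity_consistency(
    consensus: SequenceRecord,
    sites: Sequence[VariableSite],
    aln: Alignment,
    grouping: Mapping[str, str],
    group: str | None = None,
) -> list[AmbiguityCheck]:
    """Reconcile a database consensus against the clone pool.

    Every ambiguous symbol in the consensus is checked against the states
    observed in the clones at that position (``consistent`` iff the observed
    bases are covered by the symbol's expansion and at least two alternated).
    Unambiguous consensus characters sitting at clone-variable positions are
    reported as ``uninformative`` with the majority relation noted.
    """
    if len(consensus.seq) != aln.column_count:
        raise ValueError(
            f"consensus {consensus.id!r} length {len(consensus.seq)} != "
            f"alignment width {aln.column_count}"
        )
    site_by_pos = {s.position: s for s in sites}
    members = [
        r for r in aln.records
        if r.id in grouping and (group is None or grouping[r.id] == group)
    ]
    out: list[AmbiguityCheck] = []
    for c in range(1, aln.column_count + 1):
        sym = canon(consensus.seq[c - 1])
        pos = aln.column_position(c)
        observed = frozenset(
            canon(r.seq[c - 1]) for r in members if r.seq[c - 1] != GAP
        )
        if sym != GAP and is_ambiguous(sym):
            exp = expand(sym)
            if len(observed) < 2:
                verdict, note = Verdict.uninformative, "clones not variable here"
            elif observed <= exp:
                verdict, note = Verdict.consistent, ""
            else:
                verdict, note = (
                    Verdict.inconsistent,
                    f"clone states {''.join(sorted(observed))} not covered",
                )
            out.append(AmbiguityCheck(pos, sym, exp, observed, verdict, note))
        elif pos in site_by_pos and len(observed) >= 2:
            rel = "matches a clone state" if sym in observed else "absent from clones"
            out.append(
                AmbiguityCheck(
                    pos, sym, expand(sym) if sym != GAP else frozenset(), observed,
                    Verdict.uninformative, f"unambiguous consensus at variable site; {rel}",
                )
            )
    return out


def position_frequency_matrix(
    aln: Alignment, region: VariableRegion, grouping: Mapping[str, str] | None = None,
    group: str | None = None,
) -> dict[int, dict[str, int]]:
    """Per-column character counts over a region (a frequency-logo matrix)."""
    members = [
        r for r in aln.records
        if grouping is None or (r.id in grouping and (group is None or grouping[r.id] == group))
    ]
    out: dict[int, dict[str, int]] = {}
    for pos in range(region.start, region.end + 1):
        c = aln.column_of_position(pos)
        counts: dict[str, int] = {}
        for r in members:
            ch = canon(r.seq[c - 1])
            counts[ch] = counts.get(ch, 0) + 1
        out[pos] = counts
    return out


@dataclass(frozen=True)
class PairwiseDifferences:
    labels: tuple[str, ...]
    substitutions: np.ndarray  # differing base-vs-base columns
    indels: np.ndarray  # gap-vs-base columns
    identical_pairs: tuple[tuple[str, str], ...]
    max_substitutions: int
    max_pct_of_length: float


def pairwise_differences(
    aln: Alignment, ids: Sequence[str] | None = None
) -> PairwiseDifferences:
    """Pairwise substitution and indel difference counts.

    Substitutions count columns where both records carry (different) bases;
    gap-versus-base columns are tallied separately as indel differences.
    Identical pairs have zero of both.
    """
    recs = [aln[i] for i in ids] if ids is not None else list(aln.records)
    n = len(recs)
    mat = np.array([[canon(c) for c in r.seq] for r in recs])
    gap = mat == GAP
    subs = np.zeros((n, n), dtype=int)
    ind = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        both = ~gap[i] & ~gap[j]
        s = int(np.sum(both & (mat[i] != mat[j])))
        d = int(np.sum(gap[i] ^ gap[j]))
        subs[i, j] = subs[j, i] = s
        ind[i, j] = ind[j, i] = d
    identical = tuple(
        (recs[i].id, recs[j].id)
        for i, j in combinations(range(n), 2)
        if subs[i, j] == 0 and ind[i, j] == 0
    )
    max_sub = int(subs.max()) if n > 1 else 0
    return PairwiseDifferences(
        labels=tuple(r.id for r in recs),
        substitutions=subs,
        indels=ind,
        identical_pairs=identical,
        max_substitutions=max_sub,
        max_pct_of_length=100.0 * max_sub / aln.column_count,
    )
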