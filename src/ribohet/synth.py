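"""Simulator for the evolution of a tandem rDNA repeat array.

The model is a Moran-style duplication process on a fixed-size array of
repeat units: each generation one repeat is overwritten by a copy of
another (the homogenising move of concerted evolution), the new copy
acquires substitutions, and optional reticulate events (suffix-swapping
recombination, gene-conversion tracts) exchange sequence between repeats.
Mutation is hairpin-aware: transitions are favoured globally (``ts_bias``),
C<->T changes are further favoured at stem positions whose partner is a G
(where the G:U wobble keeps the RNA helix intact), and a pairing-breaking
substitution at a stem site can be accompanied by the restoring change at
its partner (``comp_comutation_p``), emulating compensatory evolution.

Every event is logged; replaying the log from the master sequence
reproduces the array byte-for-byte, which is the simulator's core
correctness invariant and the hook for ground-truth evaluation of the
analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .alphabet import GAP, minimal_code
from .seqio import Alignment, SequenceRecord
from .structure import PairTable

__all__ = [
    "Stem",
    "ArraySimConfig",
    "SimEvent",
    "SimulatedArray",
    "make_master",
    "evolve_array",
    "replay_events",
    "sample_clones",
    "emit_consensus_with_ambiguity",
    "truth_evaluation",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE[GAP] = 4
_CHAR = np.array(list(_BASES + GAP))
_COMPLEMENT = {0: 3, 3: 0, 1: 2, 2: 1}  # A<->T, C<->G codes
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T codes


def _pairs_code(a: int, b: int) -> bool:
    return (a, b) in {(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)}


@dataclass(frozen=True)
class Stem:
    """One hairpin helix: 5' strand [f_start..f_end] pairs the back-folding
    3' strand [b_start..b_end] so that f_start+k pairs b_end-k (1-based)."""

    f_start: int
    f_end: int
    b_start: int
    b_end: int

    def __post_init__(self) -> None:
        if not (self.f_start <= self.f_end < self.b_start <= self.b_end):
            raise ValueError("stem strands must be ordered and disjoint")
        if self.f_end - self.f_start != self.b_end - self.b_start:
            raise ValueError("stem strands must have equal length")

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        k = self.f_end - self.f_start + 1
        return tuple((self.f_start + i, self.b_end - i) for i in range(k))


DEFAULT_STEMS = (
    # VR1-style short hairpin with the (103,159)-type diagnostic pair offsets
    Stem(90, 113, 149, 172),
    # VR2-style longer hairpin holding a 3-bp diagnostic block (389..391/441..443)
    Stem(380, 413, 419, 452),
)


@dataclass(frozen=True)
class ArraySimConfig:
    repeat_length: int = 499
    n_repeats: int = 20
    hairpin_spec: tuple[Stem, ...] = DEFAULT_STEMS
    mu: float = 1e-3  # per-site substitution probability per duplication
    ts_bias: float = 0.8  # probability a substitution is a transition
    tc_opposite_g_bias: float = 5.0  # rate multiplier for pyrimidines opposite G
    comp_comutation_p: float = 0.5  # restoring partner change after a break
    rec_rate: float = 0.0  # expected crossovers per generation
    conv_rate: float = 0.0  # expected conversion tracts per generation
    conv_tract_mean: float = 50.0  # nt, geometric tract length
    homogenization_p: float = 0.0  # new variant overwritten by majority allele
    master_wobble_fraction: float = 0.1  # G:T pairs seeded into the master stems
    n_generations: int = 400
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("mu", "ts_bias", "comp_comutation_p", "homogenization_p",
                     "master_wobble_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        for s in self.hairpin_spec:
            if s.b_end > self.repeat_length:
                raise ValueError("stem outside repeat")
        spans = sorted((s.f_start, s.b_end) for s in self.hairpin_spec)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("overlapping stems")
        if self.seed is None:
            raise ValueError("simulation needs an explicit seed")


@dataclass(frozen=True)
class SimEvent:
    kind: Literal["duplication", "substitution", "recombination", "conversion",
                  "homogenization"]
    generation: int
    params: tuple  # kind-specific payload, see _apply_event


@dataclass(frozen=True)
class SimulatedArray:
    config: ArraySimConfig
    master: str
    pair_table: PairTable
    repeats: tuple[str, ...]
    events: tuple[SimEvent, ...]
    truth: Mapping[int, str]  # site -> {"wobble", "compensatory-pair", "disruptive", "unpaired"}


def _partner_array(config: ArraySimConfig) -> np.ndarray:
    """partner[i-1] = 1-based partner position, 0 if unpaired."""
    partner = np.zeros(config.repeat_length, dtype=int)
    for s in config.hairpin_spec:
        for i, j in s.pairs:
            partner[i - 1], partner[j - 1] = j, i
    return partner


def make_master(config: ArraySimConfig, rng: np.random.Generator | None = None
                ) -> tuple[str, PairTable]:
    """Random master repeat whose stem blocks base-pair per hairpin_spec.

    Stem strands are reverse-complementary under A:T/G:C except for a
    seeded fraction of G:T wobble pairs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    seq = rng.integers(0, 4, size=config.repeat_length)
    partner = _partner_array(config)
    for s in config.hairpin_spec:
        for i, j in s.pairs:
            if rng.random() < config.master_wobble_fraction:
                seq[i - 1], seq[j - 1] = _CODE["G"], _CODE["T"]
            else:
                seq[j - 1] = _COMPLEMENT[int(seq[i - 1])]
    return "".join(_CHAR[seq]), PairTable(partner=tuple(int(x) for x in partner))


def _apply_event(repeats: list[np.ndarray], ev: SimEvent) -> None:
    if ev.kind == "duplication":
        donor, acceptor = ev.params
        repeats[acceptor] = repeats[donor].copy()
    elif ev.kind == "substitution":
        repeat, site, _old, new = ev.params
        repeats[repeat][site - 1] = _CODE[new]
    elif ev.kind == "recombination":
        r1, r2, breakpoint = ev.params
        tail1 = repeats[r1][breakpoint:].copy()
        repeats[r1][breakpoint:] = repeats[r2][breakpoint:]
        repeats[r2][breakpoint:] = tail1
    elif ev.kind == "conversion":
        donor, acceptor, start, length = ev.params
        repeats[acceptor][start : start + length] = repeats[donor][start : start + length]
    elif ev.kind == "homogenization":
        repeat, site, majority = ev.params
        repeats[repeat][site - 1] = _CODE[majority]
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {ev.kind}")


def replay_events(master: str, n_repeats: int, events: Sequence[SimEvent]) -> tuple[str, ...]:
    """Reconstruct the array by replaying the event log from the master."""
    arr = np.array([_CODE[c] for c in master])
    repeats = [arr.copy() for _ in range(n_repeats)]
    for ev in events:
        _apply_event(repeats, ev)
    return tuple("".join(_CHAR[r]) for r in repeats)


def _choose_substitution(rng: np.random.Generator, cur: int, ts_bias: float) -> int:
    if rng.random() < ts_bias:
        return _TRANSITION[cur]
    tvs = [b for b in range(4) if b != cur and b != _TRANSITION[cur]]
    return tvs[int(rng.integers(0, 2))]


def evolve_array(config: ArraySimConfig) -> SimulatedArray:
    """Run the simulation; one global seeded RNG stream, draws consumed in a
    fixed order (master, then per generation: duplication, substitutions,
    compensation, homogenization, recombination, conversion)."""
    rng = np.random.default_rng(config.seed)
    master, pt = make_master(config, rng)
    partner = np.array(pt.partner)
    master_codes = np.array([_CODE[c] for c in master])
    # sites whose structural partner is a G in the master: wobble-prone
    partner_is_g = np.zeros(config.repeat_length, dtype=bool)
    paired = partner > 0
    partner_is_g[paired] = master_codes[partner[paired] - 1] == _CODE["G"]

    repeats = [master_codes.copy() for _ in range(config.n_repeats)]
    events: list[SimEvent] = []
    truth: dict[int, str] = {}

    def log(kind: str, gen: int, params: tuple) -> None:
        ev = SimEvent(kind=kind, generation=gen, params=params)
        events.append(ev)
        _apply_event(repeats, ev)

    L = config.repeat_length
    for gen in range(1, config.n_generations + 1):
        donor = int(rng.integers(0, config.n_repeats))
        acceptor = int(rng.integers(0, config.n_repeats))
        log("duplication", gen, (donor, acceptor))

        new = repeats[acceptor]
        rate = np.full(L, config.mu)
        pyr = (new == _CODE["C"]) | (new == _CODE["T"])
        rate[partner_is_g & pyr] *= config.tc_opposite_g_bias
        np.clip(rate, 0.0, 1.0, out=rate)
        rate[new == _CODE[GAP]] = 0.0
        hits = np.nonzero(rng.random(L) < rate)[0]
        new_subs: list[int] = []
        for idx in hits:
            site = int(idx) + 1
            cur = int(new[idx])
            nxt = _choose_substitution(rng, cur, config.ts_bias)
            log("substitution", gen, (acceptor, site, _BASES[cur], _BASES[nxt]))
            new_subs.append(site)
            p = int(partner[idx])
            if p == 0:
                truth.setdefault(site, "unpaired")
                continue
            pbase = int(new[p - 1])
            if _pairs_code(nxt, pbase):
                truth.setdefault(site, "wobble")
            elif rng.random() < config.comp_comutation_p and pbase != _CODE[GAP]:
                restore = _COMPLEMENT[nxt]
                log("substitution", gen, (acceptor, p, _BASES[pbase], _BASES[restore]))
                new_subs.append(p)
                truth[site] = "compensatory-pair"
                truth[p] = "compensatory-pair"
            else:
                truth.setdefault(site, "disruptive")

        if config.homogenization_p > 0:
            for site in new_subs:
                if rng.random() < config.homogenization_p:
                    col = np.array([r[site - 1] for r in repeats])
                    col = col[col != _CODE[GAP]]
                    majority = int(np.bincount(col).argmax())
                    log("homogenization", gen, (acceptor, site, _BASES[majority]))

        for _ in range(rng.poisson(config.rec_rate)):
            r1, r2 = rng.choice(config.n_repeats, size=2, replace=False)
            bp = int(rng.integers(1, L))
            log("recombination", gen, (int(r1), int(r2), bp))

        for _ in range(rng.poisson(config.conv_rate)):
            d, a = rng.choice(config.n_repeats, size=2, replace=False)
            start = int(rng.integers(0, L))
            length = int(min(rng.geometric(1.0 / config.conv_tract_mean), L - start))
            log("conversion", gen, (int(d), int(a), start, length))

    return SimulatedArray(
        config=config,
        master=master,
        pair_table=pt,
        repeats=tuple("".join(_CHAR[r]) for r in repeats),
        events=tuple(events),
        truth=truth,
    )


def sample_clones(
    array: SimulatedArray, n: int, seed: int, prefix: str = "clone", group: str | None = None
) -> list[SequenceRecord]:
    """Draw n repeats uniformly with replacement (random cloning from the
    PCR-amplified pool)."""
    if n < 1:
        raise ValueError("need n >= 1")
    if not array.repeats:
        raise ValueError("empty array")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(array.repeats), size=n)
    return [
        SequenceRecord(id=f"{prefix}{i+1:02d}", seq=array.repeats[p], group=group)
        for i, p in enumerate(picks)
    ]


def emit_consensus_with_ambiguity(
    repeats: Sequence[str], rec_id: str = "consensus"
) -> tuple[SequenceRecord, tuple[int, ...]]:
    """Column-wise minimal IUPAC consensus over the repeat pool.

    Columns containing a gap emit a gap and are returned as flagged
    positions (second element).
    """
    if not repeats:
        raise ValueError("no repeats")
    L = {len(r) for r in repeats}
    if len(L) != 1:
        raise ValueError("repeats must have equal length")
    out = []
    flagged = []
    for c in range(next(iter(L))):
        col = {r[c] for r in repeats}
        if GAP in col:
            out.append(GAP)
            flagged.append(c + 1)
        else:
            out.append(minimal_code(col))
    return SequenceRecord(id=rec_id, seq="".join(out)), tuple(flagged)


def truth_evaluation(
    array: SimulatedArray,
    detected_positions: Sequence[int],
    clone_records: Sequence[SequenceRecord],
    phi_significant: bool | None = None,
) -> dict:
    """Compare analysis output against the simulator's ground truth.

    Sensitivity/specificity are with respect to the positions at which the
    sampled clone pool truly differs; the Phi verdict is scored against
    whether the generating process included recombination.
    """
    L = len(array.master)
    cols = list(zip(*(r.seq for r in clone_records)))
    true_poly = {i + 1 for i, col in enumerate(cols) if len(set(col)) > 1}
    det = set(detected_positions)
    tp = len(det & true_poly)
    fp = len(det - true_poly)
    fn = len(true_poly - det)
    tn = L - tp - fp - fn
    out = {
        "n_true_polymorphic": len(true_poly),
        "n_detected": len(det),
        "sensitivity": tp / len(true_poly) if true_poly else 1.0,
        "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
        "truth_classes": dict(array.truth),
    }
    if phi_significant is not None:
        recombined = array.config.rec_rate > 0 or array.config.conv_rate > 0
        out["phi_significant"] = phi_significant
        out["recombination_simulated"] = recombined
        out["phi_verdict_correct"] = phi_significant == recombined
    return out
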