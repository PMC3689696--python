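"""Pairwise homoplasy (Phi) recombination test.

Under clonal (tree-like) evolution without homoplasy any two
parsimony-informative sites are *compatible*: both can be explained on one
tree without recurrent mutation. Recombination decouples the genealogies of
distant sites, so incompatibility grows with physical distance while nearby
sites stay compatible. The Phi statistic is the mean incompatibility over
unordered pairs of informative sites whose positions lie within a window
``w``; its null distribution is obtained by permuting the site positions
(which destroys the distance structure but preserves the site patterns),
and recombination is evidenced by an observed Phi *smaller* than the
permutation null:

    p = (1 + #{Phi_perm <= Phi_obs}) / (1 + n_permutations)

Compatibility of two sites is decided by the partition-intersection graph:
states of the two columns form the vertices, observed joint states the
edges, and the pair is compatible iff that graph is acyclic. For two
biallelic sites this is exactly the four-gamete test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .alphabet import GAP, canon
from .seqio import Alignment

__all__ = [
    "InformativeSite",
    "informative_sites",
    "pair_compatibility",
    "incompatibility_matrix",
    "phi_statistic",
    "PhiResult",
    "phi_permutation_test",
]


@dataclass(frozen=True)
class InformativeSite:
    position: int
    column: tuple[str, ...]  # per-record states, None-like gaps kept as '-'


def informative_sites(aln: Alignment, ids: Sequence[str] | None = None) -> list[InformativeSite]:
    """Parsimony-informative columns: >=2 states each carried by >=2 records.

    Gaps are treated as missing data and do not count as a state.
    """
    recs = [aln[i] for i in ids] if ids is not None else list(aln.records)
    out = []
    for c in range(1, aln.column_count + 1):
        col = tuple(canon(r.seq[c - 1]) for r in recs)
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP and ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            out.append(InformativeSite(position=aln.column_position(c), column=col))
    return out


def pair_compatibility(col_a: Sequence[str], col_b: Sequence[str]) -> bool:
    """True iff the two columns can evolve without homoplasy on one tree.

    Missing entries (gaps/ambiguity) are pairwise-deleted. Acyclicity of the
    bipartite state-intersection graph is checked with union-find. Pairs
    sharing fewer than two records are treated as compatible (flagged via a
    warning).
    """
    joint = {
        (a, b)
        for a, b in zip(col_a, col_b)
        if a in "ACGT" and b in "ACGT"
    }
    if len({a for a, _ in joint}) < 1 or len(joint) < 2:
        if sum(1 for a, b in zip(col_a, col_b) if a in "ACGT" and b in "ACGT") < 2:
            warnings.warn("fewer than 2 shared records; treating pair as compatible")
        return True
    nodes = {("a", a) for a, _ in joint} | {("b", b) for _, b in joint}
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in joint:
        ra, rb = find(("a", a)), find(("b", b))
        if ra == rb:
            return False  # edge closes a cycle
        parent[ra] = rb
    return True


def incompatibility_matrix(sites: Sequence[InformativeSite]) -> np.ndarray:
    """Symmetric 0/1 matrix; entry 1 marks an incompatible site pair."""
    n = len(sites)
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        if not pair_compatibility(sites[i].column, sites[j].column):
            m[i, j] = m[j, i] = 1.0
    return m


def _window_mask(positions: np.ndarray, w: int) -> np.ndarray:
    diff = np.abs(positions[:, None] - positions[None, :])
    mask = (diff <= w) & ~np.eye(len(positions), dtype=bool)
    return np.triu(mask)


def phi_statistic(
    aln: Alignment, w: int = 100, ids: Sequence[str] | None = None
) -> float:
    sites = informative_sites(aln, ids)
    return _phi_from_parts(
        incompatibility_matrix(sites),
        np.array([s.position for s in sites]),
        w,
    )


def _phi_from_parts(incompat: np.ndarray, positions: np.ndarray, w: int) -> float:
    mask = _window_mask(positions, w)
    npairs = int(mask.sum())
    if npairs == 0:
        raise ValueError("no informative-site pairs within the window")
    return float(incompat[mask].sum() / npairs)


@dataclass(frozen=True)
class PhiResult:
    statistic: float
    w: int
    n_informative: int
    n_permutations: int
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value out of (0, 1]")


def phi_permutation_test(
    aln: Alignment,
    w: int = 100,
    n_permutations: int = 1000,
    seed: int | None = None,
    ids: Sequence[str] | None = None,
) -> PhiResult:
    """Permutation Phi test (add-one p-value, so p is never exactly 0)."""
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    if seed is None:
        raise ValueError("the permutation test needs an explicit seed")
    sites = informative_sites(aln, ids)
    incompat = incompatibility_matrix(sites)
    positions = np.array([s.position for s in sites])
    obs = _phi_from_parts(incompat, positions, w)
    mask = _window_mask(positions, w)
    npairs = mask.sum()
    rng = np.random.default_rng(seed)
    k = len(sites)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        phi_p = incompat[np.ix_(perm, perm)][mask].sum() / npairs
        if phi_p <= obs + 1e-12:
            hits += 1
    return PhiResult(
        statistic=obs,
        w=w,
        n_informative=k,
        n_permutations=n_permutations,
        p_value=(1 + hits) / (1 + n_permutations),
        seed=seed,
    )
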