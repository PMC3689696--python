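"""Distance-based phylogenetics: p/F84/K3ST distances, NJ, bootstrap.

Distances
---------
``p``
    Proportion of differing sites.
``F84``
    Felsenstein's 1984 model with empirical base frequencies, in the
    closed form using the observed transition (P) and transversion (Q)
    proportions: with pi_R = pi_A + pi_G, pi_Y = pi_C + pi_T,
    A = pi_C pi_T / pi_Y + pi_A pi_G / pi_R, B = pi_C pi_T + pi_A pi_G,
    C = pi_R pi_Y,

        d = -2A ln(1 - P/(2A) - (A-B)Q/(2AC)) + 2(A - B - C) ln(1 - Q/(2C))

    which reduces to Kimura's two-parameter distance at equal frequencies.
``K3ST``
    Kimura's three-substitution-types distance with change classes
    P (transitions), Q (A<->T and G<->C) and R (A<->C and G<->T):

        d = -1/4 [ln(1-2P-2Q) + ln(1-2P-2R) + ln(1-2Q-2R)]

Sites with a gap or ambiguity code in either member of a pair are excluded
for that pair (pairwise deletion). A non-positive logarithm argument means
the pair is saturated for the model and raises :class:`SaturationError`
rather than returning infinity.

Neighbor joining follows the Saitou-Nei agglomeration with the standard
Q-criterion; ties are broken by the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf), so the result
is independent of input order. Negative branch-length estimates are clamped
to zero and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import BASES, GAP, canon, is_transition
from .seqio import Alignment

__all__ = [
    "DistanceMatrix",
    "SaturationError",
    "distance_matrix",
    "Node",
    "neighbor_joining",
    "bootstrap_support",
    "outgroup_root",
    "unroot",
    "bipartitions",
    "write_newick",
]


class SaturationError(ValueError):
    """Distance undefined: substitution saturation for the chosen model."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def _codes(aln: Alignment, ids: Sequence[str] | None) -> tuple[tuple[str, ...], np.ndarray]:
    recs = [aln[i] for i in ids] if ids is not None else list(aln.records)
    lut = np.full(128, -1, dtype=np.int8)
    for k, b in enumerate("ACGT"):
        lut[ord(b)] = k
    lut[ord("U")] = lut[ord("T")]
    mat = np.array([lut[np.frombuffer(r.seq.encode(), dtype=np.uint8)] for r in recs])
    return tuple(r.id for r in recs), mat  # -1 = gap/ambiguous = missing


def _log(x: float, pair: tuple[str, str], model: str) -> float:
    if x <= 0:
        raise SaturationError(f"{model} distance saturated for pair {pair}")
    return math.log(x)


_TS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T on ACGT codes
_Q_CLASS = {(0, 3), (3, 0), (2, 1), (1, 2)}  # A<->T, G<->C
_R_CLASS = {(0, 1), (1, 0), (2, 3), (3, 2)}  # A<->C, G<->T


def distance_matrix(
    aln: Alignment,
    model: str = "f84",
    ids: Sequence[str] | None = None,
    pairwise_deletion: bool = True,
) -> DistanceMatrix:
    model = model.lower()
    if model not in {"p", "f84", "k3st"}:
        raise ValueError(f"unknown model {model!r}")
    labels, mat = _codes(aln, ids)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 records")
    present = mat >= 0
    if not pairwise_deletion:
        keep = present.all(axis=0)
        mat = mat[:, keep]
        present = present[:, keep]

    if model == "f84":
        counts = np.bincount(mat[mat >= 0], minlength=4).astype(float)
        pi = counts / counts.sum()
        piA, piC, piG, piT = pi
        piR, piY = piA + piG, piC + piT
        A = piC * piT / piY + piA * piG / piR
        B = piC * piT + piA * piG
        C = piR * piY

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            L = int(both.sum())
            if L == 0:
                raise SaturationError(f"no shared sites for pair {(labels[i], labels[j])}")
            a, b = mat[i][both], mat[j][both]
            diff = a != b
            pair = (labels[i], labels[j])
            if model == "p":
                val = diff.sum() / L
            else:
                ts = tv_q = tv_r = 0
                for x, y in zip(a[diff], b[diff]):
                    key = (int(x), int(y))
                    if key in _TS:
                        ts += 1
                    elif key in _Q_CLASS:
                        tv_q += 1
                    else:
                        tv_r += 1
                P, Q, R = ts / L, tv_q / L, tv_r / L
                if model == "k3st":
                    val = -0.25 * (
                        _log(1 - 2 * P - 2 * Q, pair, model)
                        + _log(1 - 2 * P - 2 * R, pair, model)
                        + _log(1 - 2 * Q - 2 * R, pair, model)
                    )
                else:  # f84
                    Qt = Q + R
                    val = -2 * A * _log(
                        1 - P / (2 * A) - (A - B) * Qt / (2 * A * C), pair, model
                    ) + 2 * (A - B - C) * _log(1 - Qt / (2 * C), pair, model)
            d[i, j] = d[j, i] = max(val, 0.0)
    return DistanceMatrix(labels=labels, d=d, model=model)


# --- trees ----------------------------------------------------------------


@dataclass
class Node:
    """Tree node; an unrooted tree is stored rooted at a trifurcation."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def find_leaf(self, name: str) -> "Node":
        for l in self.leaves():
            if l.name == name:
                return l
        raise KeyError(name)

    def copy(self) -> "Node":
        return Node(
            self.name, self.length, self.support, [c.copy() for c in self.children]
        )


def write_newick(tree: Node) -> str:
    def fmt(n: Node) -> str:
        if n.is_leaf:
            core = n.name or ""
        else:
            inner = ",".join(fmt(c) for c in n.children)
            label = "" if n.support is None else f"{n.support:g}"
            core = f"({inner}){label}"
        return core if n.length is None else f"{core}:{n.length:.6g}"

    return fmt(tree) + ";"


def neighbor_joining(dm: DistanceMatrix) -> Node:
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes: dict[str, Node] = {l: Node(name=l) for l in dm.labels}
    # cluster label = smallest contained leaf label (used for tie-breaks)
    labels = list(dm.labels)
    d = {
        (a, b): float(dm.d[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i != j
    }

    def dist(a: str, b: str) -> float:
        return d[(a, b)]

    clamped = False
    while len(labels) > 3:
        m = len(labels)
        r = {a: sum(dist(a, k) for k in labels if k != a) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best:
                    best = key
                    pick = (a, b)
        a, b = pick
        la = dist(a, b) / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist(a, b) - la
        if la < 0 or lb < 0:
            clamped = True
        u_label = min(a, b)
        new = Node(children=[nodes[a], nodes[b]])
        nodes[a].length, nodes[b].length = max(la, 0.0), max(lb, 0.0)
        for k in labels:
            if k in (a, b):
                continue
            duk = (dist(a, k) + dist(b, k) - dist(a, b)) / 2
            d[(u_label, k)] = d[(k, u_label)] = max(duk, 0.0)
        labels = [k for k in labels if k not in (a, b)]
        labels.append(u_label)
        labels.sort()
        nodes[u_label] = new

    a, b, c = sorted(labels)
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    if min(la, lb, lc) < 0:
        clamped = True
    for lbl, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lbl].length = max(ln, 0.0)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to zero")
    return Node(children=[nodes[a], nodes[b], nodes[c]])


def bipartitions(tree: Node) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalized as the side not containing the
    alphabetically first leaf."""
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()

    def walk(n: Node) -> frozenset[str]:
        if n.is_leaf:
            return frozenset([n.name])
        below = frozenset().union(*(walk(c) for c in n.children))
        if n is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = all_leaves - below if ref in below else below
            out.add(side)
        return below

    walk(tree)
    return out


def bootstrap_support(
    aln: Alignment,
    model: str = "f84",
    replicates: int = 1000,
    seed: int | None = None,
    ids: Sequence[str] | None = None,
) -> tuple[Node, int]:
    """NJ tree from the full data with bootstrap supports (%) on its internal
    edges; returns (tree, number of successful replicates).

    Columns are resampled with replacement against the canonical column
    order, one index vector per replicate, so supports do not depend on
    record order. Replicates whose distance matrix saturates are skipped
    (with a warning) and do not count towards the denominator.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if seed is None:
        raise ValueError("bootstrap needs an explicit seed")
    full = neighbor_joining(distance_matrix(aln, model=model, ids=ids))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(full)}
    ok = skipped = 0
    ncol = aln.column_count
    from dataclasses import replace as _replace

    use = [aln[i] for i in ids] if ids is not None else list(aln.records)
    for _ in range(replicates):
        idx = rng.integers(0, ncol, size=ncol)
        recs = tuple(
            _replace(r, seq="".join(r.seq[i] for i in idx)) for r in use
        )
        try:
            rep = neighbor_joining(distance_matrix(Alignment(records=recs), model=model))
        except SaturationError:
            skipped += 1
            continue
        ok += 1
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicate(s) skipped (saturation)")
    if ok == 0:
        raise SaturationError("every bootstrap replicate saturated")

    all_leaves = full.leaf_names()
    ref = min(all_leaves)

    def annotate(n: Node, within: Node) -> None:
        for c in n.children:
            if not c.is_leaf:
                below = c.leaf_names()
                side = all_leaves - below if ref in below else below
                if side in counts:
                    c.support = 100.0 * counts[side] / ok
                annotate(c, within)

    annotate(full, full)
    return full, ok


def outgroup_root(tree: Node, outgroup_id: str) -> Node:
    """Root an unrooted tree on the outgroup's pendant edge (midpoint)."""
    t = tree.copy()
    leaves = t.leaf_names()
    if outgroup_id not in leaves:
        raise KeyError(f"outgroup {outgroup_id!r} not a leaf")

    # locate the parent chain to the outgroup leaf
    def path_to(n: Node, target: str, acc: list[Node]) -> list[Node] | None:
        acc = acc + [n]
        if n.is_leaf:
            return acc if n.name == target else None
        for c in n.children:
            got = path_to(c, target, acc)
            if got:
                return got
        return None

    path = path_to(t, outgroup_id, [])
    leaf = path[-1]
    parent = path[-2]
    parent.children.remove(leaf)
    half = (leaf.length or 0.0) / 2

    # re-hang: reverse every edge on the path old-root -> parent
    chain = path[:-1]  # root .. parent
    edges = [c.length for c in chain[1:]]  # edge above chain[i+1]
    for i in range(len(chain) - 1):
        chain[i].children.remove(chain[i + 1])
    for i in range(len(chain) - 1):
        chain[i + 1].children.append(chain[i])
        chain[i].length = edges[i]
    new_base = _suppress_unary(chain[-1])  # old parent carries everything else
    leaf.length = half
    new_base.length = half
    return Node(children=[leaf, new_base])


def _suppress_unary(n: Node) -> Node:
    n.children = [_suppress_unary(c) for c in n.children]
    if len(n.children) == 1 and n.name is None:
        c = n.children[0]
        c.length = (c.length or 0.0) + (n.length or 0.0)
        return c
    return n


def unroot(tree: Node) -> Node:
    """Collapse a bifurcating root back into a trifurcation."""
    if len(tree.children) != 2:
        return tree
    a, b = tree.children
    if b.is_leaf and not a.is_leaf:
        a, b = b, a
    if b.is_leaf:
        raise ValueError("cannot unroot a two-leaf tree")
    merged = (a.length or 0.0) + (b.length or 0.0)
    a.length = merged
    return Node(children=[a] + b.children)
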