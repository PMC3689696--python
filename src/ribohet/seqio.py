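"""Sequence and alignment I/O with the amplicon coordinate convention.

Alignment columns are reported in 1-based *amplicon positions*: column ``c``
of an :class:`Alignment` with offset ``o`` is position ``o + c - 1``,
counted from the first base downstream of the forward amplification primer
(NL1 for the D1/D2 amplicon this package was written around). All reports
elsewhere in the package use these positions, never raw column indices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment, PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .alphabet import ALPHABET, GAP

__all__ = [
    "SequenceRecord",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "read_clustal",
    "write_clustal",
    "align_center_star",
    "trim_overhangs",
]


class ParseError(ValueError):
    """Malformed sequence input; the message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence, optionally tagged with a group label."""

    id: str
    seq: str
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _normalize(seq: str) -> str:
    # '.' is an alternative gap spelling in some alignment exports
    return seq.upper().replace(".", GAP)


@dataclass(frozen=True)
class Alignment:
    """Equal-length records plus the amplicon position of column 1 (offset)."""

    records: tuple[SequenceRecord, ...]
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal record lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        if self.offset < 1:
            raise ValueError("offset must be >= 1")

    @property
    def column_count(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def column(self, column_index: int) -> str:
        """Characters of a 1-based column, in record order."""
        if not 1 <= column_index <= self.column_count:
            raise IndexError(f"column {column_index} out of 1..{self.column_count}")
        return "".join(r.seq[column_index - 1] for r in self.records)

    def column_position(self, column_index: int) -> int:
        """Amplicon position of a 1-based column index."""
        if not 1 <= column_index <= self.column_count:
            raise IndexError(f"column {column_index} out of 1..{self.column_count}")
        return self.offset + column_index - 1

    def column_of_position(self, position: int) -> int:
        c = position - self.offset + 1
        if not 1 <= c <= self.column_count:
            raise IndexError(f"position {position} outside the alignment")
        return c

    def positions(self) -> range:
        return range(self.offset, self.offset + self.column_count)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; sequences are upper-cased, U is accepted and preserved."""
    path = Path(path)
    lines = path.read_text().splitlines()
    # pre-validate so errors can name their line
    seen_header = False
    for i, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            if not s[1:].split():
                raise ParseError(f"{path}:{i}: header with no id")
            seen_header = True
        else:
            if not seen_header:
                raise ParseError(f"{path}:{i}: sequence data before first '>' header")
            bad = set(_normalize(s)) - ALPHABET
            if bad:
                raise ParseError(f"{path}:{i}: illegal characters {sorted(bad)}")
    if not seen_header:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(SequenceRecord(id=rec.id, seq=_normalize(str(rec.seq))))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


def read_clustal(path: str | Path, offset: int = 1) -> Alignment:
    """Read a Clustal-format alignment (interleaved blocks concatenated)."""
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), "clustal")
    except ValueError as exc:
        raise ParseError(f"{path}: not a valid Clustal file ({exc})") from exc
    recs = [SequenceRecord(id=r.id, seq=_normalize(str(r.seq))) for r in aln]
    return Alignment(records=tuple(recs), offset=offset)


def write_clustal(aln: Alignment, path: str | Path) -> None:
    msa = MultipleSeqAlignment(
        [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in aln.records]
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, "clustal")


def _edit_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b)["editDistance"]


def align_center_star(
    records: Sequence[SequenceRecord],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Multiple alignment by the center-star heuristic.

    The center is the record minimizing the summed pairwise edit distance
    (ties broken by input order); every other record is aligned to it by
    global pairwise alignment and the induced center gaps are merged.
    Adequate for near-identical sequences such as repeats of one rDNA
    array; not a general-purpose progressive aligner.
    """
    if len(records) < 2:
        raise ValueError("center-star alignment needs at least 2 records")
    seqs = [r.seq.replace(GAP, "") for r in records]
    n = len(records)
    sums = [sum(_edit_distance(seqs[i], seqs[j]) for j in range(n) if j != i) for i in range(n)]
    center = min(range(n), key=lambda i: (sums[i], i))

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap

    cseq = seqs[center]
    # ins[k] = max gaps any pairwise alignment inserts into the center
    # before center position k (k = 0..len(cseq))
    ins = [0] * (len(cseq) + 1)
    pair_rows: dict[int, tuple[str, str]] = {}
    for i in range(n):
        if i == center:
            continue
        best = aligner.align(cseq, seqs[i])[0]
        ca, oa = str(best[0]), str(best[1])
        pair_rows[i] = (ca, oa)
        k = run = 0
        for ch in ca:
            if ch == GAP:
                run += 1
            else:
                ins[k] = max(ins[k], run)
                run = 0
                k += 1
        ins[len(cseq)] = max(ins[len(cseq)], run)

    def expand_row(ca: str, oa: str) -> str:
        out = []
        k = run = 0
        buf = []
        for cch, och in zip(ca, oa):
            if cch == GAP:
                buf.append(och)
                run += 1
            else:
                out.append(GAP * (ins[k] - run) + "".join(buf))
                buf, run = [], 0
                out.append(och)
                k += 1
        out.append(GAP * (ins[len(cseq)] - run) + "".join(buf))
        return "".join(out)

    rows: list[str] = [""] * n
    rows[center] = expand_row(cseq, cseq)
    for i, (ca, oa) in pair_rows.items():
        rows[i] = expand_row(ca, oa)
    width = max(len(r) for r in rows)
    rows = [r.ljust(width, GAP) for r in rows]  # defensive; lengths should agree
    new = tuple(
        replace(records[i], seq=rows[i]) for i in range(n)
    )
    return Alignment(records=new)


def trim_overhangs(aln: Alignment, reference_ids: Sequence[str]) -> Alignment:
    """Drop leading/trailing columns where *all* reference records are gapped.

    Database entries longer than the amplicon leave terminal overhangs after
    alignment; trimming keeps the coordinate system anchored on the clones.
    Internal reference gaps are retained. The offset is updated so the first
    retained column keeps its original amplicon position.
    """
    missing = set(reference_ids) - set(aln.ids)
    if missing:
        raise KeyError(f"reference ids not in alignment: {sorted(missing)}")
    refs = [aln[i] for i in reference_ids]

    def all_gap(c: int) -> bool:
        return all(r.seq[c - 1] == GAP for r in refs)

    first, last = 1, aln.column_count
    while first <= last and all_gap(first):
        first += 1
    while last >= first and all_gap(last):
        last -= 1
    if first > last:
        raise ValueError("trimming would remove every column")
    new = tuple(replace(r, seq=r.seq[first - 1 : last]) for r in aln.records)
    return Alignment(records=new, offset=aln.offset + first - 1)
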