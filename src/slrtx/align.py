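"""Contig-to-reference alignment (edlib-backed semi-global alignment).

Each contig is assigned to its best-scoring reference and strand by minimum
edit distance; the chosen alignment's extended CIGAR is kept as a run-length
operation string (=, X, I, D) for downstream error profiling, terminus
offsets and pileups.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import edlib

from .annotation import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentRecord:
    query_id: str
    ref_id: str
    strand: str  # '+' | '-' (query reverse-complemented before aligning)
    ref_start: int  # 0-based half-open on the reference
    ref_end: int
    ops: list[tuple[str, int]]  # run-length (=, X, I, D)
    edit_distance: int
    query_length: int

    def __post_init__(self) -> None:
        q = sum(n for op, n in self.ops if op in "=XI")
        r = sum(n for op, n in self.ops if op in "=XD")
        if q != self.query_length or r != self.ref_end - self.ref_start:
            raise ValueError(
                f"{self.query_id}: operation lengths inconsistent with spans"
            )

    def counts(self) -> dict[str, int]:
        out = {"=": 0, "X": 0, "I": 0, "D": 0}
        for op, n in self.ops:
            out[op] += n
        return out

    @property
    def aligned_query_bases(self) -> int:
        c = self.counts()
        return c["="] + c["X"] + c["I"]

    @property
    def leading_ins(self) -> int:
        return self.ops[0][1] if self.ops and self.ops[0][0] == "I" else 0

    @property
    def trailing_ins(self) -> int:
        return self.ops[-1][1] if self.ops and self.ops[-1][0] == "I" else 0

    def query_index_at(self, ref_pos: int) -> int | None:
        """Query index aligned (match/mismatch) at a reference position."""
        rc, qi = self.ref_start, 0
        for op, n in self.ops:
            if op in "=X":
                if rc <= ref_pos < rc + n:
                    return qi + (ref_pos - rc)
                rc += n
                qi += n
            elif op == "D":
                if rc <= ref_pos < rc + n:
                    return None
                rc += n
            else:  # I
                qi += n
        return None


def _parse(query_id, ref_id, strand, qlen, res) -> AlignmentRecord:
    s, e = res["locations"][0]
    ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(res["cigar"])]
    return AlignmentRecord(
        query_id=query_id,
        ref_id=ref_id,
        strand=strand,
        ref_start=s,
        ref_end=e + 1,
        ops=ops,
        edit_distance=res["editDistance"],
        query_length=qlen,
    )


def align_pair(
    query_id: str,
    query: str,
    ref_id: str,
    ref: str,
    mode: str = "HW",
) -> AlignmentRecord:
    """Best-strand alignment of one query against one reference."""
    fwd = edlib.align(query, ref, mode=mode, task="path")
    rev = edlib.align(revcomp(query), ref, mode=mode, task="path")
    if fwd["editDistance"] <= rev["editDistance"]:
        return _parse(query_id, ref_id, "+", len(query), fwd)
    return _parse(query_id, ref_id, "-", len(query), rev)


def best_references(
    query: str, references: Mapping[str, str], mode: str = "HW"
) -> tuple[int, list[tuple[str, str]]]:
    """Minimum edit distance and every (ref, strand) achieving it."""
    best = None
    ties: list[tuple[str, str]] = []
    rc = revcomp(query)
    for rid in sorted(references):
        for strand, q in (("+", query), ("-", rc)):
            d = edlib.align(q, references[rid], mode=mode, task="distance")[
                "editDistance"
            ]
            if best is None or d < best:
                best, ties = d, [(rid, strand)]
            elif d == best:
                ties.append((rid, strand))
    return best, ties


def align_to_reference(
    queries: Mapping[str, str],
    references: Mapping[str, str],
    mode: str = "HW",
    max_divergence: float = 0.3,
) -> tuple[list[AlignmentRecord], list[str]]:
    """Assign each query to its best reference/strand; queries whose best
    alignment diverges beyond `max_divergence` of their length (and empty
    queries) are reported unaligned."""
    if not references:
        raise ValueError("empty reference set")
    records: list[AlignmentRecord] = []
    unaligned: list[str] = []
    for qid in sorted(queries):
        q = queries[qid]
        if not q:
            warnings.warn(f"skipping empty query {qid}")
            continue
        d, ties = best_references(q, references, mode=mode)
        if d > max_divergence * len(q):
            unaligned.append(qid)
            continue
        rid, strand = ties[0]
        seq = q if strand == "+" else revcomp(q)
        res = edlib.align(seq, references[rid], mode=mode, task="path")
        records.append(_parse(qid, rid, strand, len(q), res))
    return records, unaligned
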