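"""Per-UMI synthetic long-read assembly.

Short reads are binned by (sample index, UMI); each bin holds fragments of a
single barcoded molecule and is assembled independently.  Because a bin is
one molecule, a full general-purpose assembler is unnecessary: we build a
k-mer (de Bruijn) spectrum over both read orientations, drop k-mers below a
multiplicity floor (which removes most sequencing-error k-mers and short
error tips), and extend greedily from the most-supported k-mer, resolving
branch points by higher k-mer multiplicity with the alphabetically smallest
base as the deterministic tie-break — the same rule that collapses simple
error bubbles.  The draft is then polished by re-aligning the member reads
and taking a per-column plurality vote, which also yields the depth and
consensus-agreement profiles behind the per-base quality model.

The quality model integrates the three stated ingredients — per-position
depth, the member reads' own base qualities, and the degree of consensus —
as a Laplace-smoothed dissent probability

    p_err = (d - c + 1) / (d + 2)

(d = depth, c = plurality count), floored at the depth-weighted mean
per-read error probability of the column, with Q = -10·log10(p_err) capped.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .annotation import revcomp
from .sim import ADAPTER_3P, ADAPTER_5P, SimShortRead

HEADER_RE = re.compile(r"BX:(?P<sample>[^:\s]+):(?P<umi>[ACGTN]+)")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_VOTE_ROWS = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T; row 4 = deletion vote


class BinParseError(ValueError):
    pass


class AssemblyError(RuntimeError):
    pass


@dataclass
class AssemblyParams:
    k: int = 25
    min_reads_per_bin: int = 3
    min_kmer_multiplicity: int = 2
    quality_cap: int = 60
    adapter_max_edit: int = 2
    adapter_5p: str = ADAPTER_5P
    adapter_3p: str = ADAPTER_3P
    polish_rounds: int = 2

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 15 <= self.k <= 63:
            raise ValueError(f"k must be odd and in [15, 63], got {self.k}")
        if self.min_reads_per_bin < 1:
            raise ValueError("min_reads_per_bin must be >= 1")


@dataclass
class ReadBin:
    sample_index: str
    umi: str
    reads: list[SimShortRead] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.sample_index, self.umi)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class Rejection:
    sample_index: str
    umi: str
    n_reads: int
    reason: str


@dataclass
class SLRContig:
    contig_id: str
    sample_index: str
    umi: str
    sequence: str
    quality: np.ndarray  # per-base Phred, int
    depth: np.ndarray
    agreement: np.ndarray  # plurality fraction per base
    adapter_5p_found: bool
    adapter_5p_pos: tuple[int, int] | None
    adapter_3p_found: bool
    adapter_3p_pos: tuple[int, int] | None
    completeness: str  # full_length | missing_5p | missing_3p | fragment
    n_reads: int

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (len(self.quality) == len(self.depth) == len(self.agreement) == n):
            raise ValueError(f"{self.contig_id}: profile/sequence length mismatch")

    @property
    def insert(self) -> str:
        lo = self.adapter_5p_pos[1] if self.adapter_5p_found else 0
        hi = self.adapter_3p_pos[0] if self.adapter_3p_found else len(self.sequence)
        return self.sequence[lo:hi]

    @property
    def quality_string(self) -> str:
        return "".join(chr(int(q) + 33) for q in self.quality)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_reads(reads) -> list[ReadBin]:
    """Group reads by the (sample index, UMI) pair.

    Accepts SimShortRead objects or raw (header, sequence, quality) triples
    (e.g. from :func:`slrtx.io.read_fastq`); headers must carry the
    ``BX:<sample>:<UMI>`` tag.
    """
    bins: dict[tuple[str, str], ReadBin] = {}
    for r in reads:
        if isinstance(r, SimShortRead):
            key = (r.sample_index, r.umi)
            read = r
        else:
            header, seq, qual = r
            m = HEADER_RE.search(header)
            if m is None:
                rid = header.split()[0] if header else "<empty>"
                raise BinParseError(f"read {rid}: header lacks a BX:<sample>:<UMI> tag")
            key = (m.group("sample"), m.group("umi"))
            mid = re.search(r"MI:(\S+)", header)
            read = SimShortRead(
                read_id=header.split()[0],
                molecule_id=mid.group(1) if mid else ".",
                umi=key[1],
                sample_index=key[0],
                sequence=seq,
                quality=qual,
                offset=-1,
                strand=".",
            )
        bins.setdefault(key, ReadBin(*key)).reads.append(read)
    return [bins[k] for k in sorted(bins)]


# ---------------------------------------------------------------------------
# draft assembly
# ---------------------------------------------------------------------------


def _kmer_walk(reads: list[str], k: int, min_mult: int) -> str | None:
    counts: dict[str, int] = {}
    for seq in reads:
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                counts[km] = counts.get(km, 0) + 1
    counts = {km: c for km, c in counts.items() if c >= min_mult and "N" not in km}
    if not counts:
        return None
    # seed: highest multiplicity, lexicographically smallest on ties
    seed = min(counts, key=lambda km: (-counts[km], km))

    def extend(start: str, forward: bool) -> list[str]:
        path = []
        cur = start
        seen = {start}
        while True:
            best = None
            if forward:
                core = cur[1:]
                cands = [core + b for b in "ACGT"]
            else:
                core = cur[:-1]
                cands = [b + core for b in "ACGT"]
            for cand in cands:
                c = counts.get(cand)
                if c is None or cand in seen:
                    continue
                if best is None or c > counts[best]:
                    best = cand  # ties: first in ACGT order = lexicographic
            if best is None:
                return path
            seen.add(best)
            path.append(best[-1] if forward else best[0])
            cur = best

    right = extend(seed, True)
    left = extend(seed, False)
    return "".join(reversed(left)) + seed + "".join(right)


def _align_read(seq: str, contig: str, max_k: int = -1):
    """Best-orientation infix alignment of a read against the contig."""
    fwd = edlib.align(seq, contig, mode="HW", task="path", k=max_k)
    rc = revcomp(seq)
    rev = edlib.align(rc, contig, mode="HW", task="path", k=max_k)
    if fwd["editDistance"] < 0 and rev["editDistance"] < 0:
        return None
    if rev["editDistance"] < 0 or (
        0 <= fwd["editDistance"] <= rev["editDistance"]
    ):
        return seq, fwd
    return rc, rev


def _vote(reads: list[SimShortRead], contig: str):
    """Per-column base votes (rows A,C,G,T,del) + summed read error probs."""
    L = len(contig)
    votes = np.zeros((5, L), dtype=np.int32)
    errsum = np.zeros(L, dtype=np.float64)
    for r in reads:
        hit = _align_read(r.sequence, contig)
        if hit is None:
            continue
        seq, res = hit
        qual = (
            r.quality
            if seq is r.sequence
            else r.quality[::-1]
        )
        rc = res["locations"][0][0]
        qi = 0
        for n_s, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(n_s)
            if op in "=XM":
                b = np.frombuffer(seq[qi : qi + n].encode(), dtype=np.uint8)
                rows = np.searchsorted(
                    np.frombuffer(b"ACGT", dtype=np.uint8), b
                )
                ok = rows < 4
                cols = np.arange(rc, rc + n)[ok]
                np.add.at(votes, (rows[ok], cols), 1)
                eprob = 10.0 ** (
                    -(
                        np.frombuffer(qual[qi : qi + n].encode(), dtype=np.uint8)
                        - 33.0
                    )
                    / 10.0
                )
                np.add.at(errsum, cols, eprob[ok])
                rc += n
                qi += n
            elif op == "D":
                votes[4, rc : rc + n] += 1
                rc += n
            elif op == "I":
                qi += n
    return votes, errsum


def score_quality(
    depth: np.ndarray,
    plurality: np.ndarray,
    mean_read_err: np.ndarray | None = None,
    cap: int = 60,
) -> np.ndarray:
    """Phred quality from the Laplace-smoothed dissent estimate.

    p_err = (d - c + 1)/(d + 2), floored at the depth-weighted mean per-read
    error probability when supplied; Q = round(-10·log10 p_err), capped.
    """
    d = np.asarray(depth, dtype=float)
    c = np.asarray(plurality, dtype=float)
    if np.any(d <= 0):
        raise AssemblyError("zero depth at a retained position")
    p = (d - c + 1.0) / (d + 2.0)
    if mean_read_err is not None:
        p = np.maximum(p, np.asarray(mean_read_err, dtype=float))
    q = np.rint(-10.0 * np.log10(np.maximum(p, 1e-12)))
    return np.minimum(q, cap).astype(np.int32)


def locate_adapter(
    sequence: str, adapter: str, end: str, max_edit: int
) -> tuple[int, int] | None:
    """Best semi-global match of `adapter` within the terminal window of
    1.5 x adapter length at the given end ('5p' or '3p')."""
    w = int(round(1.5 * len(adapter)))
    window = sequence[:w] if end == "5p" else sequence[-w:]
    if not window:
        return None
    res = edlib.align(adapter, window, mode="HW", task="locations", k=max_edit)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    off = 0 if end == "5p" else len(sequence) - len(window)
    return (off + s, off + e + 1)


def classify_completeness(
    sequence: str,
    adapter_5p: str = ADAPTER_5P,
    adapter_3p: str = ADAPTER_3P,
    max_edit: int = 2,
):
    """(completeness class, insert, 5' hit, 3' hit).

    full_length requires both adapters found in their terminal windows."""
    hit5 = locate_adapter(sequence, adapter_5p, "5p", max_edit)
    hit3 = locate_adapter(sequence, adapter_3p, "3p", max_edit)
    if hit5 and hit3:
        cls = "full_length"
    elif hit3:
        cls = "missing_5p"
    elif hit5:
        cls = "missing_3p"
    else:
        cls = "fragment"
    lo = hit5[1] if hit5 else 0
    hi = hit3[0] if hit3 else len(sequence)
    return cls, sequence[lo:hi], hit5, hit3


# ---------------------------------------------------------------------------
# bin -> contig
# ---------------------------------------------------------------------------


def assemble_bin(bin_: ReadBin, params: AssemblyParams) -> SLRContig | Rejection:
    if len(bin_) < params.min_reads_per_bin:
        return Rejection(*bin_.key, len(bin_), "too_few_reads")
    draft = _kmer_walk(
        [r.sequence for r in bin_.reads], params.k, params.min_kmer_multiplicity
    )
    if draft is None:
        return Rejection(*bin_.key, len(bin_), "insufficient coverage")

    # orient by the 5' adapter; unoriented drafts fall back to the
    # lexicographically smaller strand for determinism
    rc = revcomp(draft)
    fwd5 = locate_adapter(draft, params.adapter_5p, "5p", params.adapter_max_edit)
    rev5 = locate_adapter(rc, params.adapter_5p, "5p", params.adapter_max_edit)
    if rev5 is not None and fwd5 is None:
        draft = rc
    elif fwd5 is None and rev5 is None and rc < draft:
        draft = rc

    contig = draft
    votes = errsum = None
    for _ in range(max(1, params.polish_rounds)):
        votes, errsum = _vote(bin_.reads, contig)
        cons_rows = np.argmax(votes, axis=0)  # ties -> first row (A<C<G<T<del)
        covered = votes.sum(axis=0) > 0
        keep = covered & (cons_rows < 4)
        new = "".join("ACGT"[r] for r in cons_rows[keep])
        if new == contig:
            break
        if not new:
            return Rejection(*bin_.key, len(bin_), "insufficient coverage")
        contig = new

    votes, errsum = _vote(bin_.reads, contig)
    depth = votes.sum(axis=0)
    # trim uncovered flanks; interior zero depth violates the contract
    nz = np.nonzero(depth > 0)[0]
    if nz.size == 0:
        return Rejection(*bin_.key, len(bin_), "insufficient coverage")
    lo, hi = int(nz[0]), int(nz[-1]) + 1
    contig = contig[lo:hi]
    votes = votes[:, lo:hi]
    errsum = errsum[lo:hi]
    depth = votes.sum(axis=0)

    base_votes = votes[:4]
    base_depth = base_votes.sum(axis=0)
    plur = base_votes.max(axis=0)
    mean_err = np.divide(
        errsum, base_depth, out=np.full_like(errsum, 0.75), where=base_depth > 0
    )
    qual = score_quality(depth, plur, mean_err, cap=params.quality_cap)
    agreement = plur / depth

    cls, _, hit5, hit3 = classify_completeness(
        contig, params.adapter_5p, params.adapter_3p, params.adapter_max_edit
    )
    return SLRContig(
        contig_id=f"{bin_.sample_index}:{bin_.umi}",
        sample_index=bin_.sample_index,
        umi=bin_.umi,
        sequence=contig,
        quality=qual,
        depth=depth,
        agreement=agreement,
        adapter_5p_found=hit5 is not None,
        adapter_5p_pos=hit5,
        adapter_3p_found=hit3 is not None,
        adapter_3p_pos=hit3,
        completeness=cls,
        n_reads=len(bin_),
    )


def assemble_all(
    bins: list[ReadBin], params: AssemblyParams | None = None
) -> tuple[list[SLRContig], list[Rejection]]:
    params = params or AssemblyParams()
    contigs, rejected = [], []
    for b in bins:
        out = assemble_bin(b, params)
        (contigs if isinstance(out, SLRContig) else rejected).append(out)
    return contigs, rejected


# ---------------------------------------------------------------------------
# SLR FASTQ round-trip
# ---------------------------------------------------------------------------


def write_slr_fastq(path: str, contigs: list[SLRContig]) -> None:
    from . import io as sio

    sio.write_fastq(
        path,
        (
            (
                f"{c.contig_id} cl:{c.completeness} rc:{c.n_reads}",
                c.sequence,
                c.quality_string,
            )
            for c in contigs
        ),
    )


def read_slr_fastq(path: str) -> list[SLRContig]:
    from . import io as sio

    out = []
    for header, seq, qual in sio.read_fastq(path):
        fields = header.split()
        cid = fields[0]
        tags = dict(f.split(":", 1) for f in fields[1:] if ":" in f)
        sample, _, umi = cid.partition(":")
        q = np.array([ord(ch) - 33 for ch in qual], dtype=np.int32)
        cls, _, hit5, hit3 = classify_completeness(seq)
        out.append(
            SLRContig(
                contig_id=cid,
                sample_index=sample,
                umi=umi,
                sequence=seq,
                quality=q,
                depth=np.zeros(len(seq), dtype=np.int32),
                agreement=np.zeros(len(seq)),
                adapter_5p_found=hit5 is not None,
                adapter_5p_pos=hit5,
                adapter_3p_found=hit3 is not None,
                adapter_3p_pos=hit3,
                completeness=tags.get("cl", cls),
                n_reads=int(tags.get("rc", 0)),
            )
        )
    return out
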