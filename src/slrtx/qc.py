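"""Reference-based validation of assembled synthetic long reads.

Covers per-position error profiling with platform-comparison-style summary
rates, terminus (TSS/TTS) offset accounting, chimera detection by split
end-mapping, observed-vs-expected abundance comparison, and probe on-target
rates.

Rate convention: every summary rate shares the denominator "total aligned
assembled bases" (query bases placed by the aligner: matches + mismatches +
insertions) and the match rate is defined as 1 minus the summed error rate,
so that match + substitution + insertion + deletion = 1 holds identically.
"""
from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord, align_pair, best_references
from .annotation import revcomp

# ---------------------------------------------------------------------------
# error profiling
# ---------------------------------------------------------------------------


def summary_from_rates(substitution: float, insertion: float, deletion: float) -> dict:
    """Summary-rate arithmetic on already-measured per-type rates."""
    s = substitution + insertion + deletion
    return {
        "substitution": substitution,
        "insertion": insertion,
        "deletion": deletion,
        "sum_error": s,
        "match": 1.0 - s,
    }


def indel_reciprocal(insertion: float, deletion: float) -> float:
    """Bases assembled per indel error (reciprocal of the summed indel rate)."""
    return 1.0 / (insertion + deletion)


@dataclass
class ErrorProfile:
    ref_lengths: dict[str, int]
    substitution: dict[str, np.ndarray] = field(default_factory=dict)
    insertion: dict[str, np.ndarray] = field(default_factory=dict)
    deletion: dict[str, np.ndarray] = field(default_factory=dict)
    coverage: dict[str, np.ndarray] = field(default_factory=dict)
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    aligned_bases: int = 0

    def __post_init__(self) -> None:
        for rid, L in self.ref_lengths.items():
            for d in (self.substitution, self.insertion, self.deletion, self.coverage):
                d.setdefault(rid, np.zeros(L, dtype=np.int64))

    def add(self, rec: AlignmentRecord) -> None:
        sub = self.substitution[rec.ref_id]
        ins = self.insertion[rec.ref_id]
        dele = self.deletion[rec.ref_id]
        cov = self.coverage[rec.ref_id]
        rc = rec.ref_start
        for op, n in rec.ops:
            if op == "=":
                cov[rc : rc + n] += 1
                rc += n
            elif op == "X":
                cov[rc : rc + n] += 1
                sub[rc : rc + n] += 1
                self.n_sub += n
                rc += n
            elif op == "D":
                cov[rc : rc + n] += 1
                dele[rc : rc + n] += 1
                self.n_del += n
                rc += n
            else:  # I — attributed to the current reference position
                ins[min(rc, len(ins) - 1)] += n
                self.n_ins += n
        self.aligned_bases += rec.aligned_query_bases

    @classmethod
    def from_alignments(
        cls, records: Iterable[AlignmentRecord], ref_lengths: Mapping[str, int]
    ) -> "ErrorProfile":
        prof = cls(dict(ref_lengths))
        for rec in records:
            prof.add(rec)
        return prof

    def summary(self) -> dict:
        if self.aligned_bases == 0:
            return summary_from_rates(0.0, 0.0, 0.0)
        return summary_from_rates(
            self.n_sub / self.aligned_bases,
            self.n_ins / self.aligned_bases,
            self.n_del / self.aligned_bases,
        )


def profile_errors(
    records: Iterable[AlignmentRecord], ref_lengths: Mapping[str, int]
) -> ErrorProfile:
    return ErrorProfile.from_alignments(records, ref_lengths)


def homopolymer_mask(seq: str, min_run: int = 4) -> np.ndarray:
    """Positions inside homopolymer runs of at least `min_run` bases."""
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def positional_bias(
    profile: ErrorProfile,
    ref_id: str,
    ref_seq: str,
    error_type: str,
    min_homopolymer: int = 4,
) -> pd.DataFrame:
    """Per-position error ratio normalised by the overall rate of the type.

    ratio(pos) = positional rate / overall rate; a zero overall rate yields
    all-zero ratios with ``undefined=True``.
    """
    counts = getattr(profile, error_type)[ref_id].astype(float)
    cov = profile.coverage[ref_id].astype(float)
    overall = profile.summary()[error_type]
    pos_rate = np.divide(counts, cov, out=np.zeros_like(counts), where=cov > 0)
    undefined = overall == 0
    ratio = pos_rate / overall if not undefined else np.zeros_like(pos_rate)
    return pd.DataFrame(
        {
            "position": np.arange(len(counts)),
            "count": counts.astype(int),
            "coverage": cov.astype(int),
            "ratio": ratio,
            "homopolymer": homopolymer_mask(ref_seq, min_homopolymer),
            "undefined": undefined,
        }
    )


# ---------------------------------------------------------------------------
# terminus offsets
# ---------------------------------------------------------------------------


@dataclass
class TerminusOffsets:
    per_contig: pd.DataFrame  # contig_id, ref_id, tss_offset, tts_offset
    tss_buckets: dict[str, float]
    tts_buckets: dict[str, float]
    n: int


def _buckets(offsets: np.ndarray) -> dict[str, float]:
    n = len(offsets)
    if n == 0:
        return {"exact": math.nan, "within_5": math.nan, "gt100_downstream": math.nan}
    return {
        "exact": float(np.mean(offsets == 0)),
        "within_5": float(np.mean((offsets != 0) & (np.abs(offsets) <= 5))),
        "gt100_downstream": float(np.mean(offsets > 100)),
    }


def terminus_offsets(
    records: Iterable[AlignmentRecord],
    ref_lengths: Mapping[str, int],
    annotated: set[str] | None = None,
) -> TerminusOffsets:
    """Signed start/termination-site offsets of full-length contigs.

    Positive = downstream of the annotated site.  The TSS offset is how far
    into the reference the reconstruction starts (minus any unaligned query
    overhang); the TTS offset is how far past the reference end it stops.
    Bucket fractions: exact, non-zero within +/-5 nt, and >100 nt downstream.
    """
    rows = []
    for rec in records:
        if annotated is not None and rec.ref_id not in annotated:
            warnings.warn(f"{rec.query_id}: reference {rec.ref_id} not annotated")
            continue
        L = ref_lengths[rec.ref_id]
        tss = rec.ref_start - rec.leading_ins
        tts = rec.ref_end - L + rec.trailing_ins
        rows.append((rec.query_id, rec.ref_id, tss, tts))
    df = pd.DataFrame(rows, columns=["contig_id", "ref_id", "tss_offset", "tts_offset"])
    return TerminusOffsets(
        per_contig=df,
        tss_buckets=_buckets(df["tss_offset"].to_numpy()),
        tts_buckets=_buckets(df["tts_offset"].to_numpy()),
        n=len(df),
    )


# ---------------------------------------------------------------------------
# chimera detection by split end-mapping
# ---------------------------------------------------------------------------


@dataclass
class ChimeraReport:
    verdicts: pd.DataFrame  # contig_id, verdict, ref_5p, ref_3p
    n_flagged: int
    n_total: int

    @property
    def rate(self) -> float:
        return self.n_flagged / self.n_total if self.n_total else math.nan

    @property
    def rate_percent(self) -> float:
        return round(100.0 * self.rate, 1)


def detect_chimeras(
    contigs: Mapping[str, str],
    references: Mapping[str, str],
    end_window: int = 100,
    max_divergence: float = 0.25,
    separation_factor: float = 1.5,
) -> ChimeraReport:
    """Map the two terminal windows of each contig independently.

    Different best references -> inter-molecular; same reference but
    inconsistent strand/order/separation -> intra-molecular; an unmappable
    window -> unmapped-end.  All three count as flagged.  When a window maps
    equally well to several references (shared sequence), the contig is clean
    if the two ends' best-reference sets intersect consistently.
    """
    rows = []
    n_flagged = 0
    for cid in sorted(contigs):
        seq = contigs[cid]
        w = end_window
        if w > len(seq) // 2:
            w = len(seq) // 2
            warnings.warn(f"{cid}: end window shrunk to {w}")
        w5, w3 = seq[:w], seq[-w:]
        d5, t5 = best_references(w5, references)
        d3, t3 = best_references(w3, references)
        ref5 = t5[0][0] if t5 else None
        ref3 = t3[0][0] if t3 else None
        if d5 > max_divergence * w or d3 > max_divergence * w:
            verdict = "unmapped-end"
        else:
            shared = sorted(set(r for r, _ in t5) & set(r for r, _ in t3))
            if not shared:
                verdict = "inter-molecular"
            else:
                rid = shared[0]
                a5 = align_pair(cid + "/5p", w5, rid, references[rid])
                a3 = align_pair(cid + "/3p", w3, rid, references[rid])
                if a5.strand != a3.strand:
                    verdict = "intra-molecular"
                else:
                    if a5.strand == "+":
                        ordered = a5.ref_start <= a3.ref_start
                        span = a3.ref_end - a5.ref_start
                    else:
                        ordered = a3.ref_start <= a5.ref_start
                        span = a5.ref_end - a3.ref_start
                    if ordered and span <= separation_factor * len(seq):
                        verdict = "clean"
                    else:
                        verdict = "intra-molecular"
                ref5 = ref3 = rid
        if verdict != "clean":
            n_flagged += 1
        rows.append((cid, verdict, ref5, ref3))
    return ChimeraReport(
        verdicts=pd.DataFrame(rows, columns=["contig_id", "verdict", "ref_5p", "ref_3p"]),
        n_flagged=n_flagged,
        n_total=len(rows),
    )


# ---------------------------------------------------------------------------
# abundance comparison
# ---------------------------------------------------------------------------


@dataclass
class AbundanceComparison:
    table: pd.DataFrame  # id, expected, length, observed
    r_all: float | None
    r_filtered: float | None
    min_length: int
    dropouts: list[str]


def compare_abundance(
    observed: Mapping[str, int],
    expected: pd.DataFrame,
    min_length: int = 700,
) -> AbundanceComparison:
    """Pearson r of log2(expected) vs log2(observed + 0.5), for all
    references and for those at least `min_length` bp long."""
    tab = expected.copy()
    if (tab["expected"] <= 0).any() or (tab["length"] <= 0).any():
        raise ValueError("expected abundances and lengths must be positive")
    tab["observed"] = [int(observed.get(i, 0)) for i in tab["id"]]

    def _r(sub: pd.DataFrame) -> float | None:
        # undefined for <3 references or a constant axis
        if len(sub) < 3 or sub["expected"].nunique() < 2 or sub["observed"].nunique() < 2:
            return None
        return float(
            stats.pearsonr(
                np.log2(sub["expected"]), np.log2(sub["observed"] + 0.5)
            ).statistic
        )

    return AbundanceComparison(
        table=tab,
        r_all=_r(tab),
        r_filtered=_r(tab[tab["length"] >= min_length]),
        min_length=min_length,
        dropouts=sorted(tab.loc[tab["observed"] == 0, "id"]),
    )


# ---------------------------------------------------------------------------
# on-target rates
# ---------------------------------------------------------------------------


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def compute_on_target(
    records: Iterable[AlignmentRecord],
    targets: Iterable[tuple[str, int, int]],
) -> dict[str, float]:
    """Read-level and base-level on-target fractions against BED intervals
    (0-based half-open, same reference namespace as the alignments)."""
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in targets:
        by_ref.setdefault(chrom, []).append((s, e))
    merged = {c: _merge(iv) for c, iv in by_ref.items()}
    starts = {c: [s for s, _ in iv] for c, iv in merged.items()}

    def overlap(chrom: str, s: int, e: int) -> int:
        iv = merged.get(chrom)
        if not iv:
            return 0
        total = 0
        i = max(0, bisect_right(starts[chrom], s) - 1)
        for ts, te in iv[i:]:
            if ts >= e:
                break
            total += max(0, min(e, te) - max(s, ts))
        return total

    n_reads = on_reads = 0
    n_bases = on_bases = 0
    for rec in records:
        n_reads += 1
        if overlap(rec.ref_id, rec.ref_start, rec.ref_end) > 0:
            on_reads += 1
        rc = rec.ref_start
        for op, n in rec.ops:
            if op in "=X":
                n_bases += n
                on_bases += overlap(rec.ref_id, rc, rc + n)
                rc += n
            elif op == "D":
                rc += n
    return {
        "read_level": on_reads / n_reads if n_reads else 0.0,
        "base_level": on_bases / n_bases if n_bases else 0.0,
        "n_contigs": n_reads,
        "n_bases": n_bases,
    }
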