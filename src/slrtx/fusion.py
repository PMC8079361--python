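"""Fusion-isoform detection.

Known fusions are found by exact text search of a junction 30-mer (15 nt on
each side of the breakpoint, taken from the centre of a 100 nt flank) over
the contigs and their reverse complements, then verified by split alignment:
the contig segments on either side of the hit must each align to the
expected partner with >= 90% identity over >= 50 nt.  Novel fusions are
contigs whose two ends map to two distinct genes; candidates then pass the
two published-style filters: (i) partners in trans, or in cis separated by
more than 40 kb with at least one gene wholly in between, and (ii) both
breakpoints at annotated exon boundaries (+/- 2 nt).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .align import best_references
from .annotation import ToyAnnotation, revcomp

JUNCTION_K = 30  # 15 + 15 around the breakpoint


class JunctionLibraryError(ValueError):
    pass


@dataclass
class JunctionEntry:
    fusion_id: str
    gene_a: str
    gene_b: str
    kmer: str
    flank: str
    chrom_a: str = "."
    break_a: int = -1
    chrom_b: str = "."
    break_b: int = -1
    ambiguous: bool = False


@dataclass
class JunctionLibrary:
    entries: list[JunctionEntry] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def build_junction_library(table: pd.DataFrame) -> JunctionLibrary:
    """Extract junction 30-mers from a fusion table carrying 100 nt flanks
    (50 upstream + 50 downstream of the breakpoint); rows with non-ACGT
    flanks are rejected, and 30-mers shared by several fusions are flagged
    ambiguous on all owners."""
    lib = JunctionLibrary()
    half = JUNCTION_K // 2
    for _, row in table.iterrows():
        fid = str(row["fusion_id"])
        flank = str(row["flank"]).upper()
        if set(flank) - set("ACGT"):
            lib.rejected.append((fid, "flank contains non-ACGT characters"))
            continue
        if len(flank) < JUNCTION_K:
            lib.rejected.append((fid, f"flank shorter than {JUNCTION_K} nt"))
            continue
        mid = len(flank) // 2
        kmer = flank[mid - half : mid + half]
        lib.entries.append(
            JunctionEntry(
                fusion_id=fid,
                gene_a=str(row["gene_a"]),
                gene_b=str(row["gene_b"]),
                kmer=kmer,
                flank=flank,
                chrom_a=str(row.get("chrom_a", ".")),
                break_a=int(row.get("break_a", -1)),
                chrom_b=str(row.get("chrom_b", ".")),
                break_b=int(row.get("break_b", -1)),
            )
        )
    seen: dict[str, list[JunctionEntry]] = {}
    for e in lib.entries:
        seen.setdefault(e.kmer, []).append(e)
    for owners in seen.values():
        if len(owners) > 1:
            for e in owners:
                e.ambiguous = True
    return lib


@dataclass
class JunctionHit:
    contig_id: str
    fusion_id: str
    offset: int  # 30-mer start on the contig (as stored orientation)
    strand: str


def search_junctions(
    contigs: dict[str, str], library: JunctionLibrary
) -> list[JunctionHit]:
    """Exact substring search of every library 30-mer and its reverse
    complement over every contig."""
    if not library.entries:
        raise JunctionLibraryError("empty junction library")
    hits = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        for e in library.entries:
            for strand, km in (("+", e.kmer), ("-", revcomp(e.kmer))):
                start = seq.find(km)
                while start != -1:
                    hits.append(JunctionHit(cid, e.fusion_id, start, strand))
                    start = seq.find(km, start + 1)
    return hits


@dataclass
class FusionCandidate:
    contig_id: str
    fusion_id: str | None  # None = novel
    gene_a: str
    gene_b: str
    junction: int  # breakpoint position on the (oriented) contig
    orientation: str = "."  # trans | cis
    separation: int | None = None
    intervening: int | None = None
    exon_edge_a: bool = False
    exon_edge_b: bool = False
    verified: str = "unverified"  # verified | unverified | short-arm
    passed: bool = False
    reason: str = ""


def _arm_identity(arm: str, ref: str) -> float:
    best = min(
        edlib.align(q, ref, mode="HW", task="distance")["editDistance"]
        for q in (arm, revcomp(arm))
    )
    return 1.0 - best / len(arm)


def verify_candidate(
    contig: str,
    hit: JunctionHit,
    ref_a: str,
    ref_b: str,
    min_arm: int = 50,
    min_identity: float = 0.9,
    refine_window: int = 10,
) -> tuple[str, int]:
    """Split-align the contig around a junction hit against the two partner
    references: (status, refined breakpoint).  Arms shorter than `min_arm`
    are unverifiable ('short-arm')."""
    seq = contig if hit.strand == "+" else revcomp(contig)
    off = hit.offset if hit.strand == "+" else len(contig) - hit.offset - JUNCTION_K
    j = off + JUNCTION_K // 2
    if j < min_arm or len(seq) - j < min_arm:
        return "short-arm", j
    ok = (
        _arm_identity(seq[:j], ref_a) >= min_identity
        and _arm_identity(seq[j:], ref_b) >= min_identity
    )
    if not ok:
        return "unverified", j
    # refine to the split with minimal combined edit distance
    best_j, best_d = j, None
    for s in range(max(min_arm, j - refine_window), min(len(seq) - min_arm, j + refine_window) + 1):
        d = (
            edlib.align(seq[:s], ref_a, mode="HW", task="distance")["editDistance"]
            + edlib.align(seq[s:], ref_b, mode="HW", task="distance")["editDistance"]
        )
        if best_d is None or d < best_d:
            best_j, best_d = s, d
    return "verified", best_j


# ---------------------------------------------------------------------------
# novel fusions
# ---------------------------------------------------------------------------


def _transcript_end_position(
    annotation: ToyAnnotation, iso_id: str, arm_len: int, side: str
) -> int:
    """Genomic coordinate of the breakpoint implied by an arm covering the
    transcript up to (side='a') or from (side='b') the split."""
    iso = annotation.isoforms[iso_id]
    if side == "a":
        t = min(arm_len - 1, iso.spliced_length - 1)
        return annotation.genomic_position(iso_id, t) + 1  # end coordinate
    t = max(0, iso.spliced_length - arm_len)
    return annotation.genomic_position(iso_id, t)


def detect_novel_fusions(
    contigs: dict[str, str],
    annotation: ToyAnnotation,
    end_window: int = 100,
    max_divergence: float = 0.15,
    min_arm: int = 50,
    coarse_step: int = 25,
) -> list[FusionCandidate]:
    """Candidates = contigs whose terminal windows map to two distinct genes.

    The breakpoint is the split position minimising the combined edit
    distance of the 5' arm against the 5' partner's transcript and the 3'
    arm against the 3' partner's (coarse grid then +/- step refinement),
    projected to genomic coordinates through each partner's exon map.
    """
    refs = {i: annotation.spliced_sequence(i) for i in annotation.isoforms}
    i2g = annotation.iso_to_gene()
    out = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        if len(seq) < 2 * end_window:
            continue
        d5, t5 = best_references(seq[:end_window], refs)
        d3, t3 = best_references(seq[-end_window:], refs)
        if d5 > max_divergence * end_window or d3 > max_divergence * end_window:
            continue
        genes5 = {i2g[r] for r, _ in t5}
        genes3 = {i2g[r] for r, _ in t3}
        if genes5 & genes3:
            continue  # both ends in one gene: not a fusion candidate
        iso_a, strand_a = t5[0]
        iso_b, strand_b = t3[0]
        if strand_a == "-":  # orient the contig along partner A's transcript
            seq = revcomp(seq)
            iso_b, strand_b = best_references(seq[-end_window:], refs)[1][0]
        ra, rb = refs[iso_a], refs[iso_b]

        def split_cost(s: int) -> int:
            return (
                edlib.align(seq[:s], ra, mode="HW", task="distance")["editDistance"]
                + edlib.align(seq[s:], rb, mode="HW", task="distance")["editDistance"]
            )

        grid = list(range(min_arm, len(seq) - min_arm + 1, coarse_step))
        j0 = min(grid, key=split_cost)
        lo = max(min_arm, j0 - coarse_step)
        hi = min(len(seq) - min_arm, j0 + coarse_step)
        j = min(range(lo, hi + 1), key=split_cost)

        gene_a, gene_b = i2g[iso_a], i2g[iso_b]
        brk_a = _transcript_end_position(annotation, iso_a, j, "a")
        brk_b = _transcript_end_position(annotation, iso_b, len(seq) - j, "b")
        ga, gb = annotation.genes[gene_a], annotation.genes[gene_b]
        out.append(
            FusionCandidate(
                contig_id=cid,
                fusion_id=None,
                gene_a=gene_a,
                gene_b=gene_b,
                junction=j,
                exon_edge_a=_near_edge(annotation, gene_a, brk_a),
                exon_edge_b=_near_edge(annotation, gene_b, brk_b),
                verified="verified",
                orientation="trans" if ga.chrom != gb.chrom else "cis",
            )
        )
    return out


def _near_edge(
    annotation: ToyAnnotation, gene_id: str, pos: int, tol: int = 2
) -> bool:
    return any(abs(pos - e) <= tol for e in annotation.exon_edges(gene_id))


def filter_novel_fusions(
    candidates: list[FusionCandidate],
    annotation: ToyAnnotation,
    min_separation: int = 40_000,
    min_intervening: int = 1,
) -> list[FusionCandidate]:
    """Apply the pass rule: [trans, or (cis AND separation > `min_separation`
    AND intervening genes >= `min_intervening`)] AND both breakpoints at
    exon boundaries AND verified.  Separation is the gap between the two
    gene spans; an intervening gene must lie wholly inside that gap."""
    out = []
    for c in candidates:
        if c.gene_a not in annotation.genes or c.gene_b not in annotation.genes:
            c.passed = False
            c.reason = "unannotated partner gene"
            out.append(c)
            continue
        ga = annotation.genes[c.gene_a]
        gb = annotation.genes[c.gene_b]
        if ga.chrom != gb.chrom:
            c.orientation = "trans"
            c.separation = None
            c.intervening = None
            geometry_ok = True
            geo_reason = ""
        else:
            c.orientation = "cis"
            lo, hi = (ga, gb) if ga.start <= gb.start else (gb, ga)
            gap = (lo.end, hi.start)
            c.separation = max(0, gap[1] - gap[0])
            c.intervening = sum(
                1
                for g in annotation.genes_on(ga.chrom)
                if g.gene_id not in (c.gene_a, c.gene_b)
                and g.start >= gap[0]
                and g.end <= gap[1]
            )
            geometry_ok = (
                c.separation > min_separation and c.intervening >= min_intervening
            )
            if not geometry_ok:
                geo_reason = (
                    f"cis separation {c.separation} <= {min_separation}"
                    if c.separation <= min_separation
                    else "no intervening gene"
                )
            else:
                geo_reason = ""
        edges_ok = c.exon_edge_a and c.exon_edge_b
        verified_ok = c.verified == "verified"
        c.passed = geometry_ok and edges_ok and verified_ok
        if not c.passed:
            reasons = []
            if not geometry_ok:
                reasons.append(geo_reason)
            if not edges_ok:
                reasons.append("breakpoint not at an exon boundary")
            if not verified_ok:
                reasons.append(f"verification status {c.verified}")
            c.reason = "; ".join(reasons)
        out.append(c)
    return out


def candidates_table(candidates: list[FusionCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "fusion_id": c.fusion_id or "novel",
                "gene_a": c.gene_a,
                "gene_b": c.gene_b,
                "junction": c.junction,
                "orientation": c.orientation,
                "separation": c.separation,
                "intervening": c.intervening,
                "exon_edge_a": c.exon_edge_a,
                "exon_edge_b": c.exon_edge_b,
                "verified": c.verified,
                "passed": c.passed,
                "reason": c.reason,
            }
            for c in candidates
        ]
    )
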