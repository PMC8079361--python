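"""Isoform assignment by splice-chain matching, count matrices, differential
expression, DEG/DEI categorisation and sample-similarity summaries.

A full-length contig is assigned by (1) picking the closest spliced
transcript by edit distance to locate the gene, (2) projecting the
contig-to-transcript alignment through that isoform's exon map, which turns
alignment deletion/insertion runs of at least `intron_threshold` nt in
transcript space into genomic splice-junction changes (exon skipping,
retained sequence), while smaller indels flanking a junction shift its
effective coordinate, and (3) matching the resulting genomic junction chain
against the annotated isoforms of the gene: the contig's chain must appear
as a contiguous block of an isoform's chain with every junction end within
the tolerance.  Among consistent isoforms the one with the fewest unmatched
junctions wins (longest-compatible-chain), with the lexicographically
smallest id as the deterministic tie-break.  Mono-exonic contigs are
assigned by exon containment.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .align import align_pair, best_references
from .annotation import ToyAnnotation
from .stats import nb_wald_test

INTRON_THRESHOLD = 20


@dataclass
class IsoformAssignment:
    contig_id: str
    isoform_id: str | None  # None for novel / unassigned
    status: str  # assigned | novel | unassigned
    reason: str = ""
    junctions: list[tuple[int, int]] | None = None
    gene_id: str | None = None


def _contig_junctions(
    contig_id: str,
    contig: str,
    iso_id: str,
    annotation: ToyAnnotation,
    transcript_ref: str,
    intron_threshold: int,
    junction_tolerance: int,
):
    """Genomic junction chain of a contig via its closest transcript.

    Returns (chain, genomic span, has_unmappable_insert).  Deletion runs of
    at least `intron_threshold` transcript nt become replacement junctions
    (e.g. a skipped exon); insertion runs that long cannot be placed on the
    genome and mark the contig novel; shorter indels within
    `junction_tolerance` of a junction shift that junction's coordinates.
    """
    iso = annotation.isoforms[iso_id]
    L = iso.spliced_length
    rec = align_pair(contig_id, contig, iso_id, transcript_ref)

    def gpos(t: int) -> int:
        return annotation.genomic_position(iso_id, t)

    # transcript coordinate of each annotated junction boundary
    bounds = []
    for d_end, a_start in iso.junction_chain():
        ta = annotation.transcript_position(iso_id, a_start)
        td = annotation.transcript_position(iso_id, d_end - 1)
        bounds.append(min(ta, td) + 1)

    # flanking genomic positions in ascending order (strand-neutral)
    chain = {
        c: (min(gpos(c - 1), gpos(c)), max(gpos(c - 1), gpos(c))) for c in bounds
    }
    shifts = {c: 0 for c in bounds}
    removed: set[int] = set()
    added: list[tuple[int, int]] = []
    has_big_insert = False

    t = rec.ref_start
    for op, n in rec.ops:
        if op in "=X":
            t += n
        elif op == "D":
            if n >= intron_threshold:
                for c in bounds:
                    if t <= c - 1 < t + n or t <= c < t + n:
                        removed.add(c)
                if 0 < t and t + n < L:
                    p1, p2 = gpos(t - 1), gpos(t + n)
                    added.append((min(p1, p2) + 1, max(p1, p2)))
            else:
                near = [c for c in bounds if abs(c - t) <= junction_tolerance + n]
                if near:
                    c = min(near, key=lambda c: abs(c - t))
                    shifts[c] -= n
            t += n
        else:  # I
            if n >= intron_threshold:
                has_big_insert = True
            else:
                near = [c for c in bounds if abs(c - t) <= junction_tolerance + n]
                if near:
                    c = min(near, key=lambda c: abs(c - t))
                    shifts[c] += n

    out = []
    for c in bounds:
        if c in removed or not (rec.ref_start < c < rec.ref_end):
            continue
        lo, hi = chain[c]
        out.append((lo + 1 + shifts[c], hi))
    out.extend(added)
    out.sort()

    gs = sorted((gpos(rec.ref_start), gpos(max(rec.ref_start, rec.ref_end - 1))))
    span = (gs[0], gs[1] + 1)
    return out, span, has_big_insert


def _chain_matches(
    contig_chain: list[tuple[int, int]],
    iso_chain: list[tuple[int, int]],
    tol: int,
) -> bool:
    """contig chain == a contiguous block of the isoform chain within tol."""
    k, m = len(contig_chain), len(iso_chain)
    if k > m:
        return False
    for off in range(m - k + 1):
        if all(
            abs(cd - jd) <= tol and abs(ca - ja) <= tol
            for (cd, ca), (jd, ja) in zip(contig_chain, iso_chain[off : off + k])
        ):
            return True
    return False


def assign_isoform(
    contig_id: str,
    contig: str,
    annotation: ToyAnnotation,
    transcript_refs: dict[str, str],
    junction_tolerance: int = 5,
    intron_threshold: int = INTRON_THRESHOLD,
) -> IsoformAssignment:
    _, ties = best_references(contig, transcript_refs)
    best_iso = ties[0][0]
    gene_id = annotation.isoforms[best_iso].gene_id
    gene = annotation.genes[gene_id]
    if gene.chrom not in annotation.chromosomes:
        return IsoformAssignment(
            contig_id, None, "unassigned", f"chromosome {gene.chrom} missing"
        )
    chain, span, big_insert = _contig_junctions(
        contig_id,
        contig,
        best_iso,
        annotation,
        transcript_refs[best_iso],
        intron_threshold,
        junction_tolerance,
    )
    if big_insert:
        return IsoformAssignment(
            contig_id, None, "novel", "unmappable inserted sequence", chain, gene_id
        )
    candidates = annotation.isoforms_of_gene(gene_id)
    if not chain:  # mono-exonic: containment in one exon
        compatible = [
            iso.isoform_id
            for iso in candidates
            if any(
                s - junction_tolerance <= span[0] and span[1] <= e + junction_tolerance
                for s, e in iso.exons
            )
        ]
        if not compatible:
            return IsoformAssignment(
                contig_id, None, "novel", "no containing exon", [], gene_id
            )
        return IsoformAssignment(
            contig_id, sorted(compatible)[0], "assigned", "", [], gene_id
        )
    matches = [
        (len(iso.junction_chain()) - len(chain), iso.isoform_id)
        for iso in candidates
        if _chain_matches(chain, iso.junction_chain(), junction_tolerance)
    ]
    if not matches:
        return IsoformAssignment(
            contig_id, None, "novel", "junction chain unannotated", chain, gene_id
        )
    # fewest unmatched junctions first (longest compatible chain), then id
    matches.sort()
    return IsoformAssignment(
        contig_id, matches[0][1], "assigned", "", chain, gene_id
    )


def assign_contigs(
    contigs: dict[str, str],
    annotation: ToyAnnotation,
    junction_tolerance: int = 5,
) -> list[IsoformAssignment]:
    refs = {i: annotation.spliced_sequence(i) for i in annotation.isoforms}
    return [
        assign_isoform(cid, seq, annotation, refs, junction_tolerance)
        for cid, seq in sorted(contigs.items())
    ]


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def build_count_matrices(
    assignments: dict[str, list[IsoformAssignment]],
    annotation: ToyAnnotation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(isoform x sample, gene x sample) integer count matrices of assigned
    contigs; gene counts are the sums of their isoforms' counts."""
    samples = sorted(assignments)
    iso_ids = sorted(annotation.isoforms)
    iso = pd.DataFrame(0, index=iso_ids, columns=samples, dtype=np.int64)
    for sample, asns in assignments.items():
        for a in asns:
            if a.status == "assigned":
                iso.loc[a.isoform_id, sample] += 1
    i2g = annotation.iso_to_gene()
    gene = iso.groupby([i2g[i] for i in iso.index]).sum()
    gene = gene.reindex(sorted(annotation.genes), fill_value=0)
    return iso, gene


def differential_expression(
    counts: pd.DataFrame, groups: dict[str, str], fdr: float = 0.05, min_fold: float = 2.0
) -> pd.DataFrame:
    """NB Wald differential test with the FDR/fold-change selection rule."""
    return nb_wald_test(counts, groups, fdr=fdr, min_fold=min_fold)


# ---------------------------------------------------------------------------
# DEG / DEI categorisation
# ---------------------------------------------------------------------------


@dataclass
class DECategorization:
    deg_only: set[str]
    intersect: set[str]
    dei_only: set[str]
    frac_deg_only: float | None  # DEG-only genes / DEGs
    frac_dei_only: float | None  # DEI-only genes / DEI genes
    defined: bool = True


def categorize_deg_dei(
    deg_genes: set[str],
    dei_isoforms: set[str],
    iso_to_gene: dict[str, str],
) -> DECategorization:
    """Partition genes into DEG-only / DEG&DEI / DEI-only sets with the two
    headline fractions."""
    missing = [i for i in dei_isoforms if i not in iso_to_gene]
    if missing:
        raise KeyError(f"isoforms with unknown parent gene: {sorted(missing)[:5]}")
    dei_genes = {iso_to_gene[i] for i in dei_isoforms}
    inter = deg_genes & dei_genes
    deg_only = deg_genes - dei_genes
    dei_only = dei_genes - deg_genes
    defined = bool(deg_genes) and bool(dei_genes)
    return DECategorization(
        deg_only=deg_only,
        intersect=inter,
        dei_only=dei_only,
        frac_deg_only=len(deg_only) / len(deg_genes) if deg_genes else None,
        frac_dei_only=len(dei_only) / len(dei_genes) if dei_genes else None,
        defined=defined,
    )


# ---------------------------------------------------------------------------
# sample similarity
# ---------------------------------------------------------------------------


@dataclass
class SampleSimilarity:
    pearson: pd.DataFrame
    linkage: np.ndarray
    newick: str
    pca: pd.DataFrame


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def sample_similarity(matrix: pd.DataFrame) -> SampleSimilarity:
    """Average-linkage clustering on 1 - Pearson distance of row-standardised
    features, plus PCA coordinates and the sample Pearson matrix.  Constant
    feature rows are dropped before standardisation.  Deterministic."""
    if matrix.shape[1] < 2:
        raise ValueError("at least two samples required")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    x = x[sd > 0]
    sd = sd[sd > 0]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    n = matrix.shape[1]
    corr = np.corrcoef(z.T) if len(z) > 1 else np.ones((n, n))
    corr = np.clip(corr, -1.0, 1.0)
    pearson = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.average(squareform(dist, checks=False))
    tree = hierarchy.to_tree(link)
    newick = _to_newick(tree, list(matrix.columns)) + ";"
    # PCA of samples on the standardised features
    xc = z.T - z.T.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate positive
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] *= -1
    k = min(n - 1, u.shape[1], 5)
    coords = u[:, :k] * s[:k]
    pca = pd.DataFrame(
        coords, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return SampleSimilarity(pearson=pearson, linkage=link, newick=newick, pca=pca)
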