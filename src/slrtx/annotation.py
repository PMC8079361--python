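"""Toy gene annotation model shared by the simulator and the analysis stages.

Coordinates are 0-based half-open internally; GTF is written/read 1-based
inclusive, as the format requires.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class Isoform:
    isoform_id: str
    gene_id: str
    exons: list[tuple[int, int]]  # genomic, sorted, non-overlapping

    def __post_init__(self) -> None:
        ex = self.exons
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(
                    f"{self.isoform_id}: exons must be strictly ordered and "
                    f"non-overlapping, got {ex}"
                )
        if ex and not ex[0][0] < ex[0][1]:
            raise ValueError(f"{self.isoform_id}: empty exon {ex[0]}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junction_chain(self) -> list[tuple[int, int]]:
        """Internal splice junctions as (donor_end, acceptor_start) genomic pairs."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class FusionPairDesign:
    gene_a: str
    gene_b: str
    kind: str  # "cis" | "trans"
    separation: int | None  # configured genomic gap (cis only)
    intervening: int | None  # configured count of genes wholly in between


@dataclass
class ToyAnnotation:
    chromosomes: dict[str, str]
    genes: dict[str, Gene]
    isoforms: dict[str, Isoform]
    fusion_pairs: list[FusionPairDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iso in self.isoforms.values():
            if iso.gene_id not in self.genes:
                raise ValueError(f"{iso.isoform_id}: unknown gene {iso.gene_id}")

    # ---- sequence access -------------------------------------------------
    def spliced_sequence(self, isoform_id: str) -> str:
        iso = self.isoforms[isoform_id]
        gene = self.genes[iso.gene_id]
        chrom = self.chromosomes[gene.chrom]
        seq = "".join(chrom[s:e] for s, e in iso.exons)
        return revcomp(seq) if gene.strand == "-" else seq

    def isoforms_of_gene(self, gene_id: str) -> list[Isoform]:
        return sorted(
            (i for i in self.isoforms.values() if i.gene_id == gene_id),
            key=lambda i: i.isoform_id,
        )

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes.values() if g.chrom == chrom),
            key=lambda g: (g.start, g.gene_id),
        )

    def iso_to_gene(self) -> dict[str, str]:
        return {i: iso.gene_id for i, iso in self.isoforms.items()}

    # Transcript coordinate of a genomic position within an isoform's exons,
    # measured from the transcript 5' end (strand aware). None if intronic /
    # outside.
    def transcript_position(self, isoform_id: str, genome_pos: int) -> int | None:
        iso = self.isoforms[isoform_id]
        gene = self.genes[iso.gene_id]
        off = 0
        hit = None
        for s, e in iso.exons:
            if s <= genome_pos < e:
                hit = off + (genome_pos - s)
                break
            off += e - s
        if hit is None:
            return None
        if gene.strand == "-":
            return iso.spliced_length - 1 - hit
        return hit

    # Genomic position of a transcript coordinate (inverse of the above).
    def genomic_position(self, isoform_id: str, t: int) -> int:
        iso = self.isoforms[isoform_id]
        gene = self.genes[iso.gene_id]
        if gene.strand == "-":
            t = iso.spliced_length - 1 - t
        off = 0
        for s, e in iso.exons:
            if t < off + (e - s):
                return s + (t - off)
            off += e - s
        raise IndexError(f"transcript position {t} outside {isoform_id}")

    def exon_edges(self, gene_id: str) -> set[int]:
        edges: set[int] = set()
        for iso in self.isoforms_of_gene(gene_id):
            for s, e in iso.exons:
                edges.add(s)
                edges.add(e)
        return edges

    # ---- I/O -------------------------------------------------------------
    def to_gtf(self, path: str) -> None:
        lines = []
        for gid in sorted(self.genes):
            g = self.genes[gid]
            attrs = f'gene_id "{gid}";'
            lines.append(
                f"{g.chrom}\tslrtx\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
            )
            for iso in self.isoforms_of_gene(gid):
                s, e = iso.span
                attrs = f'gene_id "{gid}"; transcript_id "{iso.isoform_id}";'
                lines.append(
                    f"{g.chrom}\tslrtx\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}"
                )
                for xs, xe in iso.exons:
                    lines.append(
                        f"{g.chrom}\tslrtx\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{attrs}"
                    )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_gtf(cls, path: str, chromosomes: dict[str, str] | None = None) -> "ToyAnnotation":
        genes: dict[str, Gene] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        iso_gene: dict[str, str] = {}
        iso_meta: dict[str, tuple[str, str]] = {}
        attr_re = re.compile(r'(\w+) "([^"]*)"')
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, _, feat, start, end, _, strand, _, attr_s = f[:9]
                attrs = dict(attr_re.findall(attr_s))
                if feat == "gene":
                    gid = attrs["gene_id"]
                    genes[gid] = Gene(gid, chrom, strand, int(start) - 1, int(end))
                elif feat == "exon":
                    tid = attrs["transcript_id"]
                    exons.setdefault(tid, []).append((int(start) - 1, int(end)))
                    iso_gene[tid] = attrs["gene_id"]
                    iso_meta[tid] = (chrom, strand)
        for gid_set in set(iso_gene.values()) - set(genes):
            # gene feature absent: infer span from exons
            tids = [t for t, g in iso_gene.items() if g == gid_set]
            chrom, strand = iso_meta[tids[0]]
            lo = min(min(s for s, _ in exons[t]) for t in tids)
            hi = max(max(e for _, e in exons[t]) for t in tids)
            genes[gid_set] = Gene(gid_set, chrom, strand, lo, hi)
        isoforms = {
            tid: Isoform(tid, iso_gene[tid], sorted(ex)) for tid, ex in exons.items()
        }
        return cls(chromosomes or {}, genes, isoforms)
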