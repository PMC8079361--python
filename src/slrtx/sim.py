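"""Truth-annotated simulator for UMI-tagged synthetic long-read libraries.

Emulates the library model behind UMI-binned SLR transcriptome sequencing:
each cDNA molecule receives a unique molecular identifier (UMI) and synthetic
5'/3' terminal adapters, is fragmented into short reads whose headers carry
the sample index and UMI, and downstream stages rebuild the molecule by
per-UMI assembly.  Every artefact the wet protocol produces is modelled with
an explicit truth label so detection stages can be scored exactly:

* premature reverse-transcription termination — the 5' end of the transcript
  is lost but the terminal adapter still attaches, so the molecule looks
  full length while its start site is shifted >= 100 nt downstream;
* poly-T mis-priming at the 3' end — the termination site lands within a few
  nucleotides of the annotated one (discrete normal, SD 2 nt, truncated to
  [-5, +5]);
* inter-molecular PCR chimeras — the 5' part of one molecule joined to the
  3' part of another, with the junction in the middle half of the insert.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import (
    FusionPairDesign,
    Gene,
    Isoform,
    ToyAnnotation,
    revcomp,
)

# Synthetic terminal adapters (22 nt package constants; configurable).
ADAPTER_5P = "TCGGATTCACGACTGCAATAGC"
ADAPTER_3P = "GATCGTCAGGTACTCCGTAATG"

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameter container for one simulated library."""

    n_genes: int = 6
    isoforms_per_gene: int = 1
    exons_per_gene: int = 4
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (150, 400)
    intergenic_gap: int = 2000
    n_molecules: int = 300
    abundance: tuple[float, ...] | None = None  # over sorted isoform ids
    n_samples: int = 1
    read_length: int = 150
    coverage_depth: float = 30.0
    sub_rate: float = 4e-3
    ins_rate: float = 4e-4
    del_rate: float = 5e-4
    base_quality: int = 33
    premature_termination_prob: float = 0.13
    tts_mispriming_prob: float = 0.156
    tts_offset_sd: float = 2.0
    tts_offset_max: int = 5
    chimera_rate: float = 0.018
    umi_length: int = 16
    adapter_5p: str = ADAPTER_5P
    adapter_3p: str = ADAPTER_3P
    fusions: bool = False
    min_fragment_length: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("at least one gene must be requested")
        for name in (
            "sub_rate",
            "ins_rate",
            "del_rate",
            "premature_termination_prob",
            "tts_mispriming_prob",
            "chimera_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if self.abundance is not None:
            if abs(sum(self.abundance) - 1.0) > 1e-8:
                raise SimConfigError("abundance vector must sum to 1")
        if self.isoforms_per_gene > 1 and self.exons_per_gene < 3:
            raise SimConfigError(
                "exon-skipping isoforms need exons_per_gene >= 3"
            )
        if self.fusions and self.n_genes < 5:
            raise SimConfigError("fusion scenarios need at least 5 genes")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-local generator so each operation is independently reproducible."""
        return np.random.default_rng([self.seed, stage])


@dataclass
class BarcodedMolecule:
    molecule_id: str
    umi: str
    sample_index: str
    isoform_id: str
    insert: str
    adapter_5p_present: bool = True
    adapter_3p_present: bool = True
    # truth labels
    premature_offset: int = 0  # nt of transcript 5' end lost (>= 100 when set)
    tts_offset: int = 0  # signed; + = past annotated site (into poly-A)
    chimera: str = "none"  # none | inter | intra
    chimera_partner: str | None = None
    chimera_partner_isoform: str | None = None
    chimera_junction: int | None = None  # position in insert
    fusion_id: str | None = None
    snv_truth: list[tuple[int, str]] = field(default_factory=list)
    _adapter_5p: str = ADAPTER_5P
    _adapter_3p: str = ADAPTER_3P

    @property
    def sequence(self) -> str:
        seq = self.insert
        if self.adapter_5p_present:
            seq = self._adapter_5p + seq
        if self.adapter_3p_present:
            seq = seq + self._adapter_3p
        return seq


@dataclass
class SimShortRead:
    read_id: str
    molecule_id: str
    umi: str
    sample_index: str
    sequence: str
    quality: str
    offset: int  # truth start within parent molecule sequence
    strand: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")

    @property
    def header(self) -> str:
        return f"{self.read_id} BX:{self.sample_index}:{self.umi} MI:{self.molecule_id}"


# ---------------------------------------------------------------------------
# annotation construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    cfg: SimConfig,
    strand: str = "+",
) -> tuple[Gene, list[Isoform], int]:
    """Lay out one gene's exon/intron structure from `start`; returns end."""
    pos = start
    exons: list[tuple[int, int]] = []
    for i in range(cfg.exons_per_gene):
        if i > 0:
            pos += int(rng.integers(*cfg.intron_length))
        length = int(rng.integers(*cfg.exon_length))
        exons.append((pos, pos + length))
        pos += length
    gene = Gene(gene_id, chrom, strand, start, pos)
    isoforms = [Isoform(f"{gene_id}.I1", gene_id, exons)]
    # Additional isoforms skip one internal exon each (shared-sequence variants).
    n_internal = len(exons) - 2
    for j in range(2, cfg.isoforms_per_gene + 1):
        skip = 1 + (j - 2) % max(1, n_internal)
        sub = [e for i, e in enumerate(exons) if i != skip]
        isoforms.append(Isoform(f"{gene_id}.I{j}", gene_id, sub))
    return gene, isoforms, pos


def build_toy_annotation(config: SimConfig) -> ToyAnnotation:
    """Generate genes/isoforms (and, if enabled, designed fusion geometry).

    With ``config.fusions`` the layout guarantees, on one chromosome, a cis
    pair separated by >40 kb with one gene wholly in between, a cis pair
    separated by <40 kb with no gene in between, and a trans pair on a second
    chromosome — the three geometries the fusion filters discriminate.
    """
    config.validate()
    rng = config.rng(1)
    genes: dict[str, Gene] = {}
    isoforms: dict[str, Isoform] = {}
    pairs: list[FusionPairDesign] = []
    gids = [f"G{i + 1:03d}" for i in range(config.n_genes)]

    def add(gene: Gene, isos: list[Isoform]) -> None:
        genes[gene.gene_id] = gene
        for iso in isos:
            isoforms[iso.isoform_id] = iso

    if config.fusions:
        # chr1: G1 ---18kb--- G2(intervening) ---...--- G3 --10kb-- G4
        g1, i1, end1 = _make_gene(rng, gids[0], "chr1", 1000, config)
        g2, i2, end2 = _make_gene(rng, gids[1], "chr1", end1 + 18_000, config)
        far_start = end1 + 41_000
        if far_start <= g2.end:  # keep G2 wholly between G1 and G3
            far_start = g2.end + 1000
        g3, i3, end3 = _make_gene(rng, gids[2], "chr1", far_start, config)
        g4, i4, end4 = _make_gene(rng, gids[3], "chr1", end3 + 10_000, config)
        g5, i5, end5 = _make_gene(rng, gids[4], "chr2", 1000, config)
        for g, i in [(g1, i1), (g2, i2), (g3, i3), (g4, i4), (g5, i5)]:
            add(g, i)
        pairs = [
            FusionPairDesign(g1.gene_id, g3.gene_id, "cis", g3.start - g1.end, 1),
            FusionPairDesign(g3.gene_id, g4.gene_id, "cis", g4.start - g3.end, 0),
            FusionPairDesign(g1.gene_id, g5.gene_id, "trans", None, None),
        ]
        pos3 = 1000
        for gid in gids[5:]:
            g, i, pos3 = _make_gene(rng, gid, "chr3", pos3, config)
            add(g, i)
            pos3 += config.intergenic_gap
        chrom_ids = {"chr1", "chr2"} | ({"chr3"} if len(gids) > 5 else set())
    else:
        pos = 1000
        for gid in gids:
            g, i, pos = _make_gene(rng, gid, "chr1", pos, config)
            add(g, i)
            pos += config.intergenic_gap
        chrom_ids = {"chr1"}

    chromosomes = {}
    for c in sorted(chrom_ids):
        hi = max(g.end for g in genes.values() if g.chrom == c) + 1000
        chromosomes[c] = _random_seq(rng, hi)
    return ToyAnnotation(chromosomes, genes, isoforms, pairs)


# ---------------------------------------------------------------------------
# molecule sampling
# ---------------------------------------------------------------------------


def tts_offset_pmf(sd: float = 2.0, max_offset: int = 5) -> dict[int, float]:
    """Discrete normal pmf, truncated to [-max_offset, +max_offset]."""
    xs = range(-max_offset, max_offset + 1)
    w = {x: math.exp(-(x * x) / (2 * sd * sd)) for x in xs}
    z = sum(w.values())
    return {x: v / z for x, v in w.items()}


def sample_molecules(
    annotation: ToyAnnotation,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[BarcodedMolecule]:
    """Draw UMI-tagged molecules from the isoform abundance vector.

    UMIs are uniform over the 4^L space; collisions are allowed and visible in
    the truth table, not prevented.  Premature termination keeps the 5'
    adapter attached (the false-full-length phenomenon).
    """
    rng = rng if rng is not None else config.rng(2)
    iso_ids = sorted(annotation.isoforms)
    if config.abundance is not None and len(config.abundance) != len(iso_ids):
        raise SimConfigError(
            f"abundance vector length {len(config.abundance)} != "
            f"{len(iso_ids)} isoforms"
        )
    p = (
        np.asarray(config.abundance, dtype=float)
        if config.abundance is not None
        else np.full(len(iso_ids), 1.0 / len(iso_ids))
    )
    spliced = {i: annotation.spliced_sequence(i) for i in iso_ids}
    pmf = tts_offset_pmf(config.tts_offset_sd, config.tts_offset_max)
    offs = np.array(sorted(pmf))
    offp = np.array([pmf[o] for o in sorted(pmf)])

    molecules: list[BarcodedMolecule] = []
    for m in range(config.n_molecules):
        iso = iso_ids[int(rng.choice(len(iso_ids), p=p))]
        insert = spliced[iso]
        umi = _random_seq(rng, config.umi_length)
        sample = f"S{int(rng.integers(config.n_samples)) + 1}"
        pre = 0
        if (
            rng.random() < config.premature_termination_prob
            and len(insert) >= 220
        ):
            pre = int(rng.integers(100, len(insert) // 2 + 1))
            insert = insert[pre:]
        tts = 0
        if rng.random() < config.tts_mispriming_prob:
            tts = int(offs[int(rng.choice(len(offs), p=offp))])
            if tts < 0:
                insert = insert[:tts]
            elif tts > 0:
                insert = insert + "A" * tts
        molecules.append(
            BarcodedMolecule(
                molecule_id=f"M{m:06d}",
                umi=umi,
                sample_index=sample,
                isoform_id=iso,
                insert=insert,
                premature_offset=pre,
                tts_offset=tts,
                _adapter_5p=config.adapter_5p,
                _adapter_3p=config.adapter_3p,
            )
        )
    return molecules


def inject_chimeras(
    molecules: list[BarcodedMolecule],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[BarcodedMolecule]:
    """Turn a Bernoulli(rate) fraction of molecules into inter-molecular
    chimeras: 5' part of the molecule joined to the 3' part of a partner from
    a different source isoform, junction uniform in the middle half."""
    if config.chimera_rate == 0 or not molecules:
        return molecules
    rng = rng if rng is not None else config.rng(3)
    iso_of = [m.isoform_id for m in molecules]
    if len(set(iso_of)) < 2:
        raise SimConfigError("chimera injection needs >= 2 distinct source isoforms")
    out = list(molecules)
    hits = np.nonzero(rng.random(len(molecules)) < config.chimera_rate)[0]
    for i in hits:
        a = molecules[i]
        while True:
            j = int(rng.integers(len(molecules)))
            if iso_of[j] != a.isoform_id:
                break
        b = molecules[j]
        la, lb = len(a.insert), len(b.insert)
        ja = int(rng.integers(la // 4, 3 * la // 4 + 1))
        jb = int(rng.integers(lb // 4, 3 * lb // 4 + 1))
        out[i] = replace(
            a,
            insert=a.insert[:ja] + b.insert[jb:],
            chimera="inter",
            chimera_partner=b.molecule_id,
            chimera_partner_isoform=b.isoform_id,
            chimera_junction=ja,
        )
    return out


def apply_snv(
    molecules: list[BarcodedMolecule],
    isoform_id: str,
    transcript_pos: int,
    alt_base: str,
    fraction: float,
    rng: np.random.Generator,
) -> list[BarcodedMolecule]:
    """Flip a transcript position to `alt_base` in a Bernoulli(fraction) subset
    of the molecules of one isoform (truth recorded per molecule)."""
    out = []
    for m in molecules:
        if (
            m.isoform_id == isoform_id
            and m.chimera == "none"
            and rng.random() < fraction
        ):
            p = transcript_pos - m.premature_offset
            if 0 <= p < len(m.insert):
                ins = m.insert[:p] + alt_base + m.insert[p + 1 :]
                m = replace(
                    m, insert=ins, snv_truth=m.snv_truth + [(transcript_pos, alt_base)]
                )
        out.append(m)
    return out


def sample_fusion_molecules(
    annotation: ToyAnnotation,
    config: SimConfig,
    n_per_pair: int,
    rng: np.random.Generator | None = None,
    start_index: int = 0,
) -> list[BarcodedMolecule]:
    """Emit molecules for each designed fusion pair: the 5' exons of partner A
    spliced to the 3' exons of partner B at annotated exon boundaries."""
    rng = rng if rng is not None else config.rng(4)
    out: list[BarcodedMolecule] = []
    m = start_index
    for pair in annotation.fusion_pairs:
        part_a, part_b, _ = fusion_parts(annotation, pair)
        for _ in range(n_per_pair):
            out.append(
                BarcodedMolecule(
                    molecule_id=f"F{m:06d}",
                    umi=_random_seq(rng, config.umi_length),
                    sample_index="S1",
                    isoform_id=f"{pair.gene_a}|{pair.gene_b}",
                    insert=part_a + part_b,
                    fusion_id=f"{pair.gene_a}-{pair.gene_b}",
                    chimera_junction=len(part_a),
                    _adapter_5p=config.adapter_5p,
                    _adapter_3p=config.adapter_3p,
                )
            )
            m += 1
    return out


def fusion_parts(
    annotation: ToyAnnotation, pair: FusionPairDesign
) -> tuple[str, str, tuple[int, int]]:
    """(5' partner segment, 3' partner segment, genomic breakpoints).

    The breakpoint sits at annotated exon boundaries: the donor keeps its
    first half of exons, the acceptor its last half.
    """
    iso_a = annotation.isoforms_of_gene(pair.gene_a)[0]
    iso_b = annotation.isoforms_of_gene(pair.gene_b)[0]
    ka = max(1, len(iso_a.exons) // 2)
    kb = len(iso_b.exons) - max(1, len(iso_b.exons) // 2)
    ga = annotation.genes[pair.gene_a]
    gb = annotation.genes[pair.gene_b]
    chrom_a = annotation.chromosomes[ga.chrom]
    chrom_b = annotation.chromosomes[gb.chrom]
    # toy genes are laid out on '+' for fusion designs
    part_a = "".join(chrom_a[s:e] for s, e in iso_a.exons[:ka])
    part_b = "".join(chrom_b[s:e] for s, e in iso_b.exons[kb:])
    return part_a, part_b, (iso_a.exons[ka - 1][1], iso_b.exons[kb][0])


# ---------------------------------------------------------------------------
# fragmentation into short reads
# ---------------------------------------------------------------------------


def _inject_errors(
    seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float
) -> str:
    if sub == 0 and ins == 0 and dele == 0:
        return seq
    a = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(a)
    r = rng.random((3, n))
    sub_idx = np.nonzero(r[0] < sub)[0]
    if sub_idx.size:
        cur = np.searchsorted(_BASE_ARR, a[sub_idx])
        shift = rng.integers(1, 4, size=sub_idx.size)
        a[sub_idx] = _BASE_ARR[(cur + shift) % 4]
    keep = r[1] >= dele
    ins_idx = np.nonzero(r[2] < ins)[0]
    if ins_idx.size == 0:
        return a[keep].tobytes().decode()
    parts = []
    prev = 0
    for i in ins_idx:
        parts.append(a[prev:i][keep[prev:i]])
        parts.append(_BASE_ARR[rng.integers(0, 4, size=1)])
        prev = i
    parts.append(a[prev:][keep[prev:]])
    return np.concatenate(parts).tobytes().decode()


def fragment_to_short_reads(
    molecules: list[BarcodedMolecule],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimShortRead]:
    """Shear each molecule into reads with approximately uniform start
    positions (the coverage-uniformity property the SLR error model relies
    on); ends are covered by clipped fragments.  Per-base errors are injected
    at the configured rates."""
    if config.coverage_depth <= 0:
        raise SimConfigError("coverage depth must be positive")
    rng = rng if rng is not None else config.rng(5)
    R = config.read_length
    shortest = min((len(m.sequence) for m in molecules), default=R)
    if R > shortest:
        raise SimConfigError(
            f"read length {R} exceeds shortest molecule length {shortest}"
        )
    qual_char = chr(33 + config.base_quality)
    reads: list[SimShortRead] = []
    for mol in molecules:
        seq = mol.sequence
        L = len(seq)
        n = int(round(config.coverage_depth * (L + R - 1) / R))
        starts = rng.integers(-(R - 1), L, size=n)
        flip = rng.random(n) < 0.5
        for t, (s, fl) in enumerate(zip(starts, flip)):
            s0 = max(0, int(s))
            frag = seq[s0 : int(s) + R]
            if len(frag) < config.min_fragment_length:
                continue
            frag = _inject_errors(
                frag, rng, config.sub_rate, config.ins_rate, config.del_rate
            )
            if len(frag) < config.min_fragment_length:
                continue
            strand = "-" if fl else "+"
            if fl:
                frag = revcomp(frag)
            reads.append(
                SimShortRead(
                    read_id=f"{mol.molecule_id}.R{t}",
                    molecule_id=mol.molecule_id,
                    umi=mol.umi,
                    sample_index=mol.sample_index,
                    sequence=frag,
                    quality=qual_char * len(frag),
                    offset=s0,
                    strand=strand,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# dataset orchestration + writers
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    config: SimConfig
    annotation: ToyAnnotation
    molecules: list[BarcodedMolecule]
    reads: list[SimShortRead]


def simulate_dataset(
    config: SimConfig,
    out_dir: str | None = None,
    fusion_molecules_per_pair: int = 0,
) -> SimResult:
    """Run annotation → molecules → chimeras → reads; optionally write files."""
    config.validate()
    ann = build_toy_annotation(config)
    mols = sample_molecules(ann, config)
    mols = inject_chimeras(mols, config)
    if fusion_molecules_per_pair and ann.fusion_pairs:
        mols = mols + sample_fusion_molecules(
            ann, config, fusion_molecules_per_pair
        )
    reads = fragment_to_short_reads(mols, config)
    res = SimResult(config, ann, mols, reads)
    if out_dir is not None:
        write_dataset(res, out_dir)
    return res


def write_dataset(res: SimResult, out_dir: str) -> dict[str, str]:
    import os

    from . import io as sio

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "reads": os.path.join(out_dir, "reads.fastq"),
        "references": os.path.join(out_dir, "references.fasta"),
        "genome": os.path.join(out_dir, "genome.fasta"),
        "annotation": os.path.join(out_dir, "annotation.gtf"),
        "targets": os.path.join(out_dir, "targets.bed"),
        "truth": os.path.join(out_dir, "truth_molecules.tsv"),
    }
    sio.write_fastq(
        paths["reads"],
        ((r.header, r.sequence, r.quality) for r in res.reads),
    )
    ann = res.annotation
    sio.write_fasta(
        paths["references"],
        ((i, ann.spliced_sequence(i)) for i in sorted(ann.isoforms)),
    )
    sio.write_fasta(paths["genome"], sorted(ann.chromosomes.items()))
    ann.to_gtf(paths["annotation"])
    with open(paths["targets"], "w") as fh:
        for gid in sorted(ann.genes):
            for iso in ann.isoforms_of_gene(gid):
                for s, e in iso.exons:
                    fh.write(f"{ann.genes[gid].chrom}\t{s}\t{e}\t{gid}\n")
    write_truth_table(res.molecules, paths["truth"])
    if ann.fusion_pairs:
        paths["fusions"] = os.path.join(out_dir, "fusion_table.tsv")
        write_fusion_table(ann, paths["fusions"])
    return paths


def write_truth_table(molecules: list[BarcodedMolecule], path: str) -> None:
    cols = (
        "molecule_id\tumi\tsample_index\tisoform_id\tinsert_length\t"
        "adapter_5p\tadapter_3p\tpremature_offset\ttts_offset\tchimera\t"
        "chimera_partner\tchimera_partner_isoform\tchimera_junction\tfusion_id\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for m in molecules:
            fh.write(
                f"{m.molecule_id}\t{m.umi}\t{m.sample_index}\t{m.isoform_id}\t"
                f"{len(m.insert)}\t{int(m.adapter_5p_present)}\t"
                f"{int(m.adapter_3p_present)}\t{m.premature_offset}\t"
                f"{m.tts_offset}\t{m.chimera}\t{m.chimera_partner or '.'}\t"
                f"{m.chimera_partner_isoform or '.'}\t"
                f"{'.' if m.chimera_junction is None else m.chimera_junction}\t"
                f"{m.fusion_id or '.'}\n"
            )


def write_fusion_table(annotation: ToyAnnotation, path: str, flank: int = 50) -> None:
    """Designed-fusion library: partner genes, 50+50 nt junction flanks and
    genomic breakpoints, in the TSV dialect the fusion stage consumes."""
    with open(path, "w") as fh:
        fh.write(
            "fusion_id\tgene_a\tgene_b\tchrom_a\tbreak_a\tchrom_b\tbreak_b\tflank\n"
        )
        for pair in annotation.fusion_pairs:
            part_a, part_b, (ba, bb) = fusion_parts(annotation, pair)
            fl = part_a[-flank:] + part_b[:flank]
            ga = annotation.genes[pair.gene_a]
            gb = annotation.genes[pair.gene_b]
            fh.write(
                f"{pair.gene_a}-{pair.gene_b}\t{pair.gene_a}\t{pair.gene_b}\t"
                f"{ga.chrom}\t{ba}\t{gb.chrom}\t{bb}\t{fl}\n"
            )
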