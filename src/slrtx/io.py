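"""Sequence-file I/O helpers (Biopython-backed)."""
from __future__ import annotations

from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    recs = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    )
    SeqIO.write(recs, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fastq(path: str, records: Iterable[tuple[str, str, str]]) -> None:
    """records: (header, sequence, Phred+33 quality string)."""
    with open(path, "w") as fh:
        for header, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"{header}: sequence/quality length mismatch")
            fh.write(f"@{header}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (full header, sequence, quality string)."""
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        yield rec.description, str(rec.seq), qual


def read_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {ln}: {line!r}") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}: malformed BED line {ln}: {line!r}")
            out.append((chrom, start, end))
    return out
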