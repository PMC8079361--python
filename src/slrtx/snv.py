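"""Isoform-resolved single-nucleotide-variant analysis.

Wild-type and alternate contig counts are tallied per (variant, isoform,
sample); the SNV rate is alt / (alt + wt).  Three screens follow:

* ``uneven``   — chi-squared goodness-of-fit of the ALT counts across a
  variant's isoforms against the isoforms' overall (WT+ALT) usage shares,
  restricted to variants seen on >1 isoform with >=5 supporting contigs;
* ``shift``    — exact 2xk Fisher test of WT vs ALT counts across isoforms;
* ``switching``— (variant, isoform) pairs whose SNV rate is uniformly >= 0.5
  in every sample of one group and < 0.5 in every sample of the other.

BH adjustment is applied within each tested family at FDR 5%.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import align_pair
from .annotation import COMPLEMENT, ToyAnnotation
from .stats import bh_adjust, fisher_exact_2xk


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based genomic
    ref: str
    alt: str
    gene_id: str = "."
    effect: str = "."
    validated: bool = True

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.key}: single-nucleotide variants only")
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: reference equals alternate")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


def read_variants(path: str) -> list[VariantSite]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.upper(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        out.append(
            VariantSite(
                chrom=row[cols["CHROM"]],
                pos=int(row[cols["POS"]]),
                ref=row[cols["REF"]],
                alt=row[cols["ALT"]],
                gene_id=row.get(cols.get("GENE", ""), "."),
                effect=row.get(cols.get("EFFECT", ""), "."),
                validated=str(row.get(cols.get("VALIDATED", ""), "1")) in ("1", "True", "true"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


def pileup_by_isoform(
    contigs_by_sample: dict[str, list[tuple[str, str, str]]],
    variants: list[VariantSite],
    annotation: ToyAnnotation,
) -> pd.DataFrame:
    """Tidy matrix of per (variant, isoform, sample) WT/ALT contig counts.

    `contigs_by_sample` maps sample -> [(contig_id, isoform_id, insert)].
    Each contig is aligned to its assigned isoform's spliced reference; the
    base at the variant's transcript coordinate is extracted strand-aware
    (complemented back to genome sense for '-' genes).  Contigs carrying a
    third base, or not covering the site, count in neither column.
    """
    refs = {i: annotation.spliced_sequence(i) for i in annotation.isoforms}
    rows = []
    for sample in sorted(contigs_by_sample):
        by_iso: dict[str, list[tuple[str, str]]] = {}
        for cid, iso, seq in contigs_by_sample[sample]:
            by_iso.setdefault(iso, []).append((cid, seq))
        for var in variants:
            for iso_id, members in sorted(by_iso.items()):
                iso = annotation.isoforms.get(iso_id)
                if iso is None:
                    continue
                gene = annotation.genes[iso.gene_id]
                if gene.chrom != var.chrom:
                    continue
                t = annotation.transcript_position(iso_id, var.pos - 1)
                if t is None:
                    continue
                wt = alt = 0
                for cid, seq in members:
                    rec = align_pair(cid, seq, iso_id, refs[iso_id])
                    q = seq if rec.strand == "+" else seq.translate(COMPLEMENT)[::-1]
                    qi = rec.query_index_at(t)
                    if qi is None:
                        continue
                    base = q[qi]
                    if gene.strand == "-":
                        base = base.translate(COMPLEMENT)
                    if base == var.ref:
                        wt += 1
                    elif base == var.alt:
                        alt += 1
                rows.append((var.key, iso_id, sample, wt, alt))
    df = pd.DataFrame(rows, columns=["variant", "isoform", "sample", "wt", "alt"])
    # keep (variant, isoform) pairs with any coverage in any sample
    tot = df.groupby(["variant", "isoform"])[["wt", "alt"]].transform("sum").sum(axis=1)
    df = df[tot > 0].reset_index(drop=True)
    df["rate"] = df["alt"] / (df["wt"] + df["alt"]).replace(0, np.nan)
    return df


def zero_count_rows(variants: list[VariantSite], annotation: ToyAnnotation) -> list[str]:
    """Variants on chromosomes absent from the annotation (flagged)."""
    return [
        v.key for v in variants if v.chrom not in annotation.chromosomes
    ]


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------


def test_uneven_distribution(
    matrix: pd.DataFrame,
    min_isoforms: int = 2,
    min_contigs: int = 5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Chi-squared screen for ALT counts concentrated in specific isoforms.

    Counts are pooled over samples.  Expected ALT proportions follow each
    isoform's share of the variant's total (WT+ALT) contigs; isoforms with a
    zero expected count are pooled into the neighbouring isoform with the
    closest total.  Variants on fewer than `min_isoforms` isoforms or with
    fewer than `min_contigs` contigs are excluded, not tested.
    """
    pooled = matrix.groupby(["variant", "isoform"])[["wt", "alt"]].sum().reset_index()
    rows = []
    for var, sub in pooled.groupby("variant"):
        sub = sub[(sub["wt"] + sub["alt"]) > 0]
        total = int((sub["wt"] + sub["alt"]).sum())
        if len(sub) < min_isoforms or total < min_contigs:
            continue
        alt = sub["alt"].to_numpy(dtype=float)
        tot = (sub["wt"] + sub["alt"]).to_numpy(dtype=float)
        n_alt = alt.sum()
        if n_alt == 0:
            continue
        p = tot / tot.sum()
        # pool zero-expected cells into the nearest neighbour by total count
        while (n_alt * p < 1e-12).any() and len(p) > 1:
            i = int(np.argmin(p))
            j = int(np.argmin(np.abs(np.delete(tot, i) - tot[i])))
            j = j if j < i else j + 1
            alt[j] += alt[i]
            tot[j] += tot[i]
            alt, tot = np.delete(alt, i), np.delete(tot, i)
            p = tot / tot.sum()
        stat, pval = sps.chisquare(alt, f_exp=n_alt * p)
        rows.append((var, "uneven", float(stat), float(pval), len(sub), total))
    res = pd.DataFrame(
        rows, columns=["variant", "test", "statistic", "pvalue", "n_isoforms", "n_contigs"]
    )
    res["padj"] = bh_adjust(res["pvalue"]) if len(res) else []
    res["verdict"] = res["padj"] <= fdr if len(res) else []
    return res


def test_distribution_shift(matrix: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Exact 2xk Fisher screen for SNV isoform distributions that differ
    from their wild-type counterparts (counts pooled over samples)."""
    pooled = matrix.groupby(["variant", "isoform"])[["wt", "alt"]].sum().reset_index()
    rows = []
    for var, sub in pooled.groupby("variant"):
        sub = sub[(sub["wt"] + sub["alt"]) > 0]
        if len(sub) < 2:
            continue
        table = np.vstack([sub["wt"].to_numpy(), sub["alt"].to_numpy()])
        pval = fisher_exact_2xk(table)
        rows.append((var, "shift", float("nan"), float(pval), len(sub), int(table.sum())))
    res = pd.DataFrame(
        rows, columns=["variant", "test", "statistic", "pvalue", "n_isoforms", "n_contigs"]
    )
    res["padj"] = bh_adjust(res["pvalue"]) if len(res) else []
    res["verdict"] = res["padj"] <= fdr if len(res) else []
    return res


def screen_switching(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """(variant, isoform) pairs with SNV rate uniformly >= threshold in every
    sample of one group and < threshold (strict) in the other.

    Pairs with an undefined rate (no covering contigs) in any sample are
    excluded with a reason.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    missing = set(matrix["sample"]) - set(groups)
    if missing:
        raise ValueError(f"unlabelled samples: {sorted(missing)}")
    rows = []
    for (var, iso), sub in matrix.groupby(["variant", "isoform"]):
        rates = sub.set_index("sample")["rate"]
        rates = rates.reindex(sorted(groups))
        if rates.isna().any():
            rows.append((var, iso, "excluded", "undefined rate in some sample", ""))
            continue
        hi = {g: (rates[[s for s in rates.index if groups[s] == g]] >= threshold).all() for g in labels}
        lo = {g: (rates[[s for s in rates.index if groups[s] == g]] < threshold).all() for g in labels}
        if hi[labels[0]] and lo[labels[1]]:
            rows.append((var, iso, "switching", "", f"high-in-{labels[0]}"))
        elif hi[labels[1]] and lo[labels[0]]:
            rows.append((var, iso, "switching", "", f"high-in-{labels[1]}"))
        else:
            rows.append((var, iso, "not-switching", "", ""))
    return pd.DataFrame(
        rows, columns=["variant", "isoform", "verdict", "reason", "direction"]
    )


def crossref_catalogue(
    variants: list[VariantSite], catalogue: pd.DataFrame
) -> tuple[set[str], int]:
    """Exact-key (chrom, pos, ref, alt) intersection with an external
    catalogue table; duplicate catalogue rows count once."""
    keys = set()
    for _, row in catalogue.iterrows():
        try:
            keys.add((str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"])))
        except (KeyError, ValueError, TypeError):
            warnings.warn(f"skipping malformed catalogue row: {dict(row)}")
    flagged = {
        v.key for v in variants if (v.chrom, v.pos, v.ref, v.alt) in keys
    }
    return flagged, len(flagged)
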