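"""Isoform-resolved SNV counting and the three statistical screens."""
import math

import numpy as np
import pandas as pd
import pytest

from slrtx.annotation import Gene, Isoform, ToyAnnotation
from slrtx.snv import (
    VariantSite,
    crossref_catalogue,
    pileup_by_isoform,
    screen_switching,
    zero_count_rows,
)
from slrtx.snv import test_distribution_shift as shift_screen
from slrtx.snv import test_uneven_distribution as uneven_screen


def _rand(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def snv_world():
    chrom = _rand(1200, 41)
    ann = ToyAnnotation(
        {"chr1": chrom},
        {"G": Gene("G", "chr1", "+", 100, 1100)},
        {
            "G.I1": Isoform("G.I1", "G", [(100, 400), (600, 1100)]),
            "G.I2": Isoform("G.I2", "G", [(100, 400), (800, 1100)]),
        },
    )
    # variant inside the shared first exon, genomic pos (1-based) 251
    ref_base = chrom[250]
    alt_base = "A" if ref_base != "A" else "G"
    var = VariantSite("chr1", 251, ref_base, alt_base, "G")
    return ann, var


def _mutate(seq, t, base):
    return seq[:t] + base + seq[t + 1 :]


class TestVariantSite:
    def test_multi_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            VariantSite("chr1", 5, "AT", "A")

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError):
            VariantSite("chr1", 5, "C", "C")


class TestPileup:
    def test_constructed_seven_wt_three_alt(self, snv_world):
        ann, var = snv_world
        seq = ann.spliced_sequence("G.I1")
        t = ann.transcript_position("G.I1", var.pos - 1)
        contigs = [(f"w{i}", "G.I1", seq) for i in range(7)] + [
            (f"a{i}", "G.I1", _mutate(seq, t, var.alt)) for i in range(3)
        ]
        mat = pileup_by_isoform({"S1": contigs}, [var], ann)
        row = mat.set_index("isoform").loc["G.I1"]
        assert (row.wt, row.alt) == (7, 3)
        assert row.rate == pytest.approx(0.3)

    def test_third_base_counts_in_neither_column(self, snv_world):
        ann, var = snv_world
        seq = ann.spliced_sequence("G.I1")
        t = ann.transcript_position("G.I1", var.pos - 1)
        third = next(b for b in "ACGT" if b not in (var.ref, var.alt))
        contigs = [("c1", "G.I1", seq), ("c2", "G.I1", _mutate(seq, t, third))]
        mat = pileup_by_isoform({"S1": contigs}, [var], ann)
        row = mat.set_index("isoform").loc["G.I1"]
        assert (row.wt, row.alt) == (1, 0)

    def test_no_covering_contig_gives_no_defined_rate(self, snv_world):
        ann, var = snv_world
        # variant in I1's private exon region is invisible to I2 contigs
        chrom = ann.chromosomes["chr1"]
        private = VariantSite(
            "chr1", 651, chrom[650], "A" if chrom[650] != "A" else "G", "G"
        )
        contigs = [("c1", "G.I2", ann.spliced_sequence("G.I2"))]
        mat = pileup_by_isoform({"S1": contigs}, [private], ann)
        assert mat.empty

    def test_count_conservation_never_exceeds_coverage(self, snv_world):
        ann, var = snv_world
        seq = ann.spliced_sequence("G.I1")
        t = ann.transcript_position("G.I1", var.pos - 1)
        rng = np.random.default_rng(5)
        contigs = []
        for i in range(30):
            b = "ACGT"[int(rng.integers(4))]
            contigs.append((f"c{i}", "G.I1", _mutate(seq, t, b)))
        mat = pileup_by_isoform({"S1": contigs}, [var], ann)
        assert (mat["wt"] + mat["alt"]).sum() <= 30

    def test_variant_on_absent_chromosome_flagged(self, snv_world):
        ann, _ = snv_world
        off = VariantSite("chrX", 5, "A", "C")
        assert zero_count_rows([off], ann) == [off.key]

    def test_minus_strand_gene_extracts_genome_sense_base(self):
        chrom = _rand(600, 42)
        ann = ToyAnnotation(
            {"chr1": chrom},
            {"N": Gene("N", "chr1", "-", 100, 500)},
            {"N.I1": Isoform("N.I1", "N", [(100, 500)])},
        )
        pos0 = 250
        var = VariantSite(
            "chr1", pos0 + 1, chrom[pos0], "A" if chrom[pos0] != "A" else "G", "N"
        )
        seq = ann.spliced_sequence("N.I1")  # reverse complement of the locus
        mat = pileup_by_isoform({"S1": [("c", "N.I1", seq)]}, [var], ann)
        row = mat.iloc[0]
        assert (row.wt, row.alt) == (1, 0)


def _matrix(rows):
    return pd.DataFrame(rows, columns=["variant", "isoform", "sample", "wt", "alt"]).assign(
        rate=lambda d: d.alt / (d.wt + d.alt).replace(0, np.nan)
    )


class TestUnevenScreen:
    def test_single_isoform_variant_excluded(self):
        mat = _matrix([("v1", "i1", "S1", 10, 10)])
        assert uneven_screen(mat).empty

    def test_below_contig_floor_excluded(self):
        mat = _matrix([("v1", "i1", "S1", 1, 1), ("v1", "i2", "S1", 1, 1)])
        assert uneven_screen(mat).empty

    def test_balanced_alt_counts_give_null_statistic(self):
        mat = _matrix([("v1", "i1", "S1", 5, 5), ("v1", "i2", "S1", 5, 5)])
        res = uneven_screen(mat)
        assert res.iloc[0].statistic == pytest.approx(0.0)
        assert res.iloc[0].pvalue == pytest.approx(1.0)

    def test_concentrated_alt_flagged(self):
        mat = _matrix([("v1", "i1", "S1", 30, 40), ("v1", "i2", "S1", 30, 0)])
        res = uneven_screen(mat)
        assert bool(res.iloc[0].verdict)

    def test_type_i_error_under_proportional_null(self):
        """ALT drawn proportionally to isoform usage: rejections near 5%."""
        rng = np.random.default_rng(99)
        rows = []
        tot = np.array([120, 80])
        p = tot / tot.sum()
        n_var = 1000
        for v in range(n_var):
            alt = rng.multinomial(60, p)
            for i, (t, a) in enumerate(zip(tot, alt)):
                rows.append((f"v{v}", f"i{i}", "S1", int(t - a), int(a)))
        res = uneven_screen(_matrix(rows))
        raw = (res["pvalue"] <= 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / n_var)
        assert abs(raw - 0.05) <= 3 * se
        # BH keeps the false-discovery count at or near zero under the null
        assert res["verdict"].sum() <= 0.05 * n_var


class TestShiftScreen:
    def test_matches_enumeration_oracle(self):
        mat = _matrix([("v1", "i1", "S1", 10, 0), ("v1", "i2", "S1", 0, 10)])
        res = shift_screen(mat)
        assert res.iloc[0].pvalue == pytest.approx(2 / 184756)

    def test_proportional_counts_give_p_one(self):
        mat = _matrix([("v1", "i1", "S1", 8, 4), ("v1", "i2", "S1", 4, 2)])
        res = shift_screen(mat)
        assert res.iloc[0].pvalue == 1.0

    def test_single_isoform_not_tested(self):
        mat = _matrix([("v1", "i1", "S1", 10, 10)])
        assert shift_screen(mat).empty


class TestSwitchingScreen:
    GROUPS = {"M1": "M", "M2": "M", "M3": "M", "T1": "T", "T2": "T", "T3": "T"}

    def _rows(self, m_rates, t_rates, n=20):
        rows = []
        for s, r in zip(("M1", "M2", "M3"), m_rates):
            rows.append(("v", "i", s, int(n * (1 - r)), int(n * r)))
        for s, r in zip(("T1", "T2", "T3"), t_rates):
            rows.append(("v", "i", s, int(n * (1 - r)), int(n * r)))
        return _matrix(rows)

    def test_uniform_high_vs_low_is_switching(self):
        res = screen_switching(self._rows((0.8, 0.7, 0.9), (0.1, 0.0, 0.2)), self.GROUPS)
        assert res.iloc[0].verdict == "switching"
        assert res.iloc[0].direction == "high-in-M"

    def test_non_uniform_group_is_not_switching(self):
        res = screen_switching(self._rows((0.8, 0.3, 0.9), (0.1, 0.0, 0.2)), self.GROUPS)
        assert res.iloc[0].verdict == "not-switching"

    def test_exact_half_in_low_group_fails_strict_rule(self):
        res = screen_switching(self._rows((0.8, 0.7, 0.9), (0.5, 0.0, 0.2)), self.GROUPS)
        assert res.iloc[0].verdict == "not-switching"

    def test_exact_half_in_high_group_passes(self):
        res = screen_switching(self._rows((0.5, 0.7, 0.9), (0.1, 0.0, 0.2)), self.GROUPS)
        assert res.iloc[0].verdict == "switching"

    def test_undefined_rate_excluded_with_reason(self):
        mat = self._rows((0.8, 0.7, 0.9), (0.1, 0.0, 0.2))
        mat.loc[mat["sample"] == "T3", ["wt", "alt", "rate"]] = [0, 0, np.nan]
        res = screen_switching(mat, self.GROUPS)
        assert res.iloc[0].verdict == "excluded"
        assert "undefined" in res.iloc[0].reason

    def test_recall_on_simulated_rate_flips(self):
        """0.9-vs-0.1 flips with binomial n=20 counts: recall >= 0.9."""
        rng = np.random.default_rng(17)
        rows = []
        n_pairs = 60
        for v in range(n_pairs):
            hi_group = "M" if v % 2 == 0 else "T"
            for s, g in self.GROUPS.items():
                r = 0.9 if g == hi_group else 0.1
                alt = int(rng.binomial(20, r))
                rows.append((f"v{v}", "i", s, 20 - alt, alt))
        res = screen_switching(_matrix(rows), self.GROUPS)
        recall = (res.verdict == "switching").mean()
        assert recall >= 0.9

    def test_unlabelled_sample_is_error(self):
        mat = self._rows((0.8, 0.7, 0.9), (0.1, 0.0, 0.2))
        with pytest.raises(ValueError, match="unlabelled"):
            screen_switching(mat, {k: v for k, v in self.GROUPS.items() if k != "T3"})


class TestCrossref:
    VARS = [
        VariantSite("chr1", p, "A", "C") for p in (10, 20, 30, 40, 50)
    ]

    def test_empty_catalogue_flags_nothing(self):
        cat = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        flagged, n = crossref_catalogue(self.VARS, cat)
        assert n == 0

    def test_three_of_five_intersect(self):
        cat = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [10, 30, 50], "ref": ["A"] * 3, "alt": ["C"] * 3}
        )
        flagged, n = crossref_catalogue(self.VARS, cat)
        assert n == 3
        assert flagged == {"chr1:10A>C", "chr1:30A>C", "chr1:50A>C"}

    def test_duplicate_rows_do_not_double_count(self):
        cat = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [10, 10], "ref": ["A", "A"], "alt": ["C", "C"]}
        )
        _, n = crossref_catalogue(self.VARS, cat)
        assert n == 1

    def test_malformed_row_skipped_with_warning(self):
        cat = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": ["nope", 20], "ref": ["A", "A"], "alt": ["C", "C"]}
        )
        with pytest.warns(UserWarning, match="malformed"):
            _, n = crossref_catalogue(self.VARS, cat)
        assert n == 1
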