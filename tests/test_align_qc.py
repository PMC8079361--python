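"""Alignment records, error profiling, termini, chimeras, abundance, on-target."""
import math

import numpy as np
import pandas as pd
import pytest

from slrtx.align import align_pair, align_to_reference
from slrtx.annotation import revcomp
from slrtx.qc import (
    compare_abundance,
    compute_on_target,
    detect_chimeras,
    homopolymer_mask,
    indel_reciprocal,
    positional_bias,
    profile_errors,
    summary_from_rates,
    terminus_offsets,
)


def _rand(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


class TestAlignment:
    def test_identical_query_is_all_match_full_span(self):
        ref = _rand(300, 1)
        rec = align_pair("q", ref, "r", ref)
        assert rec.ops == [("=", 300)]
        assert (rec.ref_start, rec.ref_end, rec.strand) == (0, 300, "+")

    def test_single_substitution_gives_one_mismatch_column(self):
        ref = _rand(200, 2)
        q = ref[:100] + ("A" if ref[100] != "A" else "C") + ref[101:]
        rec = align_pair("q", q, "r", ref)
        assert rec.counts() == {"=": 199, "X": 1, "I": 0, "D": 0}

    def test_reverse_complement_maps_to_minus_strand_same_operations(self):
        ref = _rand(250, 3)
        rec = align_pair("q", revcomp(ref), "r", ref)
        assert rec.strand == "-"
        assert rec.ops == [("=", 250)]

    def test_best_reference_chosen_and_unalignable_reported(self):
        refs = {"a": _rand(300, 4), "b": _rand(300, 5)}
        queries = {"qa": refs["a"][20:280], "junk": _rand(260, 6)}
        records, unaligned = align_to_reference(queries, refs, max_divergence=0.2)
        assert [r.ref_id for r in records] == ["a"]
        assert unaligned == ["junk"]

    def test_empty_reference_set_is_an_error(self):
        with pytest.raises(ValueError):
            align_to_reference({"q": "ACGT"}, {})

    def test_query_index_lookup_across_indels(self):
        ref = _rand(100, 7)
        q = ref[:40] + ref[50:]  # 10 nt deletion
        rec = align_pair("q", q, "r", ref)
        # aligned columns map onto identical bases; deleted columns map to None
        rc = rec.ref_start
        for op, n in rec.ops:
            if op in "=X":
                for p in range(rc, rc + n):
                    qi = rec.query_index_at(p)
                    assert q[qi] == ref[p]
                rc += n
            elif op == "D":
                for p in range(rc, rc + n):
                    assert rec.query_index_at(p) is None
                rc += n
        assert rec.query_index_at(10) == 10


class TestErrorProfile:
    def test_identical_sequences_all_match(self):
        ref = _rand(400, 8)
        prof = profile_errors([align_pair("q", ref, "r", ref)], {"r": 400})
        s = prof.summary()
        assert s["substitution"] == s["insertion"] == s["deletion"] == 0
        assert s["match"] == 1.0

    def test_one_substitution_in_1000_bases(self):
        ref = _rand(1000, 9)
        q = ref[:500] + ("G" if ref[500] != "G" else "T") + ref[501:]
        prof = profile_errors([align_pair("q", q, "r", ref)], {"r": 1000})
        assert prof.summary()["substitution"] == pytest.approx(1e-3)

    def test_platform_table_rate_identity(self):
        """The summed per-type rates reproduce the printed sum error and the
        match = 1 - sum convention."""
        s = summary_from_rates(3.475e-4, 2.060e-4, 2.691e-4)
        assert s["sum_error"] == pytest.approx(8.226e-4)
        assert round(s["match"], 4) == 0.9992
        assert s["match"] + s["substitution"] + s["insertion"] + s["deletion"] == pytest.approx(1.0)

    def test_indel_reciprocal_matches_printed_dna_row(self):
        assert round(indel_reciprocal(2.148e-6, 2.387e-6), -4) == 220_000

    def test_recovers_injected_substitution_rate(self):
        """Profiled substitution rate within 3 binomial SE of the injected one."""
        rng = np.random.default_rng(10)
        ref = _rand(2000, 11)
        rate = 0.01
        recs = []
        n_bases = 0
        for i in range(50):
            q = list(ref)
            hits = np.nonzero(rng.random(len(q)) < rate)[0]
            for h in hits:
                q[h] = "ACGT"[("ACGT".index(q[h]) + 1 + int(rng.integers(3))) % 4]
            recs.append(align_pair(f"q{i}", "".join(q), "r", ref))
            n_bases += len(q)
        got = profile_errors(recs, {"r": 2000}).summary()["substitution"]
        se = math.sqrt(rate * (1 - rate) / n_bases)
        assert abs(got - rate) <= 3 * se


class TestPositionalBias:
    def test_uniform_errors_give_ratios_near_one(self):
        rng = np.random.default_rng(12)
        ref = _rand(500, 13)
        recs = []
        for i in range(400):
            q = list(ref)
            for h in np.nonzero(rng.random(len(q)) < 0.02)[0]:
                q[h] = "ACGT"[("ACGT".index(q[h]) + 1) % 4]
            recs.append(align_pair(f"q{i}", "".join(q), "r", ref))
        prof = profile_errors(recs, {"r": 500})
        df = positional_bias(prof, "r", ref, "substitution")
        assert df["ratio"].mean() == pytest.approx(1.0, abs=0.05)

    def test_all_insertions_at_one_position_degenerate_ratio(self):
        ref = _rand(100, 14)
        q = ref[:50] + "A" + ref[50:]
        prof = profile_errors([align_pair("q", q, "r", ref)], {"r": 100})
        df = positional_bias(prof, "r", ref, "insertion")
        nz = df[df["count"] > 0]
        assert len(nz) == 1
        # positional rate 1/1 over overall rate 1/101 = reference-scale ratio
        assert nz["ratio"].iloc[0] == pytest.approx(101.0)
        assert (df.loc[df["count"] == 0, "ratio"] == 0).all()

    def test_zero_overall_rate_flagged(self):
        ref = _rand(100, 15)
        prof = profile_errors([align_pair("q", ref, "r", ref)], {"r": 100})
        df = positional_bias(prof, "r", ref, "deletion")
        assert df["undefined"].all()
        assert (df["ratio"] == 0).all()

    def test_homopolymer_run_of_seven_flagged(self):
        seq = _rand(60, 16) + "AAAAAAA" + _rand(60, 17)
        mask = homopolymer_mask(seq, 4)
        assert mask[60:67].all()
        run3 = "ACGCCCGTA"
        assert not homopolymer_mask(run3, 4).any()


class TestTerminusOffsets:
    def test_perfect_reconstruction_is_exact_bucket(self):
        ref = _rand(600, 18)
        to = terminus_offsets([align_pair("q", ref, "r", ref)], {"r": 600})
        row = to.per_contig.iloc[0]
        assert row.tss_offset == 0 and row.tts_offset == 0
        assert to.tss_buckets["exact"] == 1.0
        assert to.tts_buckets["exact"] == 1.0

    def test_premature_termination_lands_downstream_bucket(self):
        ref = _rand(600, 19)
        to = terminus_offsets([align_pair("q", ref[150:], "r", ref)], {"r": 600})
        assert to.per_contig.iloc[0].tss_offset == 150
        assert to.tss_buckets["gt100_downstream"] == 1.0

    def test_tts_mispriming_within_five(self):
        ref = _rand(600, 20)
        to = terminus_offsets([align_pair("q", ref[:-3], "r", ref)], {"r": 600})
        assert to.per_contig.iloc[0].tts_offset == -3
        assert to.tts_buckets["within_5"] == 1.0

    def test_unannotated_reference_excluded_with_warning(self):
        ref = _rand(300, 21)
        rec = align_pair("q", ref, "r", ref)
        with pytest.warns(UserWarning, match="not annotated"):
            to = terminus_offsets([rec], {"r": 300}, annotated=set())
        assert to.n == 0


class TestChimeraDetection:
    def _refs(self):
        return {"A": _rand(900, 22), "B": _rand(800, 23)}

    def test_clean_contig(self):
        refs = self._refs()
        rep = detect_chimeras({"c": refs["A"]}, refs)
        assert rep.verdicts.iloc[0].verdict == "clean"
        assert rep.n_flagged == 0

    def test_constructed_inter_chimera_recovers_partners(self):
        refs = self._refs()
        chim = refs["A"][:450] + refs["B"][400:]
        rep = detect_chimeras({"c": chim}, refs)
        row = rep.verdicts.iloc[0]
        assert row.verdict == "inter-molecular"
        assert {row.ref_5p, row.ref_3p} == {"A", "B"}

    def test_unmapped_end_flagged(self):
        refs = self._refs()
        chim = refs["A"][:450] + _rand(400, 24)
        rep = detect_chimeras({"c": chim}, refs)
        assert rep.verdicts.iloc[0].verdict == "unmapped-end"
        assert rep.n_flagged == 1

    def test_intra_molecular_rearrangement(self):
        refs = self._refs()
        # 3' window upstream of the 5' window on the same reference
        seq = refs["A"][500:900] + refs["A"][0:400]
        rep = detect_chimeras({"c": seq}, refs)
        assert rep.verdicts.iloc[0].verdict == "intra-molecular"

    def test_window_shrunk_with_warning_for_short_contig(self):
        refs = self._refs()
        with pytest.warns(UserWarning, match="shrunk"):
            detect_chimeras({"c": refs["A"][:150]}, refs, end_window=100)

    def test_printed_rate_arithmetic(self):
        """120 flagged of 6,803 classified contigs rounds to 1.8%."""
        from slrtx.qc import ChimeraReport

        rep = ChimeraReport(verdicts=pd.DataFrame(), n_flagged=120, n_total=6803)
        assert rep.rate_percent == 1.8


class TestAbundance:
    def _expected(self, n=10, seed=25):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "id": [f"t{i}" for i in range(n)],
                "expected": np.exp(rng.uniform(0, 6, n)),
                "length": rng.integers(300, 2000, n),
            }
        )

    def test_proportional_observed_gives_r_one(self):
        exp = self._expected()
        obs = {row.id: int(round(row.expected * 10)) for row in exp.itertuples()}
        cmp_ = compare_abundance(obs, exp)
        assert cmp_.r_all == pytest.approx(1.0, abs=0.01)

    def test_min_length_filter_restricts_the_set(self):
        exp = self._expected()
        obs = {row.id: int(round(row.expected * 5)) for row in exp.itertuples()}
        cmp_ = compare_abundance(obs, exp, min_length=700)
        kept = exp[exp["length"] >= 700]
        assert len(cmp_.table[cmp_.table["length"] >= 700]) == len(kept)
        assert set(kept["id"]).issubset(set(cmp_.table["id"]))

    def test_multinomial_sampling_oracle(self):
        """r on sampled counts within 0.02 of the resampling-oracle value."""
        exp = self._expected(20, seed=26)
        p = exp["expected"] / exp["expected"].sum()
        rng = np.random.default_rng(27)
        counts = rng.multinomial(20000, p)
        obs = dict(zip(exp["id"], (int(c) for c in counts)))
        cmp_ = compare_abundance(obs, exp)
        oracle = [
            np.corrcoef(
                np.log2(exp["expected"]),
                np.log2(rng.multinomial(20000, p) + 0.5),
            )[0, 1]
            for _ in range(50)
        ]
        assert abs(cmp_.r_all - np.mean(oracle)) <= 0.02

    def test_fewer_than_three_references_is_undefined(self):
        exp = self._expected(2)
        cmp_ = compare_abundance({}, exp)
        assert cmp_.r_all is None

    def test_dropouts_listed(self):
        exp = self._expected(5)
        obs = {"t0": 3, "t1": 1}
        cmp_ = compare_abundance(obs, exp)
        assert cmp_.dropouts == ["t2", "t3", "t4"]

    def test_nonpositive_expected_rejected(self):
        exp = self._expected(4)
        exp.loc[0, "expected"] = 0.0
        with pytest.raises(ValueError):
            compare_abundance({}, exp)


class TestOnTarget:
    def test_contigs_wholly_inside_targets(self):
        ref = _rand(500, 28)
        recs = [align_pair("q", ref[100:300], "r", ref)]
        out = compute_on_target(recs, [("r", 0, 500)])
        assert out["read_level"] == 1.0
        assert out["base_level"] == 1.0

    def test_half_covered_bases(self):
        ref = _rand(400, 29)
        recs = [align_pair("q", ref[0:200], "r", ref)]
        out = compute_on_target(recs, [("r", 0, 100)])
        assert out["base_level"] == pytest.approx(0.5)
        assert out["read_level"] == 1.0

    def test_empty_bed_zero_rates(self):
        ref = _rand(300, 30)
        recs = [align_pair("q", ref, "r", ref)]
        out = compute_on_target(recs, [])
        assert out["read_level"] == 0.0
        assert out["base_level"] == 0.0

    def test_malformed_bed_names_line_number(self, tmp_path):
        from slrtx.io import read_bed

        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t20\nchr1\tnope\t30\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(str(p))
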