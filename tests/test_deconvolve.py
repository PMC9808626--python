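"""Deconvolution: cycle classification, trimming, quality calibration."""

import itertools

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methylsnp as ms
from methylsnp.deconvolve import ILLUMINA_ADAPTER, PairClass

from conftest import simulate_library

Q37 = chr(37 + 33)


def pair(r1, r2, q1=None, q2=None, rid="r"):
    return ms.ReadPair(rid, r1, q1 or Q37 * len(r1), r2, q2 or Q37 * len(r2))


class TestClassifyPosition:
    def test_conversion_cases(self):
        assert ms.classify_position("T", "C") is PairClass.UNMETH_C
        assert ms.classify_position("C", "C") is PairClass.METH_C

    def test_partition_cases(self):
        assert ms.classify_position("A", "C") is PairClass.MISMATCH
        assert ms.classify_position("G", "G") is PairClass.AGREE
        assert ms.classify_position("N", "A") is PairClass.AMBIGUOUS

    def test_total_partition_over_all_25_combinations(self):
        tally = {cls: 0 for cls in PairClass}
        for b1, b2 in itertools.product("ACGTN", repeat=2):
            tally[ms.classify_position(b1, b2)] += 1
        assert tally == {
            PairClass.AMBIGUOUS: 9,
            PairClass.AGREE: 3,
            PairClass.METH_C: 1,
            PairClass.UNMETH_C: 1,
            PairClass.MISMATCH: 11,
        }


class TestDeconvolvePair:
    def test_toy_example(self):
        d = ms.deconvolve_pair(pair("TACGT", "CACGT"))
        assert d.sequence == "CACGT"
        assert d.methylation == "h.Z.."
        assert d.status == "deconvolved"

    def test_identity_on_c_free_mates(self):
        d = ms.deconvolve_pair(pair("AGTGA", "AGTGA"))
        assert d.sequence == "AGTGA"
        assert d.methylation == "....."
        assert d.quality == Q37 * 5

    def test_mismatch_quality_zero_reference_free(self):
        d = ms.deconvolve_pair(pair("AACGT", "ACCGT"))
        quals = [ord(c) - 33 for c in d.quality]
        assert quals[1] == 0
        assert quals[0] == quals[2] == 37

    def test_agree_quality_is_min_of_mates(self):
        d = ms.deconvolve_pair(pair("AA", "AA", q1="5I", q2="I5"))
        assert d.quality == "55"

    def test_ambiguous_gives_n_and_zero_quality(self):
        d = ms.deconvolve_pair(pair("ANA", "AAA"))
        assert d.sequence == "ANA"
        assert d.quality[1] == "!"
        assert d.methylation == "..."

    def test_rejection_above_mismatch_threshold(self):
        d = ms.deconvolve_pair(pair("AAAAAAGGGG", "AAAAAATTTT"))
        assert d.status == "rejected"
        ok = ms.deconvolve_pair(pair("AAAAAAAAAG", "AAAAAAAAAT"))
        assert ok.status == "deconvolved"

    def test_context_unknown_near_read_end(self):
        # C at the last two positions cannot see two downstream bases
        d = ms.deconvolve_pair(pair("TTTCT", "TTTCC"))
        assert d.methylation[3] == "U"  # methylated, context undeterminable
        assert d.methylation[4] == "u"  # converted, context undeterminable

    @settings(max_examples=200, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(5, 60),
    )
    def test_consistency_invariant_fuzz(self, seed, length):
        rng = np.random.default_rng(seed)
        r1 = "".join(rng.choice(list("ACGTN"), length))
        r2 = "".join(rng.choice(list("ACGTN"), length))
        d = ms.deconvolve_pair(pair(r1, r2), reject_frac=1.0)
        assert len(d.sequence) == len(d.quality) == len(d.methylation)
        for i, sym in enumerate(d.methylation):
            if sym != ".":
                assert d.sequence[i] == "C"
        assert sum(s != "." for s in d.methylation) == sum(
            1
            for b1, b2 in zip(r1, r2)
            if ms.classify_position(b1, b2)
            in (PairClass.METH_C, PairClass.UNMETH_C)
        )


class TestTrimming:
    def test_hairpin_adapter_is_46_nt(self):
        assert len(ms.HAIRPIN_ADAPTER) == 46

    def test_full_hairpin_suffix_removed(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 36 nt
        seq = insert + ms.HAIRPIN_ADAPTER
        p = ms.trim_pair("r", seq, "I" * len(seq), seq, "I" * len(seq))
        assert p is not None
        assert p.r1_seq == insert

    def test_converted_hairpin_removed_from_read1(self):
        insert = "AGGTAGGTAGGTAGGTAGGTAGGTAGGTAGGT"  # 32 nt, C-free
        conv = ms.HAIRPIN_ADAPTER.replace("C", "T")
        s1 = insert + conv
        s2 = insert + ms.HAIRPIN_ADAPTER
        p = ms.trim_pair("r", s1, "I" * len(s1), s2, "I" * len(s2))
        assert p is not None and p.r1_seq == insert and p.r2_seq == insert

    def test_no_adapter_leaves_read_unchanged(self):
        seq = "ACGT" * 20
        p = ms.trim_pair("r", seq, "I" * 80, seq, "I" * 80)
        assert p.r1_seq == seq

    def test_mates_truncated_to_shorter(self):
        s1 = "A" * 74 + ILLUMINA_ADAPTER  # trims to 74
        s2 = "A" * 80
        p = ms.trim_pair("r", s1, "I" * len(s1), s2, "I" * len(s2))
        assert len(p.r1_seq) == len(p.r2_seq) == 74

    def test_short_pairs_dropped(self):
        s = "A" * 20 + ms.HAIRPIN_ADAPTER
        assert ms.trim_pair("r", s, "I" * len(s), s, "I" * len(s)) is None

    def test_malformed_record_raises(self):
        with pytest.raises(ValueError, match="bad"):
            ms.trim_pair("bad", "ACGT", "II", "ACGT", "IIII")

    def test_partial_3prime_overlap_trimmed(self):
        seq = "G" * 70 + ms.HAIRPIN_ADAPTER[:6]
        p = ms.trim_pair("r", seq, "I" * 76, seq, "I" * 76)
        assert len(p.r1_seq) == 70


class TestCalibration:
    def test_posterior_closed_forms(self):
        t = ms.CalibrationTable()
        for _ in range(99):
            t.add("A", "A", "G", 5, success=True)
        assert t.posterior("A", "A", "G", 5) == pytest.approx(100 / 101)
        assert t.phred("A", "A", "G", 5) == 20

        t2 = ms.CalibrationTable()
        for _ in range(8):
            t2.add("G", "A", "C", 3, success=False)
        assert t2.posterior("G", "A", "C", 3) == pytest.approx(1 / 10)
        assert t2.phred("G", "A", "C", 3) == 0

    def test_unobserved_stratum_prior(self):
        t = ms.CalibrationTable()
        assert t.posterior("C", "G", "T", 0) == 0.5
        assert t.phred("C", "G", "T", 0) == 3

    def test_posterior_equals_brute_force_counts(self, tmp_path):
        # toy alignments: counts per stratum recomputed independently
        rng = np.random.default_rng(42)
        ref = "".join(rng.choice(list("ACGT"), 400))
        genome = ms.SimGenome({"chr1": ref}, origin="user-supplied")
        pairs = {}
        sam = str(tmp_path / "p1.sam")
        header = pysam.AlignmentHeader.from_references(["chr1"], [400])
        expected = {}
        with pysam.AlignmentFile(sam, "w", header=header) as out:
            for i in range(60):
                start = int(rng.integers(0, 360))
                seq = ref[start : start + 40]
                r1 = list(seq)
                # plant one mismatch per read at cycle 7
                wrong = "ACGT"[(("ACGT".index(seq[7])) + 1 + int(rng.integers(3))) % 4]
                keep_r1 = bool(rng.random() < 0.5)
                if keep_r1:
                    r2 = list(seq)
                    r2[7] = wrong  # Read2 wrong, Read1 matches reference
                else:
                    r1[7] = wrong  # Read1 wrong
                    r2 = list(seq)
                r1 = "".join(r1)
                r2 = "".join(r2)
                if ms.classify_position(r1[7], r2[7]) is not PairClass.MISMATCH:
                    continue
                rid = f"t{i}"
                pairs[rid] = ms.ReadPair(rid, r1, "I" * 40, r2, "I" * 40)
                a = pysam.AlignedSegment(header)
                a.query_name, a.flag = rid, 0
                a.reference_id, a.reference_start = 0, start
                a.query_sequence = r1
                a.query_qualities = [30] * 40
                a.cigarstring = "40M"
                a.set_tag("AS", 0, "i")
                out.write(a)
                key = (ref[start + 7], r1[7], r2[7], 0)
                x, n = expected.get(key, (0, 0))
                expected[key] = (x + (r1[7] == ref[start + 7]), n + 1)
        table = ms.build_calibration_table(pairs, sam, genome.contigs)
        assert expected  # fixture produced strata
        for (r, a_, b, cbin), (x, n) in expected.items():
            assert table.posterior(r, a_, b, cbin * 10) == pytest.approx(
                (x + 1) / (n + 2)
            )

    def test_calibrated_quality_direction(self, tmp_path):
        # strata where Read1 matched the reference earn higher Q than
        # strata where Read1 was the erroneous mate
        t = ms.CalibrationTable()
        for _ in range(50):
            t.add("A", "A", "G", 0, success=True)   # Read2 error stratum
            t.add("A", "G", "A", 0, success=False)  # Read1 error stratum
        q_read2_err = t.phred("A", "A", "G", 0)
        q_read1_err = t.phred("A", "G", "A", 0)
        assert q_read1_err < q_read2_err

    def test_calibrate_pair_lookup_and_noop(self):
        t = ms.CalibrationTable()
        for _ in range(99):
            t.add("A", "A", "C", 1, success=True)
        d = ms.calibrate_pair(pair("AACGT", "ACCGT"), t, ref_bases="AACGT")
        assert ord(d.quality[1]) - 33 == t.phred("A", "A", "C", 1) == 20
        clean = pair("TACGT", "CACGT")
        assert ms.calibrate_pair(clean, t) == ms.deconvolve_pair(clean)


class TestBatch:
    def test_round_trip_zero_error(self):
        genome, truth, pairs, results, summary = simulate_library(
            genome_len=20_000, n_fragments=300, seed=5
        )
        assert summary["deconvolved"] == 300
        by_id = {p.id: p for p in pairs}
        for d in results:
            p = by_id[d.id]
            frag = genome.contigs[p.contig][p.start : p.start + p.frag_len]
            if p.strand == "-":
                frag = ms.revcomp(frag)
            assert d.sequence == frag[: len(d.sequence)]
            called = tuple(
                i for i, c in enumerate(d.methylation) if c in "ZXHU"
            )
            assert called == p.meth_offsets

    def test_undeconvolvable_fraction_rejected(self):
        _, _, _, _, summary = simulate_library(
            genome_len=30_000,
            n_fragments=1_000,
            conversion_rate=0.975,
            undeconvolvable_fraction=0.15,
            seed=8,
        )
        frac = summary["rejected"] / summary["total"]
        assert 0.10 < frac < 0.20

    def test_summary_counts_consistent(self):
        _, _, _, results, summary = simulate_library(
            genome_len=10_000, n_fragments=100, seed=6
        )
        assert (
            summary["deconvolved"] + summary["rejected"] + summary["dropped_in_trim"]
            == summary["total"]
        )
        total_positions = sum(summary["position_classes"].values())
        assert total_positions == sum(len(d.sequence) for d in results)

    def test_empty_batch(self):
        assert ms.deconvolution_summary([]) == {
            "total": 0,
            "deconvolved": 0,
            "rejected": 0,
            "dropped_in_trim": 0,
            "position_classes": {
                "agree": 0, "meth_c": 0, "unmeth_c": 0,
                "mismatch": 0, "ambiguous": 0,
            },
        }

    def test_report_round_trip(self, tmp_path):
        _, _, _, results, _ = simulate_library(
            genome_len=5_000, n_fragments=30, seed=7
        )
        path = tmp_path / "report.tsv"
        ms.write_methylation_report(results, path)
        calls = ms.load_methylation_report(path)
        d = next(r for r in results if any(c != "." for c in r.methylation))
        assert [(o, c, s) for _, o, c, s in ms.methylation_report_rows(d)] == calls[d.id]
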