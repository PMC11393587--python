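"""Alignment error decomposition and homopolymer identification:
CIGAR/MD walking against hand-enumerated and brute-force oracles, and
exact agreement with the synthetic generator's injected-error truth."""

import re

import numpy as np
import pysam
import pytest
from conftest import make_record

from lrqc import observe as obs
from lrqc import synthetic as syn
from lrqc.observe import AlignmentFeatureCounts, HomopolymerEvent


class TestExtractAlignmentFeatures:
    @pytest.mark.parametrize(
        "cigar,md,expected",
        [
            # perfect alignment
            ("10M", "10", (10, 0, 0, 0)),
            # hand enumeration: 4 match, 1 ins, 3 match, 1 del, 2 match
            ("4M1I3M1D2M", "7^A2", (9, 0, 1, 1)),
            # MD walk: mismatch at offset 2 of 5 aligned bases
            ("5M", "2A2", (4, 1, 0, 0)),
            # soft clips excluded from every count
            ("3S10M2S", "10", (10, 0, 0, 0)),
            # multi-base indels and two substitutions
            ("2M2D6M3I2M", "1T^CA8", (9, 1, 3, 2)),
            # =/X operators classified without MD
            ("4=1X3=", None, (7, 1, 0, 0)),
            # reference skip (spliced intron) is not an error operation
            ("5M100N5M", "10", (10, 0, 0, 0)),
        ],
    )
    def test_against_hand_enumerated_oracle(self, cigar, md, expected):
        counts = obs.extract_alignment_features(make_record(cigar, md))
        assert (
            counts.n_mat, counts.n_sub, counts.n_ins, counts.n_del
        ) == expected
        assert counts.n_total == sum(expected)

    def test_missing_md_without_reference_raises(self):
        with pytest.raises(ValueError, match="MD"):
            obs.extract_alignment_features(make_record("5M"))

    def test_unmapped_record_rejected(self):
        rec = make_record("4M", "4", flag=4)
        rec.reference_id = -1
        with pytest.raises(ValueError, match="unmapped"):
            obs.extract_alignment_features(rec)

    def test_reference_fallback_reconstructs_substitutions(self, tmp_path):
        ref = syn.write_fasta(tmp_path / "r.fa", {"chr1": "ACGTACGTAC"})
        rec = make_record("10M", md=None, seq="ACGTAAGTAC", start=0)
        with pysam.FastaFile(str(ref)) as fasta:
            counts = obs.extract_alignment_features(rec, fasta)
        assert (counts.n_mat, counts.n_sub) == (9, 1)

    def test_truth_sam_counts_match_generator_exactly(self, truth_bundle):
        """On 1000 synthetic reads the extracted counts equal the
        injected-error truth for every read."""
        truth = truth_bundle["truth"].set_index("read_id")
        n = 0
        with pysam.AlignmentFile(truth_bundle["bam"]) as bam:
            for rec in bam:
                counts = obs.extract_alignment_features(rec)
                row = truth.loc[rec.query_name]
                assert (
                    counts.n_mat, counts.n_sub, counts.n_ins, counts.n_del
                ) == (row.n_mat, row.n_sub, row.n_ins, row.n_del), rec.query_name
                n += 1
        assert n >= 1000

    def test_error_rate_recovery_within_half_percent(self, truth_bundle):
        per_read, _, _ = obs.observe_alignments(
            truth_bundle["bam"], truth_bundle["reference"], "s1"
        )
        rates = truth_bundle["rates"]
        assert per_read["sub_prop"].mean() == pytest.approx(
            rates["sub"], abs=0.005
        )
        assert per_read["ins_prop"].mean() == pytest.approx(
            rates["ins"], abs=0.005
        )
        assert per_read["del_prop"].mean() == pytest.approx(
            rates["del"], abs=0.005
        )


class TestObservedMetrics:
    def test_direct_substitution_into_definitions(self):
        m = obs.observed_metrics(AlignmentFeatureCounts("r", 7, 1, 1, 1))
        assert m.observed_accuracy == pytest.approx(0.7)
        assert m.observed_identification == pytest.approx(0.875)
        assert m.ins_prop == m.del_prop == m.sub_prop == pytest.approx(0.1)

    def test_perfect_read(self):
        m = obs.observed_metrics(AlignmentFeatureCounts("r", 10, 0, 0, 0))
        assert m.observed_accuracy == 1.0
        assert m.observed_identification == 1.0

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            obs.observed_metrics(AlignmentFeatureCounts("r", 0, 0, 0, 0))

    def test_identification_missing_when_only_indels(self):
        m = obs.observed_metrics(AlignmentFeatureCounts("r", 0, 0, 2, 1))
        assert m.observed_identification is None

    def test_conservation_on_random_synthetic_alignments(self, truth_bundle):
        """Count parts sum to the total and the four proportions sum to
        one, for every one of >=1000 random alignments."""
        n = 0
        with pysam.AlignmentFile(truth_bundle["bam"]) as bam:
            for rec in bam:
                c = obs.extract_alignment_features(rec)
                assert c.n_total == c.n_mat + c.n_sub + c.n_ins + c.n_del
                m = obs.observed_metrics(c)
                total = m.observed_accuracy + m.ins_prop + m.del_prop + m.sub_prop
                assert total == pytest.approx(1.0, abs=1e-12)
                assert m.observed_identification >= m.observed_accuracy
                n += 1
        assert n >= 1000


def brute_force_runs(seq, min_len):
    """Independent oracle: regex scan for maximal single-base runs."""
    return [
        (m.start(), m.end(), m.group()[0])
        for m in re.finditer(r"(A+|C+|G+|T+)", seq)
        if m.end() - m.start() >= min_len
    ]


class TestFindHomopolymers:
    def test_worked_example(self):
        events = obs.find_homopolymers_in_sequence("AAAATTGGGGG", 4, "c")
        assert [(e.start, e.end, e.base, e.length) for e in events] == [
            (0, 4, "A", 4), (6, 11, "G", 5)
        ]

    @pytest.mark.parametrize("seq", ["AAA", ""])
    def test_short_or_empty_sequences(self, seq):
        assert obs.find_homopolymers_in_sequence(seq, 4) == []

    def test_min_len_below_two_rejected(self):
        with pytest.raises(ValueError):
            obs.find_homopolymers_in_sequence("AAAA", 1)

    def test_n_runs_excluded(self):
        events = obs.find_homopolymers_in_sequence("NNNNNAAAA", 4)
        assert [(e.base, e.start) for e in events] == [("A", 5)]

    @pytest.mark.parametrize("min_len", [3, 4, 5])
    def test_equals_brute_force_on_random_sequences(self, min_len):
        for seed in range(10):
            seq, _ = syn.generate_reference(100_000, 0.5, seed=seed)
            got = [
                (e.start, e.end, e.base)
                for e in obs.find_homopolymers_in_sequence(seq, min_len)
            ]
            assert got == brute_force_runs(seq, min_len)


class TestScoreHomopolymerEvent:
    RUN = HomopolymerEvent("chr1", 10, 14, "A")

    def _profile(self, cigar, md, start=0):
        return obs.alignment_reference_profile(make_record(cigar, md, start))

    def test_perfect_read_scores_correct(self):
        assert obs.score_homopolymer_event(
            self.RUN, self._profile("20M", "20")
        ) is True

    def test_deletion_inside_run_scores_incorrect(self):
        # deletion at reference positions 11-12, inside [10, 14)
        prof = self._profile("11M2D7M", "11^AA7")
        assert obs.score_homopolymer_event(self.RUN, prof) is False

    def test_substitution_inside_run_scores_incorrect(self):
        prof = self._profile("20M", "12T7")  # mismatch at ref pos 12
        assert obs.score_homopolymer_event(self.RUN, prof) is False

    def test_insertion_strictly_inside_run_scores_incorrect(self):
        # insertion between ref positions 11 and 12
        prof = self._profile("12M1I8M", "20")
        assert obs.score_homopolymer_event(self.RUN, prof) is False

    def test_insertion_at_run_boundary_does_not_penalize(self):
        # insertion between ref 9 and 10 (before the run) and between
        # 13 and 14 (after the last run base): flank territory
        for cigar in ("10M1I10M", "14M1I6M"):
            prof = self._profile(cigar, "20")
            assert obs.score_homopolymer_event(self.RUN, prof) is True

    def test_alignment_not_spanning_flanks_is_excluded(self):
        # starts exactly at the run: left flank not covered
        assert obs.score_homopolymer_event(
            self.RUN, self._profile("10M", "10", start=10)
        ) is None
        # ends exactly at run end: right flank not covered
        assert obs.score_homopolymer_event(
            self.RUN, self._profile("14M", "14", start=0)
        ) is None

    def test_error_free_reads_identify_all_spanned_runs(self, tmp_path):
        hp = [
            syn.HomopolymerSpec(100, "A", 6),
            syn.HomopolymerSpec(300, "G", 5),
        ]
        seq, _ = syn.generate_reference(2_000, 0.5, seed=9, homopolymers=hp)
        ref = syn.write_fasta(tmp_path / "r.fa", {"chr1": seq})
        bam = tmp_path / "perfect.bam"
        syn.simulate_reads(
            seq, n_reads=20, read_length=1000, sub_rate=0, ins_rate=0,
            del_rate=0, seed=4, bam_path=bam,
        )
        per_read, summary, stats = obs.observe_alignments(bam, ref, "s", 4)
        assert (per_read["observed_accuracy"] == 1.0).all()
        assert stats["hp_scored"] > 0
        scored = summary[summary["n_events"] > 0]
        assert (scored["accuracy"] == 1.0).all()


class TestSummarizeHomopolymers:
    def test_counting_oracle(self):
        events = [
            HomopolymerEvent("c", 0, 4, "A", scored=s)
            for s in (True, True, True, False)
        ]
        table = obs.summarize_homopolymers(events).set_index("base")
        assert table.loc["A", "n_events"] == 4
        assert table.loc["A", "accuracy"] == pytest.approx(0.75)

    def test_base_without_events_is_missing_not_zero(self):
        table = obs.summarize_homopolymers([]).set_index("base")
        assert table["n_events"].sum() == 0
        assert table["accuracy"].isna().all()

    def test_unscored_events_ignored(self):
        events = [
            HomopolymerEvent("c", 0, 4, "G", scored=True),
            HomopolymerEvent("c", 9, 14, "G", scored=None),
        ]
        table = obs.summarize_homopolymers(events).set_index("base")
        assert table.loc["G", "n_events"] == 1
        assert table.loc["G", "accuracy"] == 1.0
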