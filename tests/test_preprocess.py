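"""Preprocessing tests: exact trimming, quality and contaminant filters,
unique exact-match alignment, and ledger conservation."""
from __future__ import annotations

import numpy as np
import pytest

import ribopause as rp
from ribopause.io import ReadRecord, TranscriptRecord
from ribopause.preprocess import (
    align_to_transcriptome,
    deplete_contaminants,
    length_filter,
    quality_filter,
    trim_adapter,
)
from ribopause.synthetic import DEFAULT_ADAPTER

from helpers import toy_transcript

Q40 = chr(33 + 40)


def _read(seq, qual=None, rid="r0"):
    return ReadRecord(rid, seq, qual if qual is not None else Q40 * len(seq))


class TestTrimAdapter:
    def test_full_adapter_after_insert(self):
        insert = "ACGT" * 7  # 28 nt
        read = _read(insert + DEFAULT_ADAPTER)
        trimmed, code = trim_adapter(read, DEFAULT_ADAPTER)
        assert code == "ok"
        assert trimmed.sequence == insert
        assert len(trimmed.quality) == 28

    def test_adapter_only_read_discarded(self):
        trimmed, code = trim_adapter(_read(DEFAULT_ADAPTER), DEFAULT_ADAPTER)
        assert trimmed is None and code == "short_insert"

    def test_empty_read_distinct_code(self):
        trimmed, code = trim_adapter(_read(""), DEFAULT_ADAPTER)
        assert trimmed is None and code == "empty"

    def test_no_adapter_match_discarded(self):
        trimmed, code = trim_adapter(_read("ACGT" * 10), DEFAULT_ADAPTER)
        assert trimmed is None and code == "no_adapter"

    def test_simulated_reads_all_trim_to_truth_lengths(self, small_sim, small_spec):
        _, reads, truth = small_sim
        lengths = dict(zip(truth.reads["read_id"], truth.reads["length"]))
        n_ok = 0
        for read in reads[:1000]:
            trimmed, code = trim_adapter(read, small_spec.adapter)
            assert code == "ok"
            assert len(trimmed.sequence) == lengths[read.id]
            n_ok += 1
        assert n_ok == 1000


class TestQualityFilter:
    def test_high_quality_kept(self):
        assert quality_filter(_read("ACGT" * 7))

    def test_low_quality_discarded(self):
        assert not quality_filter(_read("ACGT" * 7, chr(33 + 10) * 28))

    def test_mean_threshold_boundary(self):
        # 97 bases at Phred 20 + 3 at Phred 19 -> mean 19.97: discarded
        qual = chr(33 + 20) * 97 + chr(33 + 19) * 3
        assert not quality_filter(_read("A" * 100, qual))
        assert quality_filter(_read("A" * 100, chr(33 + 20) * 100))

    def test_per_base_mode_stricter(self):
        qual = chr(33 + 40) * 27 + chr(33 + 19)
        read = _read("A" * 28, qual)
        assert quality_filter(read)
        assert not quality_filter(read, per_base=True)


class TestContaminantDepletion:
    def test_contaminant_substring_removed(self, contaminants):
        seq = next(iter(contaminants.values()))[100:130]
        survivors, removed = deplete_contaminants([_read(seq)], contaminants)
        assert removed == 1 and not survivors

    def test_transcript_read_kept(self, small_sim, contaminants):
        transcripts, _, _ = small_sim
        rec = next(iter(transcripts.values()))
        read = _read(rec.sequence[rec.cds_start:rec.cds_start + 30])
        survivors, removed = deplete_contaminants([read], contaminants)
        assert removed == 0 and survivors == [read]

    def test_empty_contaminant_set_warns(self):
        with pytest.warns(UserWarning):
            survivors, removed = deplete_contaminants([_read("ACGT" * 7)], {})
        assert removed == 0 and len(survivors) == 1

    def test_removed_count_matches_truth(self):
        spec = rp.SimSpec(n_transcripts=20, depth=10_000, frac_contaminant=0.1, seed=13)
        transcripts, truth0 = rp.generate_transcriptome(spec)
        reads, truth = rp.simulate_library(transcripts, truth0, spec)
        trimmed = [trim_adapter(r, spec.adapter)[0] for r in reads]
        _, removed = deplete_contaminants(trimmed, rp.load_contaminants())
        assert removed == truth.class_counts["contaminant"]


class TestAlignment:
    def test_unique_read_recovers_true_position(self, small_sim):
        transcripts, _, truth = small_sim
        row = truth.footprint_reads().iloc[0]
        seq = transcripts[row["transcript"]].sequence[
            row["five_prime"]:row["five_prime"] + row["length"]
        ]
        alns, counts = align_to_transcriptome([_read(seq)], transcripts)
        assert len(alns) == 1
        assert (alns[0].transcript_id, alns[0].five_prime_pos) == (
            row["transcript"], row["five_prime"]
        )

    def test_repeat_read_multimapped_and_dropped(self):
        t1 = TranscriptRecord("a", "A" * 40 + "ATGCCCTAA" + "G" * 20, 40, 49)
        t2 = TranscriptRecord("b", "A" * 50 + "ATGTTTTAA" + "G" * 20, 50, 59)
        alns, counts = align_to_transcriptome([_read("A" * 30)], {"a": t1, "b": t2})
        assert not alns and counts["multimapped"] == 1

    def test_unaligned_counted(self, small_sim):
        transcripts, _, _ = small_sim
        alns, counts = align_to_transcriptome([_read("ACGT" * 8)], transcripts)
        assert not alns and counts["unaligned"] == 1

    def test_full_library_alignment_is_bijective_with_truth(
        self, small_sim, small_preprocessed
    ):
        _, _, truth = small_sim
        alns, _ = small_preprocessed
        got = {(a.read_id, a.transcript_id, a.five_prime_pos, a.length) for a in alns}
        fp = truth.footprint_reads()
        want = set(
            zip(fp["read_id"], fp["transcript"], fp["five_prime"], fp["length"])
        )
        assert got == want


class TestLengthFilter:
    def test_closed_range_boundaries(self):
        alns = [
            rp.AlignmentRecord(f"r{L}", "t", 0, L) for L in (25, 26, 30, 35, 36)
        ]
        kept, excluded = length_filter(alns)
        assert [a.length for a in kept] == [26, 30, 35]
        assert excluded == 2

    def test_empty_input(self):
        kept, excluded = length_filter([])
        assert kept == [] and excluded == 0

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            length_filter([], 35, 26)

    def test_excluded_count_matches_truth(self, small_sim):
        transcripts, _, truth = small_sim
        alns = rp.true_alignments(truth)
        kept, excluded = length_filter(alns, 27, 30)
        fp = truth.footprint_reads()
        outside = int(((fp["length"] < 27) | (fp["length"] > 30)).sum())
        assert excluded == outside
        assert len(kept) + excluded == len(alns)


class TestFullChain:
    def test_ledger_conserves_reads(self, small_preprocessed):
        _, ledger = small_preprocessed
        ledger.check()
        assert ledger.input == ledger.partition_sum()
        assert ledger.quality_discarded > 0 and ledger.contaminant > 0

    def test_output_order_is_input_order(self, small_sim, small_preprocessed):
        _, reads, _ = small_sim
        alns, _ = small_preprocessed
        order = {r.id: i for i, r in enumerate(reads)}
        positions = [order[a.read_id] for a in alns]
        assert positions == sorted(positions)

    def test_inverted_range_raises_before_work(self, small_sim, contaminants):
        transcripts, reads, _ = small_sim
        with pytest.raises(ValueError):
            rp.run_preprocess(reads, transcripts, contaminants,
                              adapter=DEFAULT_ADAPTER, min_len=35, max_len=26)


class TestSamRoundtrip:
    def test_write_then_read_preserves_records(self, tmp_path):
        t = toy_transcript("t0", "A" * 30, "M" + "G" * 40, "C" * 30)
        alns = [
            rp.AlignmentRecord("r1", "t0", 5, 28),
            rp.AlignmentRecord("r2", "t0", 40, 30),
        ]
        sam = tmp_path / "a.sam"
        rp.write_sam(alns, {"t0": t}, sam)
        back, dropped = rp.read_sam(sam)
        assert [
            (a.read_id, a.transcript_id, a.five_prime_pos, a.length) for a in back
        ] == [(a.read_id, a.transcript_id, a.five_prime_pos, a.length) for a in alns]
        assert sum(dropped.values()) == 0


def test_duplicate_fasta_ids_hard_error(tmp_path):
    fa = tmp_path / "dup.fa"
    fa.write_text(">x\nACGTACGT\n>x\nTTTTAAAA\n")
    with pytest.raises(ValueError, match="duplicate"):
        rp.read_fasta(fa)
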