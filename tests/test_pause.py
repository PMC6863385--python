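"""Pause-analysis tests: motif scanning against a translate-and-regex oracle,
score arithmetic, scale invariance and the bootstrap comparison."""
from __future__ import annotations

import numpy as np
import pytest

import ribopause as rp
from ribopause.io import TranscriptRecord
from ribopause.pause import (
    MotifOccurrence,
    PauseScoreTable,
    PauseScore,
    compare_conditions,
    motif_metagene,
    pause_score,
    pause_score_table,
    scan_motifs,
)

from helpers import coverage_with_counts, toy_transcript, translate_scan_oracle


class TestScanMotifs:
    def test_spppvp_context_yields_all_three_motifs(self):
        # 10 background codons on each side of an SPPPVP cassette
        aa = "M" + "GAVL" * 5 + "SPPPVP" + "GAVL" * 5
        t = toy_transcript("t0", "A" * 30, aa, "C" * 30)
        transcripts = {"t0": t}
        ppp = scan_motifs(transcripts, "PPP")
        spp = scan_motifs(transcripts, "SPP")
        ppv = scan_motifs(transcripts, "PPV")
        assert [o.codon_index for o in ppp] == [22]
        assert [o.codon_index for o in spp] == [21]
        assert [o.codon_index for o in ppv] == [23]
        assert "SPPPVP" in ppp[0].context

    def test_no_proline_no_occurrences(self):
        t = toy_transcript("t0", "A" * 30, "M" + "GAVL" * 10, "C" * 30)
        assert scan_motifs({"t0": t}, "PPP") == []

    def test_overlapping_occurrences_both_reported(self):
        aa = "M" + "GAVL" * 3 + "PPPP" + "GAVL" * 3
        t = toy_transcript("t0", "A" * 30, aa, "C" * 30)
        idx = [o.codon_index for o in scan_motifs({"t0": t}, "PPP")]
        assert idx == [13, 14]

    def test_flank_rule_excludes_edge_occurrences(self):
        aa = "M" + "PPP" + "GAVL" * 10  # occurrence 4 codons from the start
        t = toy_transcript("t0", "A" * 30, aa, "C" * 30)
        assert scan_motifs({"t0": t}, "PPP") == []

    def test_internal_stop_skips_transcript_with_warning(self):
        t = toy_transcript("t0", "A" * 30, "M" + "GAVL" * 5 + "PPP" + "GAVL" * 5, "C" * 30)
        bad_cds = t.cds[:30] + "TAA" + t.cds[33:]
        bad = TranscriptRecord("t0", t.sequence[:30] + bad_cds + t.sequence[30 + len(t.cds):],
                               t.cds_start, t.cds_end)
        with pytest.warns(UserWarning, match="internal stop"):
            assert scan_motifs({"t0": bad}, "PPP") == []

    def test_simulated_occurrences_match_oracle(self, small_sim):
        transcripts, _, truth = small_sim
        occs = scan_motifs(transcripts, "PPP")
        got = {(o.transcript_id, o.codon_index) for o in occs}
        assert got == translate_scan_oracle(transcripts, "PPP")
        planted = {
            (tid, idx) for tid, v in truth.occurrences.items() for _, idx in v
        }
        assert got == planted


@pytest.fixture()
def motif_coverage():
    """60-codon CDS, flat background 2.0, motif codons 20-22 at 8.0."""
    aa = "M" + "GAVL" * 4 + "AGL" + "PPP" + "GAVL" * 9 + "AGL"
    t = toy_transcript("t0", "A" * 70, aa, "C" * 70)
    transcripts = {"t0": t}
    counts = np.full(t.n_codons, 2.0)
    occ = scan_motifs(transcripts, "PPP")[0]
    counts[occ.codon_index:occ.codon_index + 3] = 8.0
    return transcripts, coverage_with_counts(transcripts, {"t0": counts}), occ


class TestPauseScore:
    def test_score_arithmetic(self, motif_coverage):
        _, cov, occ = motif_coverage
        s = pause_score(cov, occ)
        assert s.usable
        assert s.score == pytest.approx(4.0)
        assert s.background == pytest.approx(2.0)

    def test_uniform_coverage_scores_one(self, motif_coverage):
        transcripts, _, occ = motif_coverage
        t = transcripts["t0"]
        cov = coverage_with_counts(transcripts, {"t0": np.full(t.n_codons, 3.0)})
        assert pause_score(cov, occ).score == pytest.approx(1.0)

    def test_zero_background_unusable_not_division_error(self, motif_coverage):
        transcripts, _, occ = motif_coverage
        cov = coverage_with_counts(transcripts, {})
        s = pause_score(cov, occ, background_floor=0.0)
        assert not s.usable and np.isnan(s.score)

    def test_below_floor_flagged_unusable(self, motif_coverage):
        transcripts, _, occ = motif_coverage
        t = transcripts["t0"]
        cov = coverage_with_counts(transcripts, {"t0": np.full(t.n_codons, 0.2)})
        assert not pause_score(cov, occ, background_floor=0.5).usable

    def test_other_occurrence_codons_excluded_from_background(self, motif_coverage):
        transcripts, cov, occ = motif_coverage
        # a fake second occurrence with huge counts sitting in the flank
        other = MotifOccurrence("t0", "PPP", occ.codon_index + 10, "")
        arr = cov.cds_counts("t0")
        arr[other.codon_index:other.codon_index + 3] = 1e6
        with_excl = pause_score(cov, occ, other_occurrences=[occ, other])
        assert with_excl.background == pytest.approx(2.0)

    def test_scale_invariance(self, small_sim):
        transcripts, _, truth = small_sim
        alns = rp.true_alignments(truth)
        table = rp.calibrate_offsets(alns, transcripts)
        cov = rp.psite_coverage(alns, table, transcripts)
        occs = scan_motifs(transcripts, "PPP")
        base = pause_score_table(cov, occs, background_floor=0.0)
        scaled = pause_score_table(cov.scale(1 / 3.0), occs, background_floor=0.0)
        for a, b in zip(base.scores, scaled.scores):
            if a.usable and b.usable:
                assert b.score == pytest.approx(a.score)

    def test_median_invariant_to_unusable_occurrences(self):
        occ = MotifOccurrence("t", "PPP", 10, "")
        usable = [PauseScore(occ, s, 2.0, True) for s in (1.0, 2.0, 3.0)]
        junk = [PauseScore(occ, float("nan"), 0.0, False)] * 5
        assert PauseScoreTable(usable).aggregate_score() == PauseScoreTable(
            usable + junk
        ).aggregate_score() == 2.0


class TestMotifMetagene:
    def test_uniform_coverage_flat_profile(self, motif_coverage):
        transcripts, _, occ = motif_coverage
        t = transcripts["t0"]
        cov = coverage_with_counts(transcripts, {"t0": np.full(t.n_codons, 3.0)})
        prof = motif_metagene(cov, [occ])
        np.testing.assert_allclose(prof.mean, 1.0)

    def test_peak_at_motif_positions(self, motif_coverage):
        _, cov, occ = motif_coverage
        prof = motif_metagene(cov, [occ])
        np.testing.assert_allclose(prof.mean[5:8], 4.0)  # positions 0..2
        np.testing.assert_allclose(np.delete(prof.mean, [5, 6, 7]), 1.0)

    def test_no_occurrences_flagged_empty(self, motif_coverage):
        _, cov, _ = motif_coverage
        prof = motif_metagene(cov, [])
        assert prof.flagged_empty


class TestCompareConditions:
    def _table(self, scores):
        occ = MotifOccurrence("t", "PPP", 10, "")
        return PauseScoreTable([PauseScore(occ, s, 2.0, True) for s in scores])

    def test_identity_comparison(self):
        rng = np.random.default_rng(3)
        table = self._table(rng.lognormal(1.0, 0.3, size=50))
        cmp = compare_conditions(table, table, n_boot=500, seed=9)
        assert cmp.ratio == pytest.approx(1.0)
        assert cmp.contains(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        a = self._table(rng.lognormal(1.0, 0.3, size=40))
        b = self._table(rng.lognormal(1.5, 0.3, size=40))
        c1 = compare_conditions(a, b, seed=11)
        c2 = compare_conditions(a, b, seed=11)
        assert (c1.ratio, c1.ci_low, c1.ci_high) == (c2.ratio, c2.ci_low, c2.ci_high)
        assert c1.ratio > 1.0

    def test_too_few_usable_refused(self):
        table = self._table([1.0] * 5)
        with pytest.raises(ValueError, match="usable"):
            compare_conditions(table, table)
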