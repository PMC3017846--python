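import dataclasses

import numpy as np
import pytest

from mircane.hairpin_check import (CheckConfig, check, locate_star,
                                   trim_stemloop)
from mircane.homology_scan import MatureQuery, PrecursorWindow
from mircane.seqio import reverse_complement
from mircane.structure import fold
from mircane.synthetic import make_criterion_knockout, make_precursor


def _window(seq, offset, mature, family="t", arm="unknown"):
    query = MatureQuery(family, mature, expected_arm=arm)
    return (PrecursorWindow("rec", "+", 0, len(seq), seq, offset,
                            len(mature), query), query)


class TestLocateStar:
    def test_perfect_inverted_repeat(self):
        mature = "GCAUGGCAUCGGACUUGGACU"  # 21 nt
        # all-C loop: C pairs neither the terminal U nor the star's A
        seq = mature + "CCCCCC" + reverse_complement(mature)
        f = fold(seq)
        stats = locate_star(f, 0, 21)
        assert stats.paired_count == 21
        assert stats.mismatch_count == 0
        assert stats.mature_arm == "5p"
        assert stats.star_contiguous

    def test_fully_unpaired_mature_is_not_an_error(self):
        seq = "A" * 30 + "GGGGGAAAACCCCC"
        f = fold(seq)
        stats = locate_star(f, 0, 21)
        assert stats.paired_count == 0

    def test_loop_spanning_mature_detected(self):
        stem = "GCAUGGCAU"
        seq = "GG" + stem + "CCC" + reverse_complement(stem) + "CC"
        f = fold(seq)
        stats = locate_star(f, 2, len(stem) * 2 + 3)
        assert stats.mature_arm == "spans_loop"


class TestTrimming:
    def test_trim_extends_through_clean_stem(self):
        mature = "GCAUGGCAUCGGACUUGGACU"
        ext = "GGCAUCGGAC"
        seq = ("A" * 20 + ext + mature + "CCCCC"
               + reverse_complement(mature) + reverse_complement(ext)
               + "A" * 20)
        f = fold(seq)
        stats = locate_star(f, 30, 21)
        lo, hi = trim_stemloop(f.pairing, min(30, stats.star_start),
                               max(50, stats.star_end))
        # the trimmed region covers the extension stem but not the
        # poly-A flanks
        assert lo == 20
        assert hi == len(seq) - 21


class TestCheck:
    def _report(self, mature, mismatches, **kwargs):
        rng = np.random.default_rng(77)
        rec, truth = make_precursor(mature, mismatches, rng=rng, **kwargs)
        window, query = _window(rec.residues, truth.mature_offset, mature)
        return check(window, fold(rec.residues), query)

    def test_valid_candidate_accepted(self):
        rep = self._report("UGACAGAAGAGAGUGAGCAC", 3)
        assert rep.verdict
        assert rep.failed == []
        assert rep.trimmed_len >= 60
        assert rep.mfei > 0.65

    def test_perfect_duplex_fails_only_mismatch_minimum(self):
        rep = self._report("UGACAGAAGAGAGUGAGCAC", 0)
        assert rep.failed == ["c4"]

    def test_seven_mismatches_fail_upper_bound(self):
        rep = self._report("UGACAGAAGAGAGUGAGCAC", 7)
        assert "c4" in rep.failed

    def test_short_stemloop_fails_only_length(self):
        rng = np.random.default_rng(3)
        record, query, offset, report = make_criterion_knockout("c9", rng)
        assert report.failed == ["c9"]
        assert report.trimmed_len < 60

    @pytest.mark.parametrize("criterion",
                             [f"c{i}" for i in range(1, 10)])
    def test_single_criterion_knockouts(self, criterion):
        """Each constructed knockout fails exactly its target criterion."""
        record, query, offset, report = make_criterion_knockout(
            criterion, np.random.default_rng(42))
        assert report.failed == [criterion]
        assert not report.verdict

    def test_verdict_monotone_under_relaxed_thresholds(self):
        """Relaxing every threshold never flips accept to reject."""
        relaxed = CheckConfig(
            mfei_min=0.0, gc_min=0.0, gc_max=100.0,
            min_duplex_mismatches=0, max_duplex_mismatches=25,
            max_consecutive_mismatches=25, min_paired=1,
            min_stemloop_len=1)
        for mismatches in (1, 3, 6):
            rng = np.random.default_rng(100 + mismatches)
            rec, truth = make_precursor("UUCCACAGCUUUCUUGAACUG", mismatches,
                                        rng=rng)
            window, query = _window(rec.residues, truth.mature_offset,
                                    "UUCCACAGCUUUCUUGAACUG")
            f = fold(rec.residues)
            assert check(window, f, query).verdict
            assert check(window, f, query, relaxed).verdict

    def test_fold_window_mismatch_rejected(self):
        mature = "UGACAGAAGAGAGUGAGCAC"
        seq = mature + "AAAA" + reverse_complement(mature)
        window, query = _window(seq, 0, mature)
        with pytest.raises(ValueError):
            check(window, fold("A" * len(seq)), query)
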