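import numpy as np
import pytest

from mircane.seqio import fasta_string
from mircane.synthetic import (ConstructionError, SynthSpec, build_database,
                               make_decoys, make_precursor, make_target_site,
                               truth_frame)


class TestDeterminism:
    def test_same_seed_gives_identical_fasta_and_truth(self):
        spec = SynthSpec(seed=99, n_embeds=3, n_random=10, n_low_gc=2,
                         n_high_gc=2, n_repeat=2, n_mite=2)
        a = build_database(spec)
        b = build_database(spec)
        assert fasta_string(a.records) == fasta_string(b.records)
        assert truth_frame(a.truths).equals(truth_frame(b.truths))

    def test_different_seeds_differ(self):
        base = dict(n_embeds=2, n_random=5, n_low_gc=0, n_high_gc=0,
                    n_repeat=0, n_mite=0)
        a = build_database(SynthSpec(seed=1, **base))
        b = build_database(SynthSpec(seed=2, **base))
        assert fasta_string(a.records) != fasta_string(b.records)


class TestMakePrecursor:
    def test_valid_precursor_verifies_as_accept(self, rng):
        rec, truth = make_precursor("UAGCCAAGGAUGACUUGCCGG", 4, rng=rng)
        assert truth.expected_verdict == "accept"
        assert truth.expected_failed == ()

    def test_infeasible_loop_rejected(self, rng):
        with pytest.raises(ConstructionError):
            make_precursor("UAGCCAAGGAUGACUUGCCGG", 3, loop_len=2, rng=rng)

    def test_too_many_mismatches_rejected(self, rng):
        with pytest.raises(ConstructionError):
            make_precursor("UAGCCAAGGAUGACUUGCCGG", 19, rng=rng)


class TestMakeTargetSite:
    def test_perfect_site(self, rng):
        rec, truth = make_target_site("UUAGAUGACCAUCAGCAAACA", 0, 0, 0,
                                      rng=rng)
        assert truth.expected_score == 0.0
        assert truth.expected_accepted

    def test_impossible_wobble_placement_is_explained(self, rng):
        # a mature with A/C at every probe position cannot host 5 wobbles
        with pytest.raises(ConstructionError, match="wobble"):
            make_target_site("ACCACCACCACCACCACCACC", 5, 0, 0, rng=rng)

    def test_block2_violation_flagged(self, rng):
        rec, truth = make_target_site("UUAGAUGACCAUCAGCAAACA", 0, 1, 0,
                                      rng=rng, force_block2=True)
        assert not truth.expected_block_pass
        assert not truth.expected_accepted


class TestDecoys:
    def test_decoy_sizes_and_categories(self, rng):
        records, truths = make_decoys(rng, n_random=5, n_low_gc=2,
                                      n_high_gc=2, n_repeat=2, n_mite=2)
        assert len(records) == 13
        cats = {t.category for t in truths}
        assert cats == {"decoy_random", "decoy_low_gc", "decoy_high_gc",
                        "decoy_repeat", "decoy_mite"}
        assert all(t.expected_verdict == "none" for t in truths)

    def test_gc_bias_is_applied(self, rng):
        from mircane.seqio import gc_percent

        records, truths = make_decoys(rng, n_random=0, n_low_gc=3,
                                      n_high_gc=3, n_repeat=0, n_mite=0)
        by_cat = {}
        for rec, tr in zip(records, truths):
            by_cat.setdefault(tr.category, []).append(gc_percent(rec.residues))
        assert max(by_cat["decoy_low_gc"]) < 35
        assert min(by_cat["decoy_high_gc"]) > 65

    def test_mite_decoy_has_terminal_inverted_repeat(self, rng):
        from mircane.seqio import reverse_complement

        records, truths = make_decoys(rng, n_random=0, n_low_gc=0,
                                      n_high_gc=0, n_repeat=0, n_mite=1)
        seq = records[0].residues
        # a 40-nt TIR is present somewhere: its reverse complement too
        found = any(reverse_complement(seq[i:i + 40]) in seq
                    for i in range(0, len(seq) - 40))
        assert found
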