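import numpy as np
import pytest

from mircane.homology_scan import MatureQuery
from mircane.oracles import duplex_score_oracle
from mircane.seqio import SequenceRecord, reverse_complement
from mircane.synthetic import make_target_site
from mircane.target_predict import align_duplex, block_filter, scan_targets

MIR156 = "UGACAGAAGAGAGUGAGCAC"   # 20 nt
MIR159 = "UUUGGAUUGAAGGGAGCUCUG"  # 21 nt


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestBlockFilter:
    def test_perfect_complement_passes_clean(self):
        ok, counts = block_filter(MIR159, reverse_complement(MIR159))
        assert ok and counts == (0, 0, 0)

    def test_block2_tolerates_no_mismatch(self):
        site = list(reverse_complement(MIR159))
        L = len(MIR159)
        p = 9  # miRNA position 10, inside the zero-tolerance block
        site[L - 1 - p] = {"A": "C", "C": "A", "G": "A", "U": "C"}[MIR159[p]]
        ok, counts = block_filter(MIR159, "".join(site))
        assert not ok and counts == (0, 1, 0)

    def test_caps_are_inclusive_boundaries(self):
        site = list(reverse_complement(MIR159))
        L = len(MIR159)
        for p in (0, 1, 11, 12, 13):  # two in block 1, three in block 3
            site[L - 1 - p] = {"A": "C", "C": "A", "G": "A", "U": "C"}[MIR159[p]]
        ok, counts = block_filter(MIR159, "".join(site))
        assert ok and counts == (2, 0, 3)

    def test_gu_counts_as_block_mismatch_by_default(self):
        mirna = "G" * 8 + "AAA" + "G" * 10
        site = list(reverse_complement(mirna))
        site[-1] = "U"  # miRNA position 1 G:C -> G:U wobble
        ok, counts = block_filter(mirna, "".join(site))
        assert counts[0] == 1
        ok2, counts2 = block_filter(mirna, "".join(site), gu_is_block_match=True)
        assert counts2[0] == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            block_filter(MIR159, "ACGU")


class TestAlignDuplex:
    def test_perfect_complement_scores_zero(self):
        aln = align_duplex(MIR156, reverse_complement(MIR156))
        assert aln.score_total == 0.0
        assert set(aln.columns) == {"wc"}

    def test_single_wobble_scores_half(self):
        mirna = "AGCAGCAGCAGCAGCAGCAGC"
        site = list(reverse_complement(mirna))
        # miRNA position 2 (a G) faces site position L-2: C -> U wobble
        site[len(site) - 2] = "U"
        aln = align_duplex(mirna, "".join(site))
        assert aln.score_total == 0.5
        assert aln.n_gu == 1

    def test_boundary_combination_scores_3_5(self):
        rec, truth = make_target_site("UCGCUUGGUGCAGAUCGGGAC", 2, 1, 1,
                                      rng=np.random.default_rng(0))
        site = rec.residues[truth.site_start:truth.site_start + truth.site_len]
        aln = align_duplex("UCGCUUGGUGCAGAUCGGGAC", site)
        assert aln.score_total == 3.5
        assert (aln.n_gu, aln.n_mismatch, aln.n_bulged) == (2, 1, 1)

    def test_length_difference_beyond_bulge_budget_rejected(self):
        with pytest.raises(ValueError):
            align_duplex(MIR159, reverse_complement(MIR159) + "AAA")

    def test_score_decomposition_sums(self, rng):
        for _ in range(50):
            L = int(rng.integers(19, 25))
            mirna = _random_rna(rng, L)
            d = int(rng.integers(-2, 3))
            site = _random_rna(rng, L + d)
            aln = align_duplex(mirna, site)
            assert aln.score_total == pytest.approx(
                0.5 * aln.n_gu + aln.n_mismatch + 1.5 * aln.n_bulged)

    @pytest.mark.parametrize("near_complement", [False, True])
    def test_dp_equals_enumeration_oracle(self, near_complement):
        """The alignment DP matches brute-force enumeration of all
        alignments within the bulge budget."""
        rng = np.random.default_rng(7000 + int(near_complement))
        for _ in range(150):
            L = int(rng.integers(19, 25))
            mirna = _random_rna(rng, L)
            if near_complement:
                site = list(reverse_complement(mirna))
                for p in rng.choice(L, size=3, replace=False):
                    site[p] = str(rng.choice(list("ACGU")))
                site = "".join(site)
                d = int(rng.integers(-2, 3))
                site = site[:L + d] if d <= 0 else site + _random_rna(rng, d)
            else:
                d = int(rng.integers(-2, 3))
                site = _random_rna(rng, L + d)
            assert align_duplex(mirna, site).score_total == pytest.approx(
                duplex_score_oracle(mirna, site))


class TestScanTargets:
    def test_exact_complement_site_recovered(self, rng):
        query = MatureQuery("miR156", MIR156)
        host = (_random_rna(rng, 120) + reverse_complement(MIR156)
                + _random_rna(rng, 120))
        hits = scan_targets([query], [SequenceRecord("t1", host)])
        assert len(hits) == 1
        assert hits[0].alignment.score_total == 0.0
        assert hits[0].site_start == 120

    def test_site_scoring_four_rejected(self):
        rec, truth = make_target_site(MIR159, 0, 4, 0,
                                      rng=np.random.default_rng(1),
                                      family="miR159")
        assert truth.expected_score == 4.0 and not truth.expected_accepted
        hits = scan_targets([MatureQuery("miR159", MIR159)], [rec])
        assert hits == []

    def test_threshold_zero_keeps_only_perfect_sites(self, rng):
        query = MatureQuery("miR159", MIR159)
        perfect = (_random_rna(rng, 50) + reverse_complement(MIR159)
                   + _random_rna(rng, 50))
        rec1 = SequenceRecord("perfect", perfect)
        rec2, _ = make_target_site(MIR159, 1, 1, 0, 300,
                                   np.random.default_rng(2),
                                   record_id="imperfect", family="miR159")
        hits = scan_targets([query], [rec1, rec2], threshold=0.0)
        assert [h.target_id for h in hits] == ["perfect"]

    def test_near_identical_transcripts_collapse_to_one_target(self, rng):
        query = MatureQuery("miR156", MIR156)
        base = (_random_rna(rng, 100) + reverse_complement(MIR156)
                + _random_rna(rng, 100))
        variant = list(base)
        variant[5] = {"A": "C", "C": "A", "G": "A", "U": "C"}[variant[5]]
        hits = scan_targets([query], [SequenceRecord("t1", base),
                                      SequenceRecord("t2", "".join(variant))])
        assert len(hits) == 1
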