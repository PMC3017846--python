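import numpy as np
import pytest

from mircane.homology_scan import (MatureQuery, exclusion_screen,
                                   extract_window, merge_hits, scan)
from mircane.oracles import scan_oracle
from mircane.seqio import SequenceRecord, reverse_complement

_SUBST = {"A": "C", "C": "A", "G": "A", "U": "C"}


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


def _embed(rng, host_len, query, n_subs):
    host = _random_rna(rng, host_len)
    mutated = list(query)
    for p in rng.choice(len(query), size=n_subs, replace=False):
        mutated[p] = _SUBST[mutated[p]]
    pos = int(rng.integers(0, host_len - len(query)))
    return host[:pos] + "".join(mutated) + host[pos + len(query):], pos


def _as_tuples(hits):
    return [(h.db_id, h.strand, h.start, h.end, h.query.family,
             h.substitutions, h.gaps) for h in hits]


class TestScan:
    def test_exact_embedding_found_once(self, rng):
        query = _random_rna(rng, 21)
        host, pos = _embed(rng, 500, query, 0)
        hits = scan([SequenceRecord("h", host)], [MatureQuery("q", query)])
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].start, plus[0].end) == (pos, pos + 21)
        assert plus[0].substitutions == 0 and plus[0].gaps == 0

    def test_two_substitutions_recovered(self, rng):
        query = _random_rna(rng, 21)
        host, pos = _embed(rng, 500, query, 2)
        hits = scan([SequenceRecord("h", host)], [MatureQuery("q", query)])
        best = min(hits, key=lambda h: h.edit_total)
        assert best.substitutions == 2 and best.gaps == 0
        assert best.start == pos

    def test_four_substitutions_not_found(self, rng):
        query = _random_rna(rng, 21)
        # four spread substitutions exceed the default 3-edit budget
        mutated = list(query)
        for p in (2, 7, 12, 18):
            mutated[p] = _SUBST[mutated[p]]
        host = _random_rna(rng, 200) + "".join(mutated) + _random_rna(rng, 200)
        hits = scan([SequenceRecord("h", host)], [MatureQuery("q", query)])
        assert hits == []

    def test_minus_strand_embedding_found(self, rng):
        query = _random_rna(rng, 21)
        host, pos = _embed(rng, 400, query, 0)
        rc_host = reverse_complement(host)
        hits = scan([SequenceRecord("h", rc_host)], [MatureQuery("q", query)])
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        n = len(host)
        assert (minus[0].start, minus[0].end) == (n - pos - 21, n - pos)

    def test_empty_inputs_rejected(self, rng):
        rec = SequenceRecord("h", _random_rna(rng, 50))
        with pytest.raises(ValueError):
            scan([], [MatureQuery("q", "A" * 21)])
        with pytest.raises(ValueError):
            scan([rec], [])

    @pytest.mark.parametrize("trial", range(12))
    def test_seeded_scan_equals_exhaustive_oracle(self, trial):
        """The pigeonhole seeding loses no hit relative to a full
        per-offset edit-distance scan."""
        rng = np.random.default_rng(5000 + trial)
        n = int(rng.integers(400, 3000))
        query = _random_rna(rng, 21)
        host, _ = _embed(rng, n, query, int(rng.integers(0, 4)))
        rec = SequenceRecord("h", host)
        queries = [MatureQuery("q", query)]
        assert _as_tuples(scan([rec], queries)) == scan_oracle([rec], queries)


class TestWindows:
    def test_window_spans_hit_with_flanks(self, rng):
        query = _random_rna(rng, 21)
        host = _random_rna(rng, 300) + query + _random_rna(rng, 300)
        rec = SequenceRecord("h", host)
        hit = scan([rec], [MatureQuery("q", query)])[0]
        win = extract_window(rec, hit, flank=300)
        assert (win.window_start, win.window_end) == (0, 621)
        assert win.mature_offset == 300
        assert win.mature_region() == query

    def test_window_clamps_at_record_edges(self, rng):
        query = _random_rna(rng, 21)
        host = _random_rna(rng, 10) + query + _random_rna(rng, 400)
        rec = SequenceRecord("h", host)
        hit = [h for h in scan([rec], [MatureQuery("q", query)])
               if h.strand == "+"][0]
        win = extract_window(rec, hit, flank=300)
        assert win.window_start == 0
        assert win.mature_offset == 10
        assert win.window_end <= len(rec)

    def test_minus_strand_window_is_reverse_complemented(self, rng):
        query = _random_rna(rng, 21)
        host = _random_rna(rng, 60) + reverse_complement(query) + _random_rna(rng, 60)
        rec = SequenceRecord("h", host)
        hit = [h for h in scan([rec], [MatureQuery("q", query)])
               if h.strand == "-"][0]
        win = extract_window(rec, hit, flank=50)
        assert win.mature_region() == query
        plus_slice = rec.residues[win.window_start:win.window_end]
        assert win.residues == reverse_complement(plus_slice)


class TestExclusionScreen:
    def _window(self, rng, mature):
        host = _random_rna(rng, 80) + mature + _random_rna(rng, 80)
        rec = SequenceRecord("h", host)
        hit = [h for h in scan([rec], [MatureQuery("q", mature)])
               if h.strand == "+"][0]
        return extract_window(rec, hit, flank=60)

    def test_matching_window_removed(self, rng):
        mature = _random_rna(rng, 21)
        win = self._window(rng, mature)
        excl = [SequenceRecord("trna1", _random_rna(rng, 30) + mature
                               + _random_rna(rng, 30))]
        assert exclusion_screen([win], excl) == []

    def test_empty_exclusion_is_identity(self, rng):
        win = self._window(rng, _random_rna(rng, 21))
        assert exclusion_screen([win], []) == [win]

    def test_distant_exclusion_entry_retains_window(self, rng):
        mature = _random_rna(rng, 21)
        win = self._window(rng, mature)
        # four spread substitutions put the entry beyond max_edits
        mutated = list(mature)
        for p in (2, 7, 12, 18):
            mutated[p] = _SUBST[mutated[p]]
        excl = [SequenceRecord("trna1", _random_rna(rng, 30)
                               + "".join(mutated) + _random_rna(rng, 30))]
        assert exclusion_screen([win], excl) == [win]
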