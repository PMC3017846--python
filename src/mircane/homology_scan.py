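"""Mismatch-tolerant scan for mature miRNAs in EST/GSS collections.

The discovery protocol seeds candidate precursor loci by locating known
mature miRNAs inside database sequences while tolerating a small unit-cost
edit distance (substitutions plus single-nucleotide indels, at most
``max_edits``, default 3) between query and matched substring.  Both
strands are scanned because EST orientation is arbitrary.

The search is an exact seed-and-extend: each query is partitioned into
disjoint seed words (pigeonhole: with at most ``e`` edits, at least one of
``e + 1`` covering words occurs verbatim in the subject), seed matches
propose candidate offsets, and a banded dynamic program verifies each
offset.  Seeding is lossless — the hit set equals an exhaustive
per-offset edit-distance scan (see :mod:`mircane.oracles`).  Around every
retained hit a precursor window of ``flank`` nucleotides (default 300) on
each side is cut out for folding, i.e. an approximately 620-nt window for
a 21-nt mature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

from .seqio import SequenceRecord, reverse_complement

log = logging.getLogger(__name__)


class _RawQuery:
    """Unvalidated query carrier for internal scans (exclusion screen)."""

    __slots__ = ("family", "residues")

    def __init__(self, family: str, residues: str):
        self.family = family
        self.residues = residues

    def __len__(self) -> int:
        return len(self.residues)

# Combined-cost encoding for the verification DP: primary key is the edit
# total, secondary key the number of gap moves (prefer substitutions over
# indels among co-optimal alignments).  Edit totals are <= max_edits << 64.
_SUB = 64
_GAP = 65


@dataclass(frozen=True)
class MatureQuery:
    """A known mature miRNA used as a scan driver.

    ``expected_arm`` records on which precursor arm (5p/3p) the homolog
    sits in other species; ``unknown`` disables the arm-concordance
    criterion downstream.
    """

    family: str
    residues: str
    expected_arm: str = "unknown"

    def __post_init__(self) -> None:
        if not 19 <= len(self.residues) <= 24:
            raise ValueError(
                f"mature query {self.family!r}: length {len(self.residues)} "
                "outside the mature-miRNA range [19, 24]"
            )
        if self.expected_arm not in ("5p", "3p", "unknown"):
            raise ValueError(f"expected_arm must be 5p/3p/unknown, "
                             f"got {self.expected_arm!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScanHit:
    """A mature-miRNA match inside a database sequence.

    ``start``/``end`` are 0-based half-open on the plus strand of the
    database record regardless of ``strand``.
    """

    db_id: str
    strand: str
    start: int
    end: int
    query: MatureQuery
    substitutions: int
    gaps: int

    @property
    def edit_total(self) -> int:
        return self.substitutions + self.gaps


@dataclass(frozen=True)
class PrecursorWindow:
    """A strand-resolved candidate precursor window.

    ``residues`` read 5'->3' in the orientation in which the mature
    sequence appears in sense; ``window_start``/``window_end`` remain plus
    strand coordinates of the source record.
    """

    db_id: str
    strand: str
    window_start: int
    window_end: int
    residues: str
    mature_offset: int
    mature_len: int
    query: MatureQuery

    def mature_region(self) -> str:
        return self.residues[self.mature_offset:self.mature_offset + self.mature_len]


def _seed_words(query: str, max_edits: int, seed_len: int) -> List[Tuple[int, str]]:
    """Disjoint covering seed words of at most ``seed_len`` nt.

    At least ``max_edits + 1`` words are produced so that any alignment
    with ``max_edits`` or fewer edits contains one word verbatim.
    """
    n = len(query)
    m = max(max_edits + 1, -(-n // seed_len))
    bounds = [n * j // m for j in range(m + 1)]
    return [(bounds[j], query[bounds[j]:bounds[j + 1]]) for j in range(m)]


def _verify(query: str, text: str, start: int, max_edits: int):
    """Banded DP at a fixed start offset.

    Returns ``(dist, gaps, end)`` for the best-scoring substring
    ``text[start:end]`` within ``max_edits`` of the query, or ``None``.
    Ties are broken toward fewer gap moves, then the smallest end.
    """
    ql = len(query)
    sub = text[start:start + ql + max_edits]
    if len(sub) < ql - max_edits:
        return None
    prev = [j * _GAP for j in range(len(sub) + 1)]
    big = 10 ** 9
    for i in range(1, ql + 1):
        qc = query[i - 1]
        cur = [i * _GAP]
        for j in range(1, len(sub) + 1):
            tc = sub[j - 1]
            diag = prev[j - 1] + (0 if (qc == tc and qc != "N") else _SUB)
            cur.append(min(diag, prev[j] + _GAP, cur[j - 1] + _GAP))
        prev = cur
    best = None
    for j in range(max(0, ql - max_edits), len(sub) + 1):
        c = prev[j]
        if c // _SUB <= max_edits and (best is None or c < best[0]):
            best = (c, j)
    if best is None:
        return None
    c, j = best
    dist, gaps = divmod(c, _SUB)
    return dist - gaps, gaps, start + j  # (substitutions, gaps, end) -- see below


def merge_hits(hits: List[ScanHit]) -> List[ScanHit]:
    """Collapse overlapping hits of the same query/strand.

    Within each chain of mutually overlapping intervals the hit with the
    lowest edit total is kept; ties go to the leftmost start.
    """
    out: List[ScanHit] = []
    keyed = {}
    for h in hits:
        keyed.setdefault((h.db_id, h.strand, h.query.family), []).append(h)
    for group in keyed.values():
        group.sort(key=lambda h: (h.start, h.end))
        chain: List[ScanHit] = []
        chain_end = -1
        for h in group:
            if chain and h.start >= chain_end:
                out.append(min(chain, key=lambda x: (x.edit_total, x.start, x.end)))
                chain = []
            chain.append(h)
            chain_end = max(chain_end, h.end)
        if chain:
            out.append(min(chain, key=lambda x: (x.edit_total, x.start, x.end)))
    out.sort(key=lambda h: (h.db_id, h.query.family, h.strand, h.start))
    return out


def _scan_text(db_id: str, strand: str, text: str, plus_len: int,
               query: MatureQuery, max_edits: int, seed_len: int) -> List[ScanHit]:
    q = query.residues
    starts = set()
    for qoff, word in _seed_words(q, max_edits, seed_len):
        pos = text.find(word)
        while pos != -1:
            diag = pos - qoff
            for s in range(diag - max_edits, diag + max_edits + 1):
                if 0 <= s < len(text):
                    starts.add(s)
            pos = text.find(word, pos + 1)
    hits = []
    for s in sorted(starts):
        res = _verify(q, text, s, max_edits)
        if res is None:
            continue
        subs, gaps, end = res
        if strand == "+":
            a, b = s, end
        else:
            a, b = plus_len - end, plus_len - s
        hits.append(ScanHit(db_id, strand, a, b, query, subs, gaps))
    return hits


def _homopolymer_fraction(s: str) -> float:
    if len(s) < 2:
        return 0.0
    runs = sum(1 for i in range(1, len(s)) if s[i] == s[i - 1])
    return runs / (len(s) - 1)


def scan(db: Sequence[SequenceRecord], queries: Sequence[MatureQuery],
         max_edits: int = 3, seed_len: int = 7) -> List[ScanHit]:
    """Locate all mature-miRNA matches in the database on both strands.

    Returns every merged hit whose unit-cost edit distance to the query is
    at most ``max_edits``; overlapping hits of the same query and strand
    are collapsed keeping the lowest edit total (ties: leftmost).
    """
    if not db:
        raise ValueError("scan: empty database")
    if not queries:
        raise ValueError("scan: empty query set")
    shortest = min(len(q) for q in queries)
    if seed_len > shortest:
        raise ValueError(f"seed_len {seed_len} exceeds shortest query ({shortest})")
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    hits: List[ScanHit] = []
    for rec in db:
        hp = _homopolymer_fraction(rec.residues)
        if hp > 0.8:
            log.warning("record %s is low-complexity (homopolymer fraction %.2f)",
                        rec.id, hp)
        rc = reverse_complement(rec.residues)
        for query in queries:
            hits.extend(_scan_text(rec.id, "+", rec.residues, len(rec),
                                   query, max_edits, seed_len))
            hits.extend(_scan_text(rec.id, "-", rc, len(rec),
                                   query, max_edits, seed_len))
    return merge_hits(hits)


def extract_window(record: SequenceRecord, hit: ScanHit,
                   flank: int = 300) -> PrecursorWindow:
    """Cut the precursor window around a hit, clamped to the record.

    For minus-strand hits the window is reverse-complemented so the mature
    sequence reads 5'->3' left to right, and ``mature_offset`` is given in
    that orientation.
    """
    if hit.db_id != record.id:
        raise ValueError(f"hit refers to {hit.db_id!r}, not {record.id!r}")
    n = len(record)
    if not (0 <= hit.start < hit.end <= n):
        raise ValueError(f"hit coordinates [{hit.start}, {hit.end}) outside "
                         f"record {record.id!r} of length {n}")
    ws = max(0, hit.start - flank)
    we = min(n, hit.end + flank)
    residues = record.residues[ws:we]
    if hit.strand == "-":
        residues = reverse_complement(residues)
        mature_offset = we - hit.end
    else:
        mature_offset = hit.start - ws
    return PrecursorWindow(record.id, hit.strand, ws, we, residues,
                           mature_offset, hit.end - hit.start, hit.query)


def exclusion_screen(candidates: Sequence[PrecursorWindow],
                     exclusion_db: Sequence[SequenceRecord],
                     max_edits: int = 3) -> List[PrecursorWindow]:
    """Drop windows whose mature region matches a known non-miRNA RNA.

    A local stand-in for tRNA/rRNA/snoRNA screens: any window whose
    mature-spanning region hits the exclusion set within ``max_edits``
    (scan semantics, both strands) is removed and the removal logged.
    An empty exclusion set is a no-op.
    """
    if not exclusion_db:
        return list(candidates)
    kept = []
    for win in candidates:
        region = win.mature_region()
        seed_len = min(7, len(region))
        found = None
        for rec in exclusion_db:
            rc = reverse_complement(rec.residues)
            # bypass MatureQuery length validation: a gapped mature region
            # may fall outside [19, 24]
            query = _RawQuery("exclusion", region)
            if (_scan_text(rec.id, "+", rec.residues, len(rec), query,
                           max_edits, seed_len)
                    or _scan_text(rec.id, "-", rc, len(rec), query,
                                  max_edits, seed_len)):
                found = rec.id
                break
        if found is None:
            kept.append(win)
        else:
            log.info("window %s:%d-%d removed by exclusion entry %s",
                     win.db_id, win.window_start, win.window_end, found)
    return kept
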