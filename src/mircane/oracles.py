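"""Brute-force reference implementations for validating the fast paths.

Each function here recomputes a pipeline primitive by exhaustive search,
sharing no code with the production implementation it checks:

* :func:`scan_oracle` — edit-distance scan by banded dynamic programming
  at *every* database offset on both strands (no seeding);
* :func:`fold_oracle_energy` — optimal folding energy by exhaustive
  recursion over all nested structures (no memoisation);
* :func:`duplex_score_oracle` — optimal duplex penalty by enumerating
  every antiparallel alignment within the bulge budget.

They are deliberately slow and are meant for property tests and the
acceptance checks on small instances.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import SequenceRecord, reverse_complement

# --- scan oracle -----------------------------------------------------------

_SUB = 64
_GAP = 65


def _per_start_hits(query: str, text: str, max_edits: int):
    """Best (subs, gaps, end) for every start offset, fully vectorised.

    For each start ``s`` the query is aligned against ``text[s:s+L+e]``
    with a full banded DP; rows are starts, so the whole scan is a stack
    of small DPs evaluated with numpy.  Cost encoding: substitutions and
    gaps both count 1 toward the edit total; among co-optimal ends the
    one with fewer gap moves, then the smallest end, wins.
    """
    L, e = len(query), max_edits
    n = len(text)
    if n == 0:
        return []
    width = L + e
    codes = np.frombuffer(text.encode(), dtype=np.uint8)
    pad = np.full(width, ord("!"), dtype=np.uint8)
    padded = np.concatenate([codes, pad])
    win = np.lib.stride_tricks.sliding_window_view(padded, width)[:n]
    starts = np.arange(n)
    valid = np.minimum(width, n - starts)  # usable text length per start

    INF = 10 ** 7
    D = np.empty((n, L + 1, width + 1), dtype=np.int64)
    D[:, 0, :] = np.arange(width + 1) * _GAP
    qcodes = np.frombuffer(query.encode(), dtype=np.uint8)
    for i in range(1, L + 1):
        qc = qcodes[i - 1]
        match = (win == qc) & (qc != ord("N"))
        sub = np.where(match, 0, _SUB)
        D[:, i, 0] = i * _GAP
        for j in range(1, width + 1):
            D[:, i, j] = np.minimum(
                D[:, i - 1, j - 1] + sub[:, j - 1],
                np.minimum(D[:, i - 1, j] + _GAP, D[:, i, j - 1] + _GAP),
            )
    # mask ends beyond the text and outside the band
    cols = np.arange(width + 1)
    final = D[:, L, :].copy()
    final[cols[None, :] > valid[:, None]] = INF
    final[:, :max(0, L - e)] = INF
    best_j = np.argmin(final, axis=1)  # first minimum -> smallest end
    best_c = final[starts, best_j]
    hits = []
    for s in range(n):
        c = int(best_c[s])
        if c >= INF:
            continue
        total, gaps = divmod(c, _SUB)
        if total <= max_edits:
            hits.append((s, s + int(best_j[s]), total - gaps, gaps))
    return hits


def _merge(hits, db_id, strand, family):
    """Single-linkage merge of overlapping intervals, keeping the best."""
    out = []
    hits = sorted(hits)
    chain, chain_end = [], -1
    for h in hits:
        if chain and h[0] >= chain_end:
            out.append(min(chain, key=lambda x: (x[2] + x[3], x[0], x[1])))
            chain = []
        chain.append(h)
        chain_end = max(chain_end, h[1])
    if chain:
        out.append(min(chain, key=lambda x: (x[2] + x[3], x[0], x[1])))
    return [(db_id, strand, s, e, family, subs, gaps)
            for (s, e, subs, gaps) in out]


def scan_oracle(db: Sequence[SequenceRecord], queries,
                max_edits: int = 3) -> List[Tuple]:
    """Exhaustive both-strand scan; comparable with the seeded scan.

    Returns sorted tuples ``(db_id, strand, start, end, family,
    substitutions, gaps)`` with plus-strand coordinates.
    """
    results = []
    for rec in db:
        for strand, text in (("+", rec.residues),
                             ("-", reverse_complement(rec.residues))):
            n = len(text)
            for q in queries:
                hits = _per_start_hits(q.residues, text, max_edits)
                if strand == "-":
                    hits = [(n - e, n - s, subs, gaps)
                            for (s, e, subs, gaps) in hits]
                results.extend(_merge(hits, rec.id, strand, q.family))
    results.sort(key=lambda h: (h[0], h[4], h[1], h[2]))
    return results


# --- fold oracle -----------------------------------------------------------

_PAIR_E = {
    frozenset(("G", "C")): -3.0,
    frozenset(("A", "U")): -2.0,
    frozenset(("G", "U")): -1.0,
}


def fold_oracle_energy(seq: str, min_loop: int = 3,
                       weights: Optional[Dict[frozenset, float]] = None) -> float:
    """Optimal energy over all nested structures by plain recursion.

    No memoisation: every decomposition is revisited, so this is
    exponential and only usable for short sequences (roughly n <= 30).
    """
    w = weights or _PAIR_E

    def rec(i: int, j: int) -> float:
        if j - i + 1 < min_loop + 2:
            return 0.0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            e = w.get(frozenset((seq[i], seq[k])))
            if e is None:
                continue
            cand = e + rec(i + 1, k - 1) + rec(k + 1, j)
            if cand < best:
                best = cand
        return best

    return rec(0, len(seq) - 1)


# --- duplex score oracle ---------------------------------------------------

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def duplex_score_oracle(mirna: str, site: str, max_bulges: int = 2) -> float:
    """Minimum duplex penalty by enumerating all alignments.

    Alignments are generated by choosing which miRNA positions and which
    site positions are bulged (at most ``max_bulges`` nucleotides in
    total); the remaining positions pair off in order, antiparallel.
    """
    t = site[::-1]
    n, m = len(mirna), len(t)
    best = None
    for bm in range(max_bulges + 1):
        bt = m - (n - bm)
        if bt < 0 or bm + bt > max_bulges:
            continue
        for mir_bulges in combinations(range(n), bm):
            mir_keep = [i for i in range(n) if i not in mir_bulges]
            for t_bulges in combinations(range(m), bt):
                t_keep = [j for j in range(m) if j not in t_bulges]
                score = 1.5 * (bm + bt)
                for i, j in zip(mir_keep, t_keep):
                    pair = (mirna[i], t[j])
                    if pair in _WC:
                        continue
                    score += 0.5 if pair in _GU else 1.0
                if best is None or score < best:
                    best = score
    if best is None:
        raise ValueError("length difference exceeds the bulge budget")
    return best
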